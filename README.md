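# cambind

Quantitative structural analysis of calmodulin (CaM) / target-peptide
complexes, built around the solution-NMR study of CaM bound to the
CaM-target peptide of calcineurin (CaNp, residues 391–414 of the
calcineurin A subunit).

Calmodulin recognizes most of its 1:1 targets by wrapping its two EF-hand
domains around an amphipathic target helix, gripping bulky hydrophobic
*anchor* residues in the hydrophobic pocket of each domain. The one-based
spacing between the first and last anchor names the binding-mode family
(1–10, 1–14, 1–16, 1–18 …), and the two domains sit in an approximately
two-fold (C2) symmetric arrangement about the peptide helix axis. This
package implements the analyses needed to characterize such a complex from
multi-model coordinates and simple tabular spectroscopy data:

- **structure_io** — multi-model PDB reading/writing and deterministic atom
  selection (author numbering preserved; altloc and HETATM handling).
- **geometry_core** — Kabsch least-squares superposition, RMSD-to-mean
  ensemble statistics, and the Chasles screw decomposition
  (axis, angle, pitch) of any rigid transform.
- **helix_analysis** — dihedral-based helix assignment, helix-axis fitting
  (second-difference construction refined by a cylinder fit), inter-helical
  kink angles, helicity fractions.
- **domain_symmetry** — the interdomain CA transform (fixed EF-hand sequence
  offset) and its deviation from an ideal 180° rotation about the peptide
  axis: the pseudo-C2 deviation.
- **binding_interface** — heavy-atom contacts (4.5 Å NOE-proxy cutoff),
  Arg/Lys↔Glu/Asp salt bridges (4.0 Å N–O), hydrophobic anchor
  identification and the "1–K" spacing-mode label.
- **csp_mapping** — the normalized amide chemical-shift perturbation
  Δδ_residue = √(( Δδ_HN² + (Δδ_N/5)² ) / 2) with 2×/3×-mean region calling.
- **biophys_calibration** — DLS log₁₀R_H → log₁₀M_r power-law calibration and
  a two-state 222 nm CD helicity estimator.
- **synthetic_data** — seeded generators (ideal/kinked helices from standard
  internal coordinates, pseudo-C2 toy complexes, shift tables, CD spectra,
  size standards) with exact ground truth for every analysis.
- **cli_reports** — a `cambind` command with subcommands for each analysis,
  writing JSON/TSV reports.

## Worked example

Generate the synthetic fixture set and run two analyses:

```sh
cambind make-fixtures --outdir fixtures --seed 3
cambind symmetry fixtures/toy_complex.pdb \
    --receptor-chain R --peptide-chain P \
    --n-domain 1:30 --c-domain 101:130 --peptide-range 1:24 \
    --offset 100 --out symmetry.json
cambind calibrate-dls fixtures/dls_standards.csv --query-rh 2.61 --out dls.json
```

The toy complex is built with its second domain rotated 17° beyond perfect
C2 symmetry about the peptide axis; the symmetry report recovers it from the
five noisy models:

```json
"mean_c2_deviation_deg": 17.26,
"sd_c2_deviation_deg": 1.23
```

and the DLS calibration over the four globular standards (BSA 6.75 nm/67 kDa,
calmodulin 2.44 nm/16.7 kDa, lysozyme 2.20 nm/14.7 kDa, ubiquitin
1.7 nm/8.4 kDa) evaluated at the complex's measured R_H of 2.61 nm gives

```json
"estimated_mr_kda": 17.4
```

i.e. an apparent size of ≈17 kDa — a single wrapped 1:1 complex, not a
domain-swapped dimer.

In Python the same analyses are three calls:

```python
from cambind import (ToyComplexParams, make_toy_complex, fit_helix_axis,
                     analyze_domain_symmetry, DomainSpec)
import numpy as np

toy = make_toy_complex(ToyComplexParams(c2_twist=17.0))
model = toy.models[0]
axis = fit_helix_axis(np.array([r.atom("CA").coords
                                for r in model if r.chain_id == "P"]))
report = analyze_domain_symmetry(
    model,
    DomainSpec("R", (1, 30), "N-domain"),
    DomainSpec("R", (101, 130), "C-domain"),
    axis, offset=100)
print(round(report.c2_deviation, 3))   # 17.0
```

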