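# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Coordinates and selections

Structures are multi-model PDB ensembles; author residue numbering is kept
everywhere because the residues of interest (Ile396, Gly404, Glu84, …) are
always cited by author number. Alternate locations are resolved to the
highest-occupancy conformer (ties go to altloc A). Insertion codes are
rejected — none occur in the depositions this package targets, and silently
reinterpreting them would corrupt numbering. "Backbone" means {N, CA, C, O};
"heavy" means every non-hydrogen, with hydrogens recognized by the element
field when present and otherwise by the first alphabetic character of the
atom name. HETATM residues (the four bound Ca²⁺ ions in calmodulin
ensembles) are parsed and selectable but excluded from selections by
default, including all RMSD statistics; pass `include_het` to override.
"All-atom" ensemble statistics therefore mean all *heavy* atoms of the
selected residue ranges.

## Superposition and ensemble statistics

Superposition is the closed-form least-squares solution (Kabsch/SVD) with
the determinant correction, so reflections are never returned. Ensemble
precision follows the standard NMR convention: all models are superposed on
model 1, averaged, re-superposed on the running mean until the mean moves
less than 1e-6 Å (at most 50 iterations; seeding with model 1 makes the
procedure deterministic), and the per-model RMSD to the converged mean is
reported as mean ± sd with the n−1 denominator.

For m models that are a common structure plus isotropic Gaussian noise of
sd σ per coordinate, the expected RMSD to the mean is σ√3·√((m−1)/m); the
test suite checks this closed form at σ = 0.5 Å, m = 20 (superposition
removes six rigid degrees of freedom of ~300, a ≈1% effect absorbed by the
10% test tolerance).

## Screw decomposition

Any rigid transform is rotation about a line plus translation along it
(Chasles). The rotation angle and axis come from the rotation matrix (via
its rotation vector, angle in [0°, 180°]); the axis point solves
(I − R)p = t⊥ in the least-squares sense, which leaves the residual
translation purely axial. Rotations below ~1e-7 rad are treated as pure
translations: the axis is taken along the translation, or +z when the
translation also vanishes. Recomposition reproduces the input transform to
1e-6, property-tested over seeded random transforms.

## Helix assignment and axes

A residue is helical when φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; maximal
runs of ≥ 4 consecutive residues become segments. The window is deliberately
permissive so slightly curved NMR helices are not fragmented, and it is a
module constant, not folklore buried in code. Terminal residues missing φ
or ψ are never helical; numbering gaps break runs.

Axis directions use the second-difference construction: for a regular helix
CA(i−1) − 2·CA(i) + CA(i+1) points exactly radially, so cross products of
successive second differences are exactly axial. Their normalized mean is
the initial estimate, refined by a least-squares cylinder fit (direction,
axis position, radius). The combination is exact on ideal geometry — even
for segments barely longer than one turn, where a principal-component fit
of smoothed centre points carries a multi-degree bias — and close to
maximum likelihood under coordinate noise (≈1° direction error at 0.3 Å
noise on a 24-residue helix). The axis origin is the centroid of
moving-average centre points (window of four CAs ≈ one turn, which cancels
most of the 2.3 Å CA radius); `fit_rms` is the RMS distance of those centre
points to the axis and stays below 0.3 Å for an ideal helix.

The kink angle at a hinge residue is the angle between the N→C axis
directions fitted independently to the residues before and after the hinge;
the hinge residue itself (the Gly404 tether in the calcineurin peptide)
belongs to neither segment. Constructed bends of 0–45° are recovered within
1° on noise-free fixtures. Kinks are computed on model 1 by default; the
CLI `--ensemble` flag averages over models and reports mean ± sd. Whether
the study's quoted kink was measured on one model or the ensemble mean is
not recorded; both conventions agree within a few degrees on NMR-quality
ensembles, which is why the integration script reports both.

## Pseudo-C2 domain orientation

The two calmodulin domains are internally homologous (two EF-hands each),
so residue i of the N-domain is paired with residue i + 73 of the C-domain
by a fixed sequence offset — deterministic, with no structure-alignment
step; the offset is a parameter so other windows (e.g. the 84–145 C-domain
window) can be used. The interdomain transform is the least-squares CA
superposition over those pairs.

The symmetry metric factors an ideal half-turn about the *measured* peptide
helix axis out of the interdomain rotation: c2_deviation is the rotation
angle of R_interdomain · R_ideal(axis, 180°)ᵀ. When the screw axis
coincides with the peptide axis this equals |screw angle − 180°| exactly;
both numbers are reported, along with the tilt between the screw axis and
the peptide axis. The peptide axis is fitted to the whole bound peptide
(residues 392–413 for the calcineurin peptide) rather than to one helical
half — the construction the wrap-around architecture implies — with
per-segment fits available through the helix module. Because the metric is
an unsigned angle, per-model noise biases it upward near zero; ensembles
are therefore analyzed per model and summarized as mean ± sd rather than
folded into a single model.

## Contacts, salt bridges, anchors, binding mode

NOE-observable proximity is approximated by heavy-atom distance: two
residues are in contact when any heavy-atom pair is within 4.5 Å (an
NOE-style proxy: observable NOEs correspond to distances ≲ 5 Å). Salt
bridges are Arg/Lys side-chain nitrogens (NE/NH1/NH2/NZ) within 4.0 Å of
Glu/Asp carboxylate oxygens (OE1/OE2/OD1/OD2), deduplicated per residue
pair; backbone oxygens never count. Both cutoffs are arguments.

An anchor is a hydrophobic peptide residue (ILE, LEU, VAL, PHE, MET, TRP,
TYR or ALA — alanine and methionine included because both line the
calmodulin pockets) with at least one side-chain heavy-atom contact to a
side-chain atom of a hydrophobic receptor residue. `contact_count` counts
distinct receptor residues contacted; anchors with ≥ 5 rank "major". The
count is a proxy for per-residue NOE abundance — whether the original
major/minor ranking reflected NOE counts or buried surface is not recorded,
so the threshold is a configurable parameter rather than a constant.
Spacing indices are one-based from the first anchor; the mode label "1–K"
takes K from the last index (anchors 396/400/410/413 give 1-5-15-18 and
mode "1–18"). Orientation is "parallel" when the first anchor is buried in
the N-domain (CaMKK-like) and "antiparallel" when in the C-domain
(M13-like). For ensembles the CLI reports residue pairs present in at least
half the models, since NMR ensembles fluctuate around the contact cutoff.

## Chemical-shift perturbation

Δδ_residue = √(( Δδ_HN² + (Δδ_N/5)² ) / 2), with the ¹⁵N difference scaled
by exactly 5 (some literature uses ≈6.5 from gyromagnetic ratios; this
package follows the 1/5 convention of the study it reimplements). The mean
is taken over every residue assigned in both states; perturbed regions are
maximal runs of residues above multiplier × mean, with a gap of exactly one
*unassigned* residue bridged (assignment gaps — prolines, exchange-broadened
amides — are routine; a residue that is present but below threshold always
breaks a region). Bridging is switchable. Reproducing any particular
published mean requires the exact free-state shift set that study used;
the module computes whatever tables it is given.

## DLS and CD calibrations

Globular proteins follow an approximate power law between hydrodynamic
radius and molecular weight, so the calibration is ordinary least squares of
log₁₀M_r on log₁₀R_H over *all* standards jointly. Piecewise interpolation
between the bracketing pair is deliberately not used: over the four
standards shipped in `reference` it shifts the estimate at 2.61 nm by about
1 kDa (≈18.3 vs 17.4 kDa), and the joint fit is the one that reproduces the
published estimate. Queries outside the standards' R_H range warn about
extrapolation.

Helicity from CD uses a two-state estimator at 222 nm:
f = (Δε(222) − Δε_coil)/(Δε_helix − Δε_coil), clamped to [0, 1], applied to
the complex-minus-free difference spectrum (which isolates the bound
peptide's contribution when the receptor's own spectrum is unchanged by
binding). The default references Δε_helix(222) = −11.1 and
Δε_coil(222) = −0.3 M⁻¹cm⁻¹ are per-residue literature conventions, not
fitted values, and are arguments; multi-basis deconvolution (the job of
dedicated CD-analysis services) is out of scope. Molar spectra are
converted to per-residue by a user-supplied residue count.

## Synthetic generators

All fixtures are pure functions of (parameters, seed) with a single
`numpy.random.default_rng(seed)` stream per generator.

- **Ideal helices** are built by natural-extension (NeRF) placement from
  standard internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
  C=O 1.231 Å, CA–CB 1.521 Å; ω = 180°), giving CA–CA distances of 3.80 Å
  at φ = −57°, ψ = −47°. Only backbone plus CB is built — enough for every
  geometric analysis here, and nothing pretends to be a physical side chain.
- **Kinked helices** rotate all residues after the hinge rigidly by the
  requested bend about an axis through the hinge CA perpendicular to the
  helix axis, so the inter-segment angle is known exactly.
- **The toy complex** places a 30-residue two-helix bundle against the
  N-terminal half of a kinked peptide and constructs the second "domain" as
  an exact screw image (180° + twist about the fitted peptide axis, plus a
  translation along it), so the interdomain rotation is known to machine
  precision. Anchor contacts are engineered: designated receptor residues
  get an extra side-chain atom placed exactly 4.0 Å from the anchor's CB
  (six receptor residues for the first and last anchor, two for middle
  anchors), with serine at all non-anchor peptide positions so no accidental
  anchors appear. Defaults (24-residue peptide, 17° kink at position 12,
  anchors 1-5-15-18, 20-model ensembles at 0.3–0.5 Å noise) mirror the
  geometry of the calcineurin-peptide complex. The bundle is deliberately
  *not* an EF-hand domain: these fixtures validate geometry and contact
  logic, not calmodulin biology, so passing tests say nothing about
  force-field realism, side-chain packing, or real NOE patterns.
- **Shift tables** draw free shifts from typical amide ranges (¹H 7.5–9.3,
  ¹⁵N 105–130 ppm) and add Gaussian background perturbations (sd 0.02 ppm in
  ¹H, five-fold that in ¹⁵N, matching the nitrogen normalization). Hotspot
  residues receive an extra offset of hotspot_scale × the background sd,
  applied in the direction of the residue's background deviation, so every
  hotspot's normalized perturbation exceeds the scale factor by
  construction and region recovery is seed-independent at the default
  six-fold scale.
- **CD spectra** are Gaussian-band helix and coil bases (helix minima at
  208/222 nm, coil minimum at 198 nm) normalized to the reference Δε(222)
  values and mixed linearly; **DLS standards** sample an exact power law
  with optional lognormal scatter.

## Problem sizes

The default suite and the reproduction script run entirely on synthetic
inputs: 20-model ensembles of the ~84-residue toy complex, 148-residue
shift tables, 100 five-point clouds for the superposition cross-check and
1000 random transforms for the screw round-trip — sizes chosen to exercise
every code path at interactive speed while keeping the statistical checks
(closed-form RMSD, twist recovery within 3° under 0.3 Å noise)
well-resolved.

## Known limitations

- No mmCIF, NMR restraint files, or NMR-STAR beyond simple tabular shifts.
- Secondary structure is dihedral-only; no hydrogen-bond (DSSP-style)
  assignment, no 3₁₀/π classes.
- Correspondence for superposition is always explicit (equal-length paired
  selections or a fixed sequence offset); there is no structure alignment
  of non-identical compositions.
- The contact proxy is distance-only: no NOE back-calculation, buried
  surface area, or electrostatic potential surfaces.
- The CD estimator is strictly two-state at a single wavelength; spectra
  with strong aromatic or disulfide contributions will bias it.
- The unsigned pseudo-C2 metric is biased upward near 0° under coordinate
  noise (by roughly twice the axis-fit error); compare ensembles via the
  reported mean ± sd, not single models.
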