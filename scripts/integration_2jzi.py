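#!/usr/bin/env python
"""Optional integration analysis against the deposited NMR ensemble.

Requires a locally downloaded copy of PDB entry 2JZI (the solution structure
of the calmodulin/calcineurin-peptide complex); nothing is fetched here.

    python scripts/integration_2jzi.py path/to/2jzi.pdb [--out report.json]

Recomputes, from the deposited coordinates: the ensemble backbone and
heavy-atom RMSD to the mean (calmodulin 5-145 + peptide 392-413), the
peptide kink at Gly404, the pseudo-C2 deviation of the two calmodulin
domains about the peptide axis, the intermolecular salt bridges, and the
hydrophobic anchor set with its spacing mode.
"""

from __future__ import annotations

import argparse
import json
from collections import Counter

import numpy as np

from cambind import reference
from cambind.binding_interface import find_salt_bridges, identify_anchors, spacing_pattern
from cambind.domain_symmetry import DomainSpec, analyze_domain_symmetry
from cambind.geometry_core import ensemble_rmsd_to_mean
from cambind.helix_analysis import fit_helix_axis, kink_angle
from cambind.structure_io import parse_structure, select_atoms, SelectionSpec


def detect_chains(model):
    """Peptide chain = the one holding residues 391-414; receptor the other."""
    chains = {}
    for res in model:
        if not res.het:
            chains.setdefault(res.chain_id, set()).add(res.seq_number)
    peptide = receptor = None
    for cid, nums in chains.items():
        if reference.CANP_START in nums and reference.CANP_END in nums and len(nums) < 50:
            peptide = cid
        elif len(nums) > 100:
            receptor = cid
    if peptide is None or receptor is None:
        raise SystemExit(f"could not identify chains among {list(chains)}")
    return receptor, peptide


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("pdb", help="local path to the deposited 2JZI PDB file")
    parser.add_argument("--out", default="2jzi_report.json")
    args = parser.parse_args()

    ens = parse_structure(args.pdb, id="2JZI")
    receptor, peptide = detect_chains(ens.models[0])
    print(f"{ens.n_models} models; receptor chain {receptor!r}, peptide chain {peptide!r}")

    results: dict = {"n_models": ens.n_models}

    # ensemble precision over the ordered residue windows; both chains'
    # windows are concatenated into one joint selection per model
    from cambind.geometry_core import _rmsd, kabsch

    for atoms, key in (("backbone", "backbone_rmsd_A"), ("heavy", "heavy_rmsd_A")):
        coords = []
        for i in range(ens.n_models):
            a = select_atoms(ens, SelectionSpec(receptor, reference.CAM_ORDERED_RANGE, atoms), i)
            b = select_atoms(ens, SelectionSpec(peptide, (392, 413), atoms), i)
            coords.append(np.vstack([a.coords, b.coords]))
        mean = coords[0].copy()
        for _ in range(50):
            fitted = [kabsch(c, mean).apply(c) for c in coords]
            new_mean = np.mean(fitted, axis=0)
            if np.max(np.linalg.norm(new_mean - mean, axis=1)) < 1e-6:
                mean = new_mean
                break
            mean = new_mean
        per_model = [_rmsd(kabsch(c, mean).apply(c), mean) for c in coords]
        results[key] = {"mean": round(float(np.mean(per_model)), 2),
                        "sd": round(float(np.std(per_model, ddof=1)), 2)}

    # peptide kink at the Gly tether
    kinks = [kink_angle(m, peptide, reference.CANP_KINK_RESIDUE) for m in ens.models]
    results["kink_deg"] = {"mean": round(float(np.mean(kinks)), 1),
                           "sd": round(float(np.std(kinks, ddof=1)), 1),
                           "model1": round(kinks[0], 1)}

    # pseudo-C2 deviation about the peptide axis
    n_spec = DomainSpec(receptor, reference.CAM_N_DOMAIN, "N-domain")
    c_spec = DomainSpec(receptor, (reference.CAM_N_DOMAIN[0] + reference.EF_HAND_OFFSET,
                                   reference.CAM_N_DOMAIN[1] + reference.EF_HAND_OFFSET),
                        "C-domain")
    devs = []
    for i, model in enumerate(ens.models):
        ca = select_atoms(ens, SelectionSpec(peptide, (392, 413), frozenset({"CA"})), i)
        rep = analyze_domain_symmetry(model, n_spec, c_spec, fit_helix_axis(ca),
                                      reference.EF_HAND_OFFSET)
        devs.append(rep.c2_deviation)
    results["c2_deviation_deg"] = {"mean": round(float(np.mean(devs)), 1),
                                   "sd": round(float(np.std(devs, ddof=1)), 1)}

    # salt bridges present in at least half the models
    counts: Counter = Counter()
    for model in ens.models:
        for b in find_salt_bridges(model, peptide, receptor):
            counts[(b.basic_residue[1], b.acidic_residue[1])] += 1
    found = sorted(k for k, v in counts.items() if v >= ens.n_models / 2)
    results["salt_bridges"] = found
    results["published_pairs_found"] = [
        list(p) for p in reference.SALT_BRIDGE_PAIRS if p in set(found)
    ]

    # anchors and binding mode (model 1)
    anchors = identify_anchors(
        ens.models[0],
        SelectionSpec(peptide, (reference.CANP_START, reference.CANP_END)),
        (n_spec, DomainSpec(receptor, reference.CAM_C_DOMAIN, "C-domain")),
    )
    results["anchors"] = [
        {"residue": a.residue[1], "name": a.residue[2], "rank": a.rank,
         "contacts": a.contact_count, "domain": a.buried_domain}
        for a in anchors
    ]
    if anchors:
        pattern = spacing_pattern(anchors)
        results["mode_label"] = pattern.mode_label
        results["orientation"] = pattern.orientation

    with open(args.out, "w") as fh:
        json.dump(results, fh, indent=2)
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
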