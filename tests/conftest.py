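"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: the
rotation-space minimizer searches quaternion space numerically instead of
using the closed-form SVD solution, and the contact/salt-bridge oracles are
plain double loops over atom records.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cambind.structure_io import BACKBONE_ATOMS
from cambind.synthetic_data import (
    ToyComplexParams,
    build_ideal_helix,
    build_kinked_helix,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def kinked_helix_17():
    return build_kinked_helix("A" * 24, split_index=12, bend=17.0)


@pytest.fixture(scope="session")
def toy_complex():
    """Noise-free pseudo-C2 toy with a 17° extra twist."""
    return make_toy_complex(ToyComplexParams(c2_twist=17.0))


@pytest.fixture(scope="session")
def toy_complex_exact_c2():
    return make_toy_complex(ToyComplexParams(c2_twist=0.0))


# ---------------------------------------------------------------------------
# oracles


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                  n_grid: int = 300, seed: int = 1234) -> float:
    """Minimum RMSD over rotations via random quaternion grid + local refine.

    Centers both clouds (the optimal translation always matches centroids),
    scans ``n_grid`` uniformly random rotations, then polishes the best few
    starting points with a derivative-free rotation-vector minimizer.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rot: Rotation) -> float:
        return float(np.sqrt(np.mean(np.sum((mob @ rot.as_matrix().T - ref) ** 2, axis=1))))

    grid = Rotation.random(n_grid, random_state=np.random.default_rng(seed))
    scores = [rmsd_of(r) for r in grid]
    best = np.inf
    for idx in np.argsort(scores)[:5]:
        res = minimize(
            lambda v: rmsd_of(Rotation.from_rotvec(v)),
            grid[int(idx)].as_rotvec(),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        best = min(best, float(res.fun))
    return best


def brute_force_contacts(model, spec_a, spec_b, cutoff):
    """All residue pairs with any heavy-atom pair within cutoff: O(N²) loops."""
    def residues_of(spec):
        lo, hi = spec.residue_range
        return [r for r in model
                if r.chain_id == spec.chain_id and lo <= r.seq_number <= hi
                and (spec.include_het or not r.het)]

    out = {}
    for ra in residues_of(spec_a):
        for rb in residues_of(spec_b):
            n_pairs = 0
            dmin = np.inf
            for aa in ra.atoms:
                if aa.is_hydrogen:
                    continue
                for ab in rb.atoms:
                    if ab.is_hydrogen:
                        continue
                    d = float(np.linalg.norm(aa.coords - ab.coords))
                    if d <= cutoff:
                        n_pairs += 1
                        dmin = min(dmin, d)
            if n_pairs:
                key = ((ra.chain_id, ra.seq_number, ra.res_name),
                       (rb.chain_id, rb.seq_number, rb.res_name))
                out[key] = (dmin, n_pairs)
    return out


def brute_force_salt_bridges(model, chain_a, chain_b, cutoff):
    """Arg/Lys N ↔ Glu/Asp O cross-chain pairs by exhaustive loops."""
    n_names = {"NE", "NH1", "NH2", "NZ"}
    o_names = {"OE1", "OE2", "OD1", "OD2"}
    out = {}
    for rb in model:
        if rb.res_name not in ("ARG", "LYS") or rb.chain_id not in (chain_a, chain_b):
            continue
        other = chain_b if rb.chain_id == chain_a else chain_a
        for ra in model:
            if ra.chain_id != other or ra.res_name not in ("GLU", "ASP"):
                continue
            dmin = np.inf
            for an in rb.atoms:
                if an.name not in n_names:
                    continue
                for ao in ra.atoms:
                    if ao.name not in o_names:
                        continue
                    dmin = min(dmin, float(np.linalg.norm(an.coords - ao.coords)))
            if dmin <= cutoff:
                out[((rb.chain_id, rb.seq_number, rb.res_name),
                     (ra.chain_id, ra.seq_number, ra.res_name))] = dmin
    return out


def count_heavy_atoms_in_pdb(path, chain_id):
    """Independent line scan: non-hydrogen ATOM/HETATM records of one chain."""
    count = 0
    with open(path) as fh:
        in_first_model = True
        for line in fh:
            if line.startswith("ENDMDL"):
                in_first_model = False
            if not in_first_model:
                continue
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            if line[21] != chain_id:
                continue
            element = line[76:78].strip()
            name = line[12:16].strip()
            symbol = element or next((c for c in name if c.isalpha()), "")
            if symbol.upper() not in ("H", "D"):
                count += 1
    return count


__all__ = [
    "BACKBONE_ATOMS",
    "grid_min_rmsd",
    "brute_force_contacts",
    "brute_force_salt_bridges",
    "count_heavy_atoms_in_pdb",
]
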