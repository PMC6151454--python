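"""Pseudo-C2 analysis of the two calmodulin domains about the peptide axis.

In wrap-around calmodulin/peptide complexes the two homologous domains sit
in an approximately two-fold symmetric arrangement about the bound peptide's
helical axis: the rigid transform carrying the N-domain CA trace onto the
homologous C-domain CA trace is close to a 180° screw rotation about that
axis.  This module quantifies how far a given structure deviates from that
ideal: the residual rotation left after factoring an exact 180° turn about
the measured peptide axis out of the interdomain transform.

Residue correspondence between the domains is by a fixed sequence offset
(default 73, pairing calmodulin residues 5–72 with 78–145 — the two pairs of
EF-hand motifs are internally homologous), not by structure alignment, so
the measurement is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PairingError
from .geometry_core import (
    RigidTransform,
    ScrewDecomposition,
    angle_between_deg,
    rotation_angle_deg,
    screw_decompose,
    superpose,
)
from .helix_analysis import HelixAxis
from .structure_io import CoordinateSet, Residue, get_residue

DEFAULT_OFFSET = 73


@dataclass(frozen=True)
class DomainSpec:
    chain_id: str
    residue_range: tuple[int, int]
    label: Literal["N-domain", "C-domain"]


@dataclass
class SymmetryReport:
    interdomain: ScrewDecomposition
    axis_tilt: float  # degrees between screw axis and peptide axis, in [0, 90]
    c2_deviation: float  # degrees, residual rotation beyond ideal C2
    screw_angle_excess: float  # |screw angle − 180|, the alternative metric
    fit_rmsd: float | None = None
    n_pairs: int | None = None


def interdomain_transform(
    model: Sequence[Residue],
    n_spec: DomainSpec,
    c_spec: DomainSpec,
    offset: int = DEFAULT_OFFSET,
) -> tuple[RigidTransform, float, int]:
    """Least-squares transform mapping N-domain CAs onto C-domain CAs.

    Residue i of the N-domain pairs with residue i+offset of the C-domain;
    pairs with a missing partner or missing CA are dropped.  Returns
    (transform, fit RMSD in angstrom, number of CA pairs).
    """
    start, end = n_spec.residue_range
    c_lo, c_hi = c_spec.residue_range
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    missing: list[tuple[int, int]] = []
    for i in range(start, end + 1):
        j = i + offset
        if not c_lo <= j <= c_hi:
            continue
        rn = get_residue(model, n_spec.chain_id, i)
        rc = get_residue(model, c_spec.chain_id, j)
        ca_n = rn.atom("CA") if rn is not None else None
        ca_c = rc.atom("CA") if rc is not None else None
        if ca_n is None or ca_c is None:
            missing.append((i, j))
            continue
        pairs.append((ca_n.coords, ca_c.coords))
    if len(pairs) < 10:
        raise PairingError(
            f"only {len(pairs)} CA pairs for offset {offset}"
            + (f"; missing pairs: {missing}" if missing else "")
        )
    mob = CoordinateSet(
        labels=[("N", k, "CA") for k in range(len(pairs))],
        coords=np.array([p[0] for p in pairs]),
    )
    ref = CoordinateSet(
        labels=[("C", k, "CA") for k in range(len(pairs))],
        coords=np.array([p[1] for p in pairs]),
    )
    result = superpose(mob, ref)
    return result.transform, result.rmsd, result.n_atoms


def c2_deviation(
    t: RigidTransform,
    peptide_axis: HelixAxis,
    fit_rmsd: float | None = None,
    n_pairs: int | None = None,
) -> SymmetryReport:
    """Deviation of an interdomain transform from ideal C2 about the peptide.

    The primary metric is the rotation angle of ``t.rotation · R_180ᵀ`` where
    ``R_180`` is the exact half-turn about the peptide axis direction; for a
    transform whose screw axis coincides with the peptide axis this equals
    |screw angle − 180°| exactly.  ``axis_tilt`` measures how far the actual
    screw axis leans away from the peptide axis.
    """
    axis = np.asarray(peptide_axis.direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    r_ideal = Rotation.from_rotvec(np.pi * axis).as_matrix()
    residual = t.rotation @ r_ideal.T
    deviation = rotation_angle_deg(residual)
    screw = screw_decompose(t)
    tilt = angle_between_deg(screw.axis, axis, fold=True)
    return SymmetryReport(
        interdomain=screw,
        axis_tilt=tilt,
        c2_deviation=deviation,
        screw_angle_excess=abs(screw.angle - 180.0),
        fit_rmsd=fit_rmsd,
        n_pairs=n_pairs,
    )


def analyze_domain_symmetry(
    model: Sequence[Residue],
    n_spec: DomainSpec,
    c_spec: DomainSpec,
    peptide_axis: HelixAxis,
    offset: int = DEFAULT_OFFSET,
) -> SymmetryReport:
    """Convenience wrapper: interdomain transform + C2 deviation in one call."""
    t, rmsd, n = interdomain_transform(model, n_spec, c_spec, offset)
    return c2_deviation(t, peptide_axis, fit_rmsd=rmsd, n_pairs=n)
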