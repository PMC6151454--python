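"""Helical-segment assignment and helix-axis geometry.

Helices are assigned from backbone dihedrals alone (a residue is helical
when φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°], with maximal runs of at least
four residues) — deliberately permissive so slightly curved NMR helices are
not fragmented.  Axis directions come from the second-difference
construction: for a regular helix the vector CA(i−1) − 2·CA(i) + CA(i+1)
points exactly radially, so cross products of successive second differences
are exactly axial; their mean, refined by a least-squares cylinder fit, is
exact on ideal geometry and close to maximum likelihood under coordinate
noise.  Centre points for the axis location are moving averages of four
consecutive CAs (about one turn), which cancels most of the 2.3 Å CA radius.

The kink angle of a bent helix is the angle between the N→C axis directions
fitted independently to the residues before and after a chosen hinge
residue (the hinge itself — Gly404 in the calcineurin target peptide —
belongs to neither segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegeneracyError
from .structure_io import CoordinateSet, Residue, chain_residues

logger = logging.getLogger(__name__)

PHI_RANGE = (-100.0, -30.0)
PSI_RANGE = (-80.0, -5.0)
MIN_RUN = 4
AXIS_WINDOW = 4  # CA moving-average window for axis centre points


@dataclass(frozen=True)
class HelixSegment:
    chain_id: str
    start: int
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < MIN_RUN:
            raise ValueError("helix segment shorter than 4 residues")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HelixAxis:
    """N→C oriented axis of one helical stretch."""

    direction: np.ndarray
    centroid: np.ndarray
    fit_rms: float


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.rad2deg(np.arctan2(y, x)))


def backbone_dihedrals(
    residues: Sequence[Residue],
) -> list[tuple[int, float | None, float | None]]:
    """(seq_number, φ, ψ) per residue; None where a flanking residue or atom
    is missing or the chain numbering is not consecutive."""
    out: list[tuple[int, float | None, float | None]] = []
    coords = []
    for r in residues:
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        if n is None or ca is None or c is None:
            logger.warning("residue %s/%d lacks backbone atoms; skipped",
                           r.chain_id, r.seq_number)
            coords.append(None)
        else:
            coords.append((n.coords, ca.coords, c.coords))
    for i, r in enumerate(residues):
        phi = psi = None
        if coords[i] is not None:
            prev_ok = (i > 0 and coords[i - 1] is not None
                       and residues[i - 1].seq_number == r.seq_number - 1)
            next_ok = (i + 1 < len(residues) and coords[i + 1] is not None
                       and residues[i + 1].seq_number == r.seq_number + 1)
            n, ca, c = coords[i]
            if prev_ok:
                phi = dihedral_deg(coords[i - 1][2], n, ca, c)
            if next_ok:
                psi = dihedral_deg(n, ca, c, coords[i + 1][0])
        out.append((r.seq_number, phi, psi))
    return out


def assign_helices(model: Sequence[Residue], chain_id: str) -> list[HelixSegment]:
    """Maximal runs (≥ 4 residues) inside the helical dihedral window.

    Terminal residues lacking φ or ψ are never helical.
    """
    residues = chain_residues(model, chain_id)
    if len(residues) < MIN_RUN:
        return []
    dihedrals = backbone_dihedrals(residues)
    helical = [
        phi is not None and psi is not None
        and PHI_RANGE[0] <= phi <= PHI_RANGE[1]
        and PSI_RANGE[0] <= psi <= PSI_RANGE[1]
        for _, phi, psi in dihedrals
    ]
    segments: list[HelixSegment] = []
    run_start = None
    nums = [num for num, _, _ in dihedrals]
    for i, flag in enumerate(helical + [False]):
        contiguous = i > 0 and i < len(nums) and nums[i] == nums[i - 1] + 1
        if flag and run_start is not None and not contiguous:
            # numbering gap breaks the run
            if i - run_start >= MIN_RUN:
                segments.append(HelixSegment(chain_id, nums[run_start], nums[i - 1]))
            run_start = i
        elif flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= MIN_RUN:
                segments.append(HelixSegment(chain_id, nums[run_start], nums[i - 1]))
            run_start = None
    return segments


def _crossdiff_direction(ca: np.ndarray) -> np.ndarray:
    """Initial axis estimate from CA second differences.

    For a regular helix the second difference CA(i−1) − 2·CA(i) + CA(i+1)
    is exactly radial, so cross products of successive second differences
    are exactly axial; their normalized mean is exact on ideal geometry
    regardless of segment length.
    """
    second = ca[:-2] - 2.0 * ca[1:-1] + ca[2:]
    crosses = np.cross(second[:-1], second[1:])
    norms = np.linalg.norm(crosses, axis=1)
    keep = norms > 1e-9
    if not keep.any():
        raise DegeneracyError("degenerate CA trace: no curvature to define an axis")
    crosses = crosses[keep] / norms[keep, None]
    rough = ca[-1] - ca[0]
    crosses[crosses @ rough < 0] *= -1.0
    direction = crosses.mean(axis=0)
    return direction / np.linalg.norm(direction)


def _cylinder_axis(ca: np.ndarray, d0: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Refine an axis direction by least-squares cylinder fitting.

    Minimizes the spread of CA distances to the axis line over direction,
    axis position (in the plane normal to the initial direction) and
    radius.  Exact for noise-free regular helices; close to the maximum
    likelihood direction under isotropic coordinate noise.
    """
    u = np.cross(d0, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(d0, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d0, u)

    def unpack(p):
        d = d0 + p[0] * u + p[1] * v
        d /= np.linalg.norm(d)
        return d, c0 + p[2] * u + p[3] * v, p[4]

    def residuals(p):
        d, point, radius = unpack(p)
        rel = ca - point
        perp = rel - np.outer(rel @ d, d)
        return np.linalg.norm(perp, axis=1) - radius

    rel0 = ca - c0
    r0 = float(np.mean(np.linalg.norm(rel0 - np.outer(rel0 @ d0, d0), axis=1)))
    sol = least_squares(residuals, [0.0, 0.0, 0.0, 0.0, r0], method="lm")
    return unpack(sol.x)[0]


def fit_helix_axis(ca_coords: CoordinateSet | np.ndarray) -> HelixAxis:
    """Fit the axis of a helical CA trace.

    The direction starts from the second-difference cross-product estimate
    and is refined by a least-squares cylinder fit, oriented so that it
    points from the first CA toward the last.  The axis passes through the
    centroid of moving-average centre points; ``fit_rms`` is the RMS
    distance of those centre points to the fitted line.
    """
    ca = ca_coords.coords if isinstance(ca_coords, CoordinateSet) else np.asarray(ca_coords)
    ca = ca.reshape(-1, 3)
    if len(ca) < AXIS_WINDOW + 1:
        raise DegeneracyError(f"helix axis fit needs at least {AXIS_WINDOW + 1} CA atoms")
    centers = np.stack(
        [ca[i : i + AXIS_WINDOW].mean(axis=0) for i in range(len(ca) - AXIS_WINDOW + 1)]
    )
    centroid = centers.mean(axis=0)
    direction = _cylinder_axis(ca, _crossdiff_direction(ca), centroid)
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    resid = (centers - centroid) - np.outer((centers - centroid) @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return HelixAxis(direction=direction, centroid=centroid, fit_rms=fit_rms)


def _ca_trace(residues: Sequence[Residue]) -> np.ndarray:
    cas = [r.atom("CA") for r in residues]
    return np.array([a.coords for a in cas if a is not None])


def kink_angle(
    model: Sequence[Residue],
    chain_id: str,
    split_residue: int,
    flank: int | None = None,
) -> float:
    """Angle in degrees between the helix axes on either side of a hinge.

    Axes are fitted to the CAs of [start .. split−1] and [split+1 .. end];
    the hinge residue belongs to neither.  ``flank`` optionally trims each
    side to the residues nearest the hinge.
    """
    residues = chain_residues(model, chain_id)
    before = [r for r in residues if r.seq_number < split_residue]
    after = [r for r in residues if r.seq_number > split_residue]
    if flank is not None:
        before = before[-flank:]
        after = after[:flank]
    if len(before) < AXIS_WINDOW + 1 or len(after) < AXIS_WINDOW + 1:
        raise DegeneracyError(
            f"kink at {split_residue} needs ≥ {AXIS_WINDOW + 1} CA on each side"
        )
    ax_n = fit_helix_axis(_ca_trace(before))
    ax_c = fit_helix_axis(_ca_trace(after))
    c = float(np.clip(ax_n.direction @ ax_c.direction, -1.0, 1.0))
    return float(np.rad2deg(np.arccos(c)))


def helicity_fraction(
    segments: Sequence[HelixSegment], chain_length: int
) -> tuple[float, int]:
    """(fraction of chain in helix, helical residue count)."""
    if chain_length < 1:
        raise ValueError("chain_length must be ≥ 1")
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(f"overlapping segments {a} and {b}")
    count = sum(len(s) for s in ordered)
    return count / chain_length, count
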