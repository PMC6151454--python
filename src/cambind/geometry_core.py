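"""Rigid-body superposition, ensemble RMSD statistics, screw decomposition.

Superposition uses the closed-form least-squares (Kabsch/SVD) solution with
the determinant correction so that only proper rotations are returned.
Ensemble statistics follow the standard NMR-ensemble convention: all models
are superposed on an iteratively refined mean structure and the RMSD of each
model to that mean is reported as mean ± sd (n−1 denominator).

Any rigid transform can be written as a rotation about a line in space plus
a translation along that line (Chasles' theorem); :func:`screw_decompose`
computes that axis/angle/pitch form, which is what the pseudo-C2
domain-orientation analysis consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegeneracyError, PairingError, SelectionError
from .structure_io import CoordinateSet, SelectionSpec, StructureEnsemble, select_atoms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ rotation @ x + translation, angstrom units."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


@dataclass
class EnsembleStats:
    """Per-model RMSD to the iteratively refined mean structure."""

    mean_coords: CoordinateSet
    per_model_rmsd: list[float]
    mean_rmsd: float
    sd_rmsd: float
    converged: bool = True


@dataclass(frozen=True)
class ScrewDecomposition:
    """Axis/angle/pitch form of a rigid transform.

    ``angle`` is in degrees in [0, 180]; ``translation_along_axis`` is the
    pitch component; ``axis_point`` is a point on the screw axis (chosen so
    the residual translation is purely parallel to the axis).
    """

    axis: np.ndarray
    angle: float
    translation_along_axis: float
    axis_point: np.ndarray

    def recompose(self) -> RigidTransform:
        R = Rotation.from_rotvec(np.deg2rad(self.angle) * self.axis).as_matrix()
        p = np.asarray(self.axis_point)
        t = p - R @ p + self.translation_along_axis * np.asarray(self.axis)
        return RigidTransform(R, t)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rotation+translation mapping ``mobile`` onto ``reference``.

    The SVD determinant correction guarantees a proper rotation (no
    reflection) even for near-planar point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cr - R @ cm)


def superpose(mobile: CoordinateSet, reference: CoordinateSet) -> SuperpositionResult:
    """Optimal superposition of ``mobile`` onto ``reference`` (paired atoms)."""
    if len(mobile) != len(reference):
        raise PairingError(
            f"cannot pair {len(mobile)} mobile atoms with {len(reference)} reference atoms"
        )
    if len(mobile) < 3:
        raise DegeneracyError("superposition needs at least 3 paired atoms")
    spread = np.linalg.svd(mobile.coords - mobile.coords.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-9:
        raise DegeneracyError("mobile points are collinear")
    t = kabsch(mobile.coords, reference.coords)
    return SuperpositionResult(
        transform=t,
        rmsd=_rmsd(t.apply(mobile.coords), reference.coords),
        n_atoms=len(mobile),
    )


def ensemble_rmsd_to_mean(
    ensemble: StructureEnsemble,
    spec: SelectionSpec,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> EnsembleStats:
    """RMSD of every model to the converged mean structure of the selection.

    All models are first superposed on model 1, averaged, then re-superposed
    on the running mean until the mean moves less than ``tol`` angstrom
    (or ``max_iter`` iterations, in which case a warning is logged and the
    last iterate is used).
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble statistics need at least 2 models")
    sets = [select_atoms(ensemble, spec, i) for i in range(ensemble.n_models)]
    if any(s.labels != sets[0].labels for s in sets):
        raise SelectionError("selection labels differ between models")
    coords = [s.coords for s in sets]
    mean = coords[0].copy()
    converged = False
    for _ in range(max_iter):
        fitted = [kabsch(c, mean).apply(c) for c in coords]
        new_mean = np.mean(fitted, axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("mean structure did not converge in %d iterations", max_iter)
    per_model = [_rmsd(kabsch(c, mean).apply(c), mean) for c in coords]
    return EnsembleStats(
        mean_coords=CoordinateSet(labels=sets[0].labels, coords=mean),
        per_model_rmsd=per_model,
        mean_rmsd=float(np.mean(per_model)),
        sd_rmsd=float(np.std(per_model, ddof=1)),
        converged=converged,
    )


def screw_decompose(t: RigidTransform) -> ScrewDecomposition:
    """Chasles decomposition of a rigid transform.

    A near-identity rotation (angle < ~1e-7 rad) is treated as a pure
    translation: the axis is set along the translation (or +z when the
    translation also vanishes) and the axis point to the origin.
    """
    rot = Rotation.from_matrix(t.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    tvec = t.translation
    if angle < 1e-7:
        norm = float(np.linalg.norm(tvec))
        axis = tvec / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        return ScrewDecomposition(
            axis=axis,
            angle=float(np.rad2deg(angle)),
            translation_along_axis=norm,
            axis_point=np.zeros(3),
        )
    axis = rotvec / angle
    d = float(tvec @ axis)
    t_perp = tvec - d * axis
    # point p on the axis satisfies (I - R) p = t_perp; (I - R) is singular
    # along the axis, so solve in the least-squares sense
    p, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    return ScrewDecomposition(
        axis=axis,
        angle=float(np.rad2deg(angle)),
        translation_along_axis=d,
        axis_point=p,
    )


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3×3 rotation matrix, degrees in [0, 180]."""
    return float(
        np.rad2deg(np.linalg.norm(Rotation.from_matrix(np.asarray(R)).as_rotvec()))
    )


def angle_between_deg(u: np.ndarray, v: np.ndarray, fold: bool = False) -> float:
    """Angle between two vectors in degrees; ``fold`` maps into [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))
    ang = float(np.rad2deg(np.arccos(c)))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang
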