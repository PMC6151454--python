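"""Hydrodynamic-size and circular-dichroism calibrations.

DLS: globular proteins obey an approximate power law between hydrodynamic
radius R_H and molecular weight M_r, so a least-squares line in
(log10 R_H, log10 M_r) space over standard proteins converts a measured
R_H into an apparent M_r.  The fit uses all standards jointly (not
piecewise interpolation between the bracketing pair, which for the
standards used here shifts the estimate by about 1 kDa).

CD: the molar CD absorption coefficient at 222 nm tracks α-helical content.
A two-state estimator places the measured Δε(222) between reference
helix and coil values; the defaults (−11.1 and −0.3 M⁻¹cm⁻¹ per residue)
are common literature conventions and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, FormatError

logger = logging.getLogger(__name__)

REF_HELIX_222 = -11.1  # Δε per residue at 222 nm, fully helical
REF_COIL_222 = -0.3  # Δε per residue at 222 nm, random coil


@dataclass(frozen=True)
class CalibrationPoint:
    r_h: float  # nm
    m_r: float  # kDa
    label: str = ""

    def __post_init__(self) -> None:
        if self.r_h <= 0 or self.m_r <= 0:
            raise ValueError("R_H and M_r must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """log10(M_r) = intercept + slope · log10(R_H)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    rh_range: tuple[float, float]


@dataclass
class CDSpectrum:
    wavelengths: np.ndarray  # nm, strictly ascending
    delta_eps: np.ndarray  # M⁻¹ cm⁻¹

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        de = np.asarray(self.delta_eps, dtype=float)
        if wl.shape != de.shape:
            raise ValueError("wavelengths and delta_eps must have equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.wavelengths = wl
        self.delta_eps = de

    def at(self, wavelength: float) -> float:
        """Linearly interpolated Δε at one wavelength (must be inside grid)."""
        if not self.wavelengths[0] <= wavelength <= self.wavelengths[-1]:
            raise ValueError(f"{wavelength} nm outside grid")
        return float(np.interp(wavelength, self.wavelengths, self.delta_eps))


def fit_loglog_calibration(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Ordinary least squares of log10(M_r) on log10(R_H) over all standards."""
    if len(points) < 2:
        raise DegeneracyError("calibration needs at least 2 standards")
    rh = np.array([p.r_h for p in points])
    mr = np.array([p.m_r for p in points])
    if len(points) == 2 and np.isclose(rh[0], rh[1]):
        raise DegeneracyError("two standards with identical R_H cannot define a line")
    res = stats.linregress(np.log10(rh), np.log10(mr))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
        rh_range=(float(rh.min()), float(rh.max())),
    )


def estimate_mr(curve: CalibrationCurve, r_h: float) -> float:
    """Apparent molecular weight (kDa) at hydrodynamic radius ``r_h`` (nm)."""
    if r_h <= 0:
        raise ValueError("R_H must be positive")
    lo, hi = curve.rh_range
    if not lo <= r_h <= hi:
        logger.warning("R_H %.3g nm outside the standards' range [%g, %g]: "
                       "extrapolating", r_h, lo, hi)
    return float(10 ** (curve.intercept + curve.slope * np.log10(r_h)))


def read_standards(path: str | Path) -> list[CalibrationPoint]:
    """CSV with columns label, rh_nm, mr_kda (order-insensitive header)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        return [
            CalibrationPoint(
                r_h=float(row[cols["rh_nm"]]),
                m_r=float(row[cols["mr_kda"]]),
                label=str(row[cols.get("label", cols["rh_nm"])]),
            )
            for _, row in df.iterrows()
        ]
    except KeyError as exc:
        raise FormatError(f"standards file needs rh_nm and mr_kda columns: {exc}") from exc


def read_cd_spectrum(path: str | Path) -> CDSpectrum:
    """CSV with columns wavelength_nm, delta_eps."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "wavelength_nm" not in cols or "delta_eps" not in cols:
        raise FormatError(
            f"spectrum file needs wavelength_nm and delta_eps columns, got {list(df.columns)}"
        )
    df = df.sort_values(cols["wavelength_nm"])
    return CDSpectrum(
        wavelengths=df[cols["wavelength_nm"]].to_numpy(float),
        delta_eps=df[cols["delta_eps"]].to_numpy(float),
    )


def cd_difference(complex_spec: CDSpectrum, free_spec: CDSpectrum) -> CDSpectrum:
    """Pointwise Δε(complex) − Δε(free) on the overlapping wavelength range.

    When the grids differ the free spectrum is linearly interpolated onto
    the complex grid restricted to the overlap.
    """
    lo = max(complex_spec.wavelengths[0], free_spec.wavelengths[0])
    hi = min(complex_spec.wavelengths[-1], free_spec.wavelengths[-1])
    if lo > hi:
        raise ValueError("spectra share no wavelength overlap")
    mask = (complex_spec.wavelengths >= lo) & (complex_spec.wavelengths <= hi)
    wl = complex_spec.wavelengths[mask]
    free_interp = np.interp(wl, free_spec.wavelengths, free_spec.delta_eps)
    return CDSpectrum(wavelengths=wl, delta_eps=complex_spec.delta_eps[mask] - free_interp)


def estimate_helix_fraction(
    spec: CDSpectrum,
    ref_helix_222: float = REF_HELIX_222,
    ref_coil_222: float = REF_COIL_222,
) -> float:
    """Two-state helix fraction from Δε at 222 nm, clamped to [0, 1]."""
    if np.isclose(ref_helix_222, ref_coil_222):
        raise ValueError("helix and coil references must differ")
    value = spec.at(222.0)
    f = (value - ref_coil_222) / (ref_helix_222 - ref_coil_222)
    return float(np.clip(f, 0.0, 1.0))
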