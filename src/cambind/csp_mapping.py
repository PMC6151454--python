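"""Chemical-shift perturbation (CSP) mapping.

The per-residue perturbation combines the amide proton and nitrogen shift
changes between the free and bound states into a single normalized value,

    Δδ_residue = sqrt( ( Δδ_HN² + (Δδ_N / 5)² ) / 2 )            [ppm]

with the ¹⁵N difference down-weighted by a factor of 5 to account for its
wider dispersion.  Residues whose Δδ_residue exceeds a multiple (2× and 3×
by convention) of the mean over all assigned residues mark regions of
structural adjustment upon binding.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

NITROGEN_SCALE = 5.0

# column-name aliases accepted by the tabular reader (case-insensitive)
_RESIDUE_ALIASES = ("residue", "res", "resid", "residue_number", "seq_id")
_NAME_ALIASES = ("res_name", "residue_name", "name", "aa")
_HN_ALIASES = ("hn", "delta_hn", "h", "dhn", "shift_hn", "1h")
_N_ALIASES = ("n", "delta_n", "dn", "shift_n", "15n")


@dataclass
class ShiftTable:
    """Amide ¹H/¹⁵N shifts per residue for one state (free or bound)."""

    data: pd.DataFrame  # columns: residue, res_name, delta_HN, delta_N
    label: Literal["free", "bound"] | str = "free"

    def __post_init__(self) -> None:
        df = self.data
        if df["residue"].duplicated().any():
            dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue numbers: {dupes}")
        if not np.isfinite(df[["delta_HN", "delta_N"]].to_numpy()).all():
            raise ValueError("non-finite chemical shifts")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CSPRecord:
    residue: int
    d_HN: float  # bound − free, ppm
    d_N: float  # bound − free, ppm
    delta_residue: float  # ppm, ≥ 0


@dataclass
class CSPSummary:
    records: list[CSPRecord]
    mean: float
    over_2x: list[int]
    over_3x: list[int]


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_shift_table(
    path: str | Path | io.StringIO, label: str = "free"
) -> ShiftTable:
    """Read a delimited shift table (CSV or TSV) with a header row.

    The header must name a residue-number column and the ¹H and ¹⁵N shift
    columns (several common spellings are accepted).  Rows with missing
    shifts are dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    res_col = _find_column(df.columns, _RESIDUE_ALIASES)
    hn_col = _find_column(df.columns, _HN_ALIASES)
    n_col = _find_column(df.columns, _N_ALIASES)
    if res_col is None or hn_col is None or n_col is None:
        raise FormatError(
            f"cannot identify residue/HN/N columns among {list(df.columns)}"
        )
    name_col = _find_column(df.columns, _NAME_ALIASES)
    out = pd.DataFrame(
        {
            "residue": pd.to_numeric(df[res_col], errors="coerce"),
            "res_name": df[name_col] if name_col is not None else "",
            "delta_HN": pd.to_numeric(df[hn_col], errors="coerce"),
            "delta_N": pd.to_numeric(df[n_col], errors="coerce"),
        }
    )
    bad = out[["residue", "delta_HN", "delta_N"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d row(s) with missing values", int(bad.sum()))
        out = out[~bad]
    out = out.astype({"residue": int}).reset_index(drop=True)
    return ShiftTable(data=out, label=label)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def compute_csp(free: ShiftTable, bound: ShiftTable) -> CSPSummary:
    """Per-residue normalized perturbation over the shared residues.

    The summary mean is taken over every residue present in both tables;
    residues exceeding 2× and 3× that mean are flagged.
    """
    merged = free.data.merge(bound.data, on="residue", suffixes=("_free", "_bound"))
    if merged.empty:
        raise ValueError("free and bound tables share no residue numbers")
    d_hn = merged["delta_HN_bound"] - merged["delta_HN_free"]
    d_n = merged["delta_N_bound"] - merged["delta_N_free"]
    delta = np.sqrt((d_hn**2 + (d_n / NITROGEN_SCALE) ** 2) / 2.0)
    records = [
        CSPRecord(residue=int(r), d_HN=float(h), d_N=float(n), delta_residue=float(d))
        for r, h, n, d in zip(merged["residue"], d_hn, d_n, delta)
    ]
    mean = float(delta.mean())
    return CSPSummary(
        records=records,
        mean=mean,
        over_2x=[rec.residue for rec in records if rec.delta_residue > 2 * mean],
        over_3x=[rec.residue for rec in records if rec.delta_residue > 3 * mean],
    )


def perturbed_regions(
    records: Sequence[CSPRecord],
    multiplier: float,
    bridge_missing: bool = True,
) -> list[tuple[int, int]]:
    """Contiguous residue ranges with Δδ_residue above multiplier × mean.

    A gap of exactly one residue that is absent from the records (an
    unassigned residue, e.g. a proline) is bridged when ``bridge_missing``
    is set; a present-but-below-threshold residue always breaks a region.
    """
    if not records:
        raise ValueError("no CSP records")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    mean = float(np.mean([r.delta_residue for r in records]))
    present = {r.residue for r in records}
    hot = sorted(r.residue for r in records if r.delta_residue > multiplier * mean)
    regions: list[tuple[int, int]] = []
    for res in hot:
        if regions and (
            res == regions[-1][1] + 1
            or (
                bridge_missing
                and res == regions[-1][1] + 2
                and res - 1 not in present
            )
        ):
            regions[-1] = (regions[-1][0], res)
        else:
            regions.append((res, res))
    return regions


def csp_barplot(summary: CSPSummary, ax=None):
    """Bar plot of Δδ_residue vs residue with mean/2×/3× guide lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    residues = [r.residue for r in summary.records]
    values = [r.delta_residue for r in summary.records]
    ax.bar(residues, values, width=0.8, color="0.4")
    for mult, color in ((1, "gold"), (2, "magenta"), (3, "green")):
        ax.axhline(mult * summary.mean, color=color, lw=1,
                   label=f"{mult}× mean" if mult > 1 else "mean")
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta\delta_{residue}$ (ppm)")
    ax.legend(frameon=False, fontsize=8)
    return ax
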