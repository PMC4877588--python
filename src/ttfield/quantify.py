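"""Image-derived statistics for 3D nuclei-centroid tables.

A nuclei table is a :class:`pandas.DataFrame` with one row per detected
nucleus and the columns

    id, t_h, x_um, y_um, z_um, condition, cell_type, <marker flags as 0/1>

(the IMARIS-export style centroid CSV).  From such tables this module
computes the study's readouts:

* aggregate centroid and 3D dispersion Δ (RMS distance of nuclei from
  the centroid), and the normalized dispersion Δ/Δ₀ used to track
  invasive spreading of an aggregate over time;
* proliferation rate, the percentage increase in nucleus count relative
  to the 0 h count;
* cell density per region of interest (cells/mm³) and marker-positivity
  fractions (Ki-67, caspase-3/7, dead-cell dye);
* mean ± SEM summaries and two-tailed unpaired t-tests (pooled-variance
  or Welch) for group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POSITION_COLUMNS",
    "REQUIRED_COLUMNS",
    "ROI",
    "DispersionResult",
    "GroupComparison",
    "load_nuclei_csv",
    "validate_table",
    "aggregate_center",
    "dispersion",
    "normalized_dispersion",
    "proliferation_rate",
    "cell_density",
    "positivity_fraction",
    "summarize",
    "compare_groups",
]

POSITION_COLUMNS = ["x_um", "y_um", "z_um"]
REQUIRED_COLUMNS = ["id", "t_h", "x_um", "y_um", "z_um", "condition", "cell_type"]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned 3D box in μm, the counting volume for density/positivity."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min and self.z_max > self.z_min):
            raise ValueError("ROI must have positive extent on every axis")

    @property
    def volume_mm3(self) -> float:
        """Box volume in mm³ (edges are in μm; 1 mm³ = 1e9 μm³)."""
        return (
            (self.x_max - self.x_min)
            * (self.y_max - self.y_min)
            * (self.z_max - self.z_min)
            / 1e9
        )

    def contains(self, table: pd.DataFrame) -> pd.Series:
        """Boolean mask of nuclei inside the box (half-open on the max side)."""
        x, y, z = (table[c] for c in POSITION_COLUMNS)
        return (
            (x >= self.x_min) & (x < self.x_max)
            & (y >= self.y_min) & (y < self.y_max)
            & (z >= self.z_min) & (z < self.z_max)
        )


@dataclass(frozen=True)
class DispersionResult:
    t_h: float
    center: tuple[float, float, float]
    delta: float
    delta0: float
    normalized: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    df: float
    p: float
    welch: bool


# --------------------------------------------------------------------------
# I/O and validation
# --------------------------------------------------------------------------

def load_nuclei_csv(path: str | Path) -> pd.DataFrame:
    """Read a centroid CSV and validate its schema."""
    table = pd.read_csv(path)
    validate_table(table)
    return table


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nuclei table is missing columns: {missing}")
    if not np.isfinite(table[POSITION_COLUMNS].to_numpy(float)).all():
        raise ValueError("nuclei positions must be finite")
    if (table["t_h"] < 0).any():
        raise ValueError("timepoints must be non-negative")
    for t, group in table.groupby("t_h"):
        if group["id"].duplicated().any():
            raise ValueError(f"duplicate nucleus ids at t={t}")


def _positions(table: pd.DataFrame) -> np.ndarray:
    if len(table) == 0:
        raise ValueError("nuclei table is empty")
    return table[POSITION_COLUMNS].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# dispersion
# --------------------------------------------------------------------------

def aggregate_center(table: pd.DataFrame) -> tuple[float, float, float]:
    """Per-axis arithmetic mean of the nuclei centroids (x̄, ȳ, z̄), μm."""
    pts = _positions(table)
    return tuple(pts.mean(axis=0))


def dispersion(table: pd.DataFrame, *, ddof: int = 0) -> float:
    """3D dispersion Δ of an aggregate, in μm.

    With the default ``ddof=0`` this is the population RMS distance of
    the N nuclei from their centroid,

        Δ = sqrt( (1/N) Σᵢ ‖pᵢ − p̄‖² ).

    ``ddof=1`` divides by N−1 instead (the sum of the per-axis sample
    variances).  The two conventions differ by a constant factor
    sqrt(N/(N−1)) only, which cancels in the normalized dispersion
    Δ/Δ₀ whenever N is in a comparable regime.
    """
    pts = _positions(table)
    n = len(pts)
    if n - ddof <= 0:
        raise ValueError(f"need more than {ddof} nuclei for ddof={ddof}")
    sq = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1)
    return float(np.sqrt(sq.sum() / (n - ddof)))


def normalized_dispersion(
    table: pd.DataFrame, *, t0: float = 0.0, ddof: int = 0
) -> list[DispersionResult]:
    """Δ_t/Δ₀ per timepoint for one aggregate's timecourse table.

    Δ₀ is the dispersion at ``t0``; the result at ``t0`` is exactly 1.
    Raises if no nuclei exist at ``t0`` or the aggregate there is
    degenerate (Δ₀ = 0).
    """
    times = sorted(table["t_h"].unique())
    if t0 not in times:
        raise ValueError(f"no nuclei recorded at t0={t0}")
    ref = table[table["t_h"] == t0]
    delta0 = dispersion(ref, ddof=ddof)
    if delta0 <= 0:
        raise ValueError("degenerate aggregate: dispersion at t0 is zero")
    out = []
    for t in times:
        sub = table[table["t_h"] == t]
        d = dispersion(sub, ddof=ddof)
        out.append(
            DispersionResult(
                t_h=float(t),
                center=aggregate_center(sub),
                delta=d,
                delta0=delta0,
                normalized=1.0 if t == t0 else d / delta0,
                n=len(sub),
            )
        )
    return out


# --------------------------------------------------------------------------
# counts, densities, fractions
# --------------------------------------------------------------------------

def proliferation_rate(n_t: int, n_0: int) -> float:
    """Percentage increase in cell number relative to the 0 h count."""
    if n_0 < 1:
        raise ValueError("baseline count must be at least 1")
    return 100.0 * (n_t - n_0) / n_0


def cell_density(count: int, roi: ROI) -> float:
    """Cell count divided by the ROI volume, in cells/mm³."""
    if count < 0:
        raise ValueError("count must be non-negative")
    volume = roi.volume_mm3
    if volume <= 0:
        raise ValueError("ROI volume must be positive")
    return count / volume


def positivity_fraction(table: pd.DataFrame, marker: str) -> float:
    """Percentage of nuclei whose ``marker`` flag is set."""
    if marker not in table.columns:
        raise KeyError(f"marker column {marker!r} not in table")
    n = len(table)
    if n == 0:
        raise ValueError("nuclei table is empty")
    return 100.0 * float(table[marker].astype(bool).sum()) / n


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def summarize(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, SEM, n) of a sample; SEM uses the n−1 sample SD.

    With n < 2 the SEM is undefined and returned as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return mean, sem, n


def compare_groups(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> GroupComparison:
    """Two-tailed unpaired t-test between two samples.

    ``welch=False`` uses the pooled-variance Student t with
    df = n_a + n_b − 2; ``welch=True`` uses the Welch statistic with
    Satterthwaite degrees of freedom.  Each group needs n ≥ 2.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    mean_a, sem_a, _ = summarize(a)
    mean_b, sem_b, _ = summarize(b)
    return GroupComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        t_stat=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        welch=welch,
    )


def holm_correction(p_values: Iterable[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; raw p is the default
    reporting convention in this pipeline)."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
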