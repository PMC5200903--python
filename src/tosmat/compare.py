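"""Benchmark colocalization metrics: Pearson, Spearman, Manders M1/M2 with
Costes automatic thresholding, and the chance-corrected M1diff/M2diff.

M1diff/M2diff subtract the chance expectations (the fraction of pixels above
the other channel's threshold) from M1/M2.  When Costes' scan cannot
evaluate any candidate threshold the result carries ``thresholding_failed``
and the diff values are NaN; such cells are dropped per-metric downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CellPixels, tos_matrix
from .errors import UndefinedCoefficientError, UndefinedCorrelationError

__all__ = [
    "MandersResult",
    "MetricPanel",
    "pearson",
    "spearman",
    "manders",
    "costes_thresholds",
    "manders_costes",
    "compute_panel",
]

#: column order of an exported per-cell metric panel row
PANEL_COLUMNS = (
    "cell_id",
    "tos_h",
    "tos_max",
    "tos_min",
    "pcc",
    "srcc",
    "m1",
    "m2",
    "m1diff",
    "m2diff",
    "costes_failed",
)


@dataclass(frozen=True)
class MandersResult:
    """Intensity-weighted overlap coefficients at one threshold pair."""

    m1: float
    m2: float
    threshold1: float
    threshold2: float
    f_above1: float
    f_above2: float
    thresholding_failed: bool = False

    @property
    def m1diff(self) -> float:
        return math.nan if self.thresholding_failed else self.m1 - self.f_above2

    @property
    def m2diff(self) -> float:
        return math.nan if self.thresholding_failed else self.m2 - self.f_above1


def pearson(cell: CellPixels) -> float:
    """Product-moment correlation of the two channels."""
    s1, s2 = cell.signal1, cell.signal2
    if s1.std() == 0 or s2.std() == 0:
        raise UndefinedCorrelationError("zero variance in at least one channel")
    return float(stats.pearsonr(s1, s2).statistic)

def spearman(cell: CellPixels) -> float:
    """Rank correlation (Pearson correlation of mid-ranks)."""
    s1, s2 = cell.signal1, cell.signal2
    if np.unique(s1).size < 2 or np.unique(s2).size < 2:
        raise UndefinedCorrelationError("zero rank variance in at least one channel")
    return float(stats.spearmanr(s1, s2).statistic)


def manders(cell: CellPixels, t1: float, t2: float) -> MandersResult:
    """Manders M1/M2 at explicit thresholds; "exceed" is strict (>).

    ``m1`` is the summed signal-1 intensity of pixels jointly above both
    thresholds, over the summed signal-1 intensity of pixels above ``t1``
    (``m2`` symmetric).
    """
    s1, s2 = cell.signal1, cell.signal2
    above1 = s1 > t1
    above2 = s2 > t2
    joint = above1 & above2
    denom1 = s1[above1].sum()
    denom2 = s2[above2].sum()
    if denom1 == 0 or denom2 == 0:
        raise UndefinedCoefficientError(
            "no above-threshold intensity in at least one channel"
        )
    return MandersResult(
        m1=float(s1[joint].sum() / denom1),
        m2=float(s2[joint].sum() / denom2),
        threshold1=float(t1),
        threshold2=float(t2),
        f_above1=float(above1.mean()),
        f_above2=float(above2.mean()),
    )


def costes_thresholds(
    cell: CellPixels, below: str = "both"
) -> tuple[float, float, bool]:
    """Joint threshold pair by Costes' minimum-correlation scan.

    Fits ordinary least squares ``signal2 = a*signal1 + b`` on all pixels,
    then walks candidate thresholds ``t1`` over the distinct signal-1
    intensities from high to low with ``t2 = a*t1 + b``.  Each candidate is
    scored by the Pearson correlation of the below-threshold pixels;
    candidates with fewer than 3 such pixels, or with zero variance among
    them, are skipped.  The pair minimizing the below-threshold correlation
    is returned.

    Parameters
    ----------
    below : {"both", "either"}
        Membership rule for the below-threshold population: strictly below
        both thresholds (default) or below at least one.

    Returns
    -------
    (t1, t2, failed) — ``failed`` is True when the regression is degenerate
    or no candidate is evaluable; no exception is raised in that case.
    """
    s1, s2 = cell.signal1, cell.signal2
    if s1.size < 3 or s1.std() == 0 or s2.std() == 0:
        return math.nan, math.nan, True
    a, b = np.polyfit(s1, s2, 1)
    best: tuple[float, float, float] | None = None  # (corr, t1, t2)
    for t1 in np.unique(s1)[::-1]:
        t2 = a * t1 + b
        if below == "both":
            mask = (s1 < t1) & (s2 < t2)
        else:
            mask = (s1 < t1) | (s2 < t2)
        if mask.sum() < 3:
            continue
        lo1, lo2 = s1[mask], s2[mask]
        sd1, sd2 = lo1.std(), lo2.std()
        if sd1 == 0 or sd2 == 0:
            continue
        # plain-numpy Pearson: the scan visits every distinct intensity and
        # scipy's per-call overhead dominates otherwise
        corr = float(((lo1 - lo1.mean()) * (lo2 - lo2.mean())).mean() / (sd1 * sd2))
        if best is None or corr < best[0]:
            best = (corr, float(t1), float(t2))
    if best is None:
        return math.nan, math.nan, True
    return best[1], best[2], False


def manders_costes(cell: CellPixels, below: str = "both") -> MandersResult:
    """Manders coefficients at Costes-selected thresholds."""
    t1, t2, failed = costes_thresholds(cell, below=below)
    if failed:
        return MandersResult(
            m1=math.nan,
            m2=math.nan,
            threshold1=math.nan,
            threshold2=math.nan,
            f_above1=math.nan,
            f_above2=math.nan,
            thresholding_failed=True,
        )
    try:
        return manders(cell, t1, t2)
    except UndefinedCoefficientError:
        return MandersResult(
            m1=math.nan,
            m2=math.nan,
            threshold1=t1,
            threshold2=t2,
            f_above1=math.nan,
            f_above2=math.nan,
            thresholding_failed=True,
        )


@dataclass(frozen=True)
class MetricPanel:
    """Per-cell values of every benchmarked metric."""

    cell_id: str
    tos_h: float
    tos_max: float
    tos_min: float
    pcc: float
    srcc: float
    m1: float
    m2: float
    m1diff: float
    m2diff: float
    costes_failed: bool

    def as_row(self) -> dict:
        return {col: getattr(self, col) for col in PANEL_COLUMNS}


def compute_panel(cell: CellPixels) -> MetricPanel:
    """Evaluate the full metric panel on one cell.

    Correlations undefined on degenerate channels are reported as NaN
    rather than raised, mirroring the per-metric exclusion rule.
    """
    matrix = tos_matrix(cell)
    try:
        pcc = pearson(cell)
    except UndefinedCorrelationError:
        pcc = math.nan
    try:
        srcc = spearman(cell)
    except UndefinedCorrelationError:
        srcc = math.nan
    mres = manders_costes(cell)
    return MetricPanel(
        cell_id=cell.cell_id,
        tos_h=matrix.tos_h,
        tos_max=matrix.tos_max,
        tos_min=matrix.tos_min,
        pcc=pcc,
        srcc=srcc,
        m1=mres.m1,
        m2=mres.m2,
        m1diff=mres.m1diff,
        m2diff=mres.m2diff,
        costes_failed=mres.thresholding_failed,
    )
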