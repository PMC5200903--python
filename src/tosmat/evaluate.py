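"""Statistical comparison and ROC construction for metric panels."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "ROCResult",
    "mann_whitney_u",
    "histogram_edges",
    "roc_curve",
    "compare_metrics_roc",
]

#: metrics swept when comparing panels by ROC
ROC_METRICS = (
    "tos_h",
    "tos_max",
    "tos_min",
    "pcc",
    "srcc",
    "m1",
    "m2",
    "m1diff",
    "m2diff",
)

EXACT_MAX_COMBINED_N = 16


def mann_whitney_u(values_a, values_b) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Uses exact enumeration when the combined sample size is <= 16 and the
    data are tie-free, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= EXACT_MAX_COMBINED_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _scott_width(values: np.ndarray) -> float:
    # h = 3.49 * sigma * n^(-1/3)
    return 3.49 * values.std(ddof=1) * values.size ** (-1.0 / 3.0)


def histogram_edges(
    values,
    mode: str = "scott_sim",
    low: float = -1.2,
    high: float = 1.2,
) -> np.ndarray:
    """Bin edges over [low, high] for histogramming / ROC thresholds.

    ``scott_sim``: Scott's-rule width fitted to the data, covering the full
    range with equal bins (a single bin when the data have no spread).
    ``experimental_coarse`` / ``experimental_fine``: fixed 0.1 / 0.001
    increments regardless of the data.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("values must be nonempty")
    if mode == "scott_sim":
        spread = values.std(ddof=1) if values.size > 1 else 0.0
        # repeated values: fall back to a single bin rather than a
        # vanishing Scott width
        if spread <= 1e-9 * max(1.0, np.abs(values).max()):
            return np.array([low, high])
        h = _scott_width(values)
        n_bins = max(1, int(np.ceil((high - low) / h)))
        return np.linspace(low, high, n_bins + 1)
    if mode == "experimental_coarse":
        step = 0.1
    elif mode == "experimental_fine":
        step = 0.001
    else:
        raise InvalidInputError(f"unknown edge mode {mode!r}")
    n_bins = int(round((high - low) / step))
    return np.linspace(low, high, n_bins + 1)


@dataclass(frozen=True)
class ROCResult:
    """ROC curve for one metric over two cell populations."""

    metric_name: str
    thresholds: np.ndarray  # descending sweep
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0


def roc_curve(pos_values, neg_values, edges, metric_name: str = "metric") -> ROCResult:
    """ROC from a high-to-low threshold sweep over ``edges``.

    At each threshold the true/false positive rate is the fraction of the
    condition-positive/-negative values strictly above it.  Implicit (0,0)
    and (1,1) endpoints are appended and the AUC is the trapezoidal
    integral of TPR over FPR.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both populations must be nonempty")
    thresholds = np.sort(np.asarray(edges, dtype=float))[::-1]
    tpr = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] > thresholds[:, None]).mean(axis=1)
    fpr_full = np.concatenate([[0.0], fpr, [1.0]])
    tpr_full = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_full, fpr_full))
    return ROCResult(
        metric_name=metric_name,
        thresholds=thresholds,
        fpr=fpr_full,
        tpr=tpr_full,
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def compare_metrics_roc(
    panels_pos,
    panels_neg,
    metrics: tuple[str, ...] = ROC_METRICS,
    edge_mode: str = "scott_sim",
) -> dict[str, ROCResult]:
    """One ROC per metric from condition-positive/-negative metric panels.

    Cells with an undefined value (NaN) for a given metric are excluded for
    that metric only; the exclusion count is carried on the result.  A
    metric undefined for every cell is skipped with a warning.
    """
    out: dict[str, ROCResult] = {}
    for name in metrics:
        pos = np.array([getattr(p, name) for p in panels_pos], dtype=float)
        neg = np.array([getattr(p, name) for p in panels_neg], dtype=float)
        n_excluded = int(np.isnan(pos).sum() + np.isnan(neg).sum())
        pos = pos[~np.isnan(pos)]
        neg = neg[~np.isnan(neg)]
        if pos.size == 0 or neg.size == 0:
            warnings.warn(f"metric {name!r} undefined for all cells; skipped")
            continue
        edges = histogram_edges(np.concatenate([pos, neg]), mode=edge_mode)
        res = roc_curve(pos, neg, edges, metric_name=name)
        out[name] = ROCResult(
            metric_name=name,
            thresholds=res.thresholds,
            fpr=res.fpr,
            tpr=res.tpr,
            auc=res.auc,
            n_pos=res.n_pos,
            n_neg=res.n_neg,
            n_excluded=n_excluded,
        )
    return out
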