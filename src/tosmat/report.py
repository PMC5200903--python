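"""Cohort aggregation and figure/table export."""

from __future__ import annotations

import json
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .compare import PANEL_COLUMNS, MetricPanel
from .core import TOSMatrix
from .errors import InvalidInputError
from .evaluate import ROCResult

__all__ = [
    "CohortSummary",
    "aggregate_cohort",
    "panels_to_frame",
    "write_matrix_heatmap",
    "write_roc_results",
]

_PERCENTILE_METRICS = (
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


@dataclass(frozen=True)
class CohortSummary:
    """Element-wise median matrix plus per-metric percentile triples."""

    n_cells: int
    fractions: tuple[float, ...]
    median_matrix: np.ndarray
    percentiles: dict  # metric -> {"p10": ..., "median": ..., "p90": ...}

    def to_json(self, path=None) -> str:
        payload = {
            "n_cells": self.n_cells,
            "fractions": list(self.fractions),
            "median_matrix": self.median_matrix.tolist(),
            "percentiles": self.percentiles,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def aggregate_cohort(
    matrices: list[TOSMatrix], panels: list[MetricPanel] | None = None
) -> CohortSummary:
    """Combine per-cell matrices/panels into cohort medians and percentiles.

    Percentiles use the linear-interpolation definition (numpy default).
    NaN metric values (per-metric exclusions) are ignored in the triples.
    """
    if not matrices:
        raise InvalidInputError("cohort must contain at least one cell")
    fractions = matrices[0].fractions
    for m in matrices[1:]:
        if m.fractions != fractions:
            raise InvalidInputError("all matrices must share the fraction grid")
    stack = np.stack([m.values for m in matrices])
    median_matrix = np.median(stack, axis=0)
    percentiles: dict = {}
    if panels:
        for name in _PERCENTILE_METRICS:
            vals = np.array([getattr(p, name) for p in panels], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            p10, med, p90 = np.percentile(vals, [10, 50, 90])
            percentiles[name] = {"p10": float(p10), "median": float(med), "p90": float(p90)}
    return CohortSummary(
        n_cells=len(matrices),
        fractions=fractions,
        median_matrix=median_matrix,
        percentiles=percentiles,
    )


def panels_to_frame(panels: list[MetricPanel]) -> pd.DataFrame:
    """Per-cell metric panel table, one row per cell."""
    return pd.DataFrame([p.as_row() for p in panels], columns=list(PANEL_COLUMNS))


def write_matrix_heatmap(
    values: np.ndarray, fractions, path, title: str = "TOS matrix"
) -> None:
    """Heat-map export with the lowest fraction pair in the upper-right.

    Rows (channel-2 fraction) are flipped so the (0.1, 0.1) element renders
    in the upper-right corner.
    """
    values = np.asarray(values)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        values[::-1, :], vmin=-1, vmax=1, cmap="RdBu_r", interpolation="nearest"
    )
    labels = [f"{f:g}" for f in fractions]
    ax.set_xticks(range(len(labels)), labels)
    ax.set_yticks(range(len(labels)), labels[::-1])
    ax.set_xlabel("selected fraction, signal 1")
    ax.set_ylabel("selected fraction, signal 2")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="TOS")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def matrix_to_csv(values: np.ndarray, fractions, path) -> None:
    """9x9 CSV with fraction headers (rows: signal-2 fraction)."""
    with open(path, "w") as fh:
        fh.write("f_t2\\f_t1," + ",".join(f"{f:g}" for f in fractions) + "\n")
        for f2, row in zip(fractions, values):
            fh.write(f"{f2:g}," + ",".join(f"{v:.10g}" for v in row) + "\n")


def write_roc_results(results: dict[str, ROCResult], csv_path, json_path) -> None:
    """CSV of (metric, threshold, fpr, tpr) plus a JSON AUC summary."""
    rows = []
    for name, res in results.items():
        # interior points only: endpoints are implicit
        for t, f, tp in zip(res.thresholds, res.fpr[1:-1], res.tpr[1:-1]):
            rows.append({"metric": name, "threshold": t, "fpr": f, "tpr": tp})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    summary = {
        name: {
            "auc": res.auc,
            "n_pos": res.n_pos,
            "n_neg": res.n_neg,
            "n_excluded": res.n_excluded,
        }
        for name, res in results.items()
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
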