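"""Core threshold-overlap-score (TOS) computations.

A cell is a pair of equal-length pixel-intensity vectors.  Thresholds are
parameterized as *selected fractions*: the fraction of a channel's pixels
with the highest intensities that is retained after rank ordering.  The
observed fractional area of overlap (AO) between the two selected pixel
sets is normalized by its expectation under a uniform, independent null
(giving the AO ratio) and then linearly rescaled so the analytic minimum,
null and maximum map to -1, 0 and +1 at every fraction pair (giving TOS).

Evaluating TOS over a 9x9 grid of fraction pairs (0.9 .. 0.1, step 0.1 on
each channel) yields a TOS matrix from which three scalar features are
extracted: the score at the lowest fraction pair (``tos_h``), the grid
maximum (``tos_max``) and the grid minimum (``tos_min``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateCellError,
    IncompatibleSelectionError,
    InvalidFractionError,
)

__all__ = [
    "DEFAULT_FRACTIONS",
    "CellPixels",
    "ThresholdSelection",
    "OverlapResult",
    "TOSMatrix",
    "select_top_fraction",
    "observed_overlap",
    "overlap_result",
    "ao_ratio",
    "ao_ratio_bounds",
    "tos",
    "tos_matrix",
    "classify_localization",
]

#: Selected fractions of the standard grid, highest to lowest so the
#: (0.1, 0.1) cell lands in the heat map's upper-right corner.
DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.9 - 0.1 * i, 1) for i in range(9))


@dataclass(frozen=True)
class CellPixels:
    """Paired pixel-intensity vectors for one cell or organism.

    Parameters
    ----------
    signal1, signal2 : array-like
        Nonnegative, finite intensities; equal length, at least 2 pixels.
    cell_id : str
        Identifier carried through to exported tables.
    """

    signal1: np.ndarray
    signal2: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        s1 = np.asarray(self.signal1, dtype=float)
        s2 = np.asarray(self.signal2, dtype=float)
        if s1.ndim != 1 or s2.ndim != 1:
            raise DegenerateCellError("signals must be 1-D vectors")
        if s1.shape != s2.shape:
            raise DegenerateCellError(
                f"channel lengths differ: {s1.size} vs {s2.size}"
            )
        if s1.size < 2:
            raise DegenerateCellError("a cell needs at least 2 pixels")
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise DegenerateCellError("intensities must be finite")
        if s1.min() < 0 or s2.min() < 0:
            raise DegenerateCellError("intensities must be nonnegative")
        object.__setattr__(self, "signal1", s1)
        object.__setattr__(self, "signal2", s2)

    @property
    def n_pixels(self) -> int:
        return int(self.signal1.size)

    def to_csv(self, path) -> None:
        """Write the cell as a two-column CSV (signal1, signal2)."""
        arr = np.column_stack([self.signal1, self.signal2])
        np.savetxt(path, arr, delimiter=",", header="signal1,signal2", comments="")

    @classmethod
    def from_csv(cls, path, cell_id: str = "cell") -> "CellPixels":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], cell_id=cell_id)


@dataclass(frozen=True)
class ThresholdSelection:
    """The highest-intensity pixel subset of one channel at one fraction."""

    requested_fraction: float
    selected_indices: np.ndarray
    n_total: int
    #: set when every intensity in the channel is identical, so the "top"
    #: pixels are an arbitrary (but deterministic) index-order prefix
    degenerate_channel: bool = False

    @property
    def selected_count(self) -> int:
        return int(self.selected_indices.size)

    @property
    def effective_fraction(self) -> float:
        return self.selected_count / self.n_total


@dataclass(frozen=True)
class OverlapResult:
    """Observed and expected overlap for one fraction pair."""

    ao1: float
    ao2: float
    expected_ao1: float  # = effective F_T2
    expected_ao2: float  # = effective F_T1
    ao_ratio: float
    ao_ratio_min: float
    ao_ratio_max: float


def overlap_result(cell: CellPixels, f_t1: float, f_t2: float) -> OverlapResult:
    """Observed/expected overlap and bounded AO ratio at one fraction pair.

    Expected fractions and bounds are evaluated at the *effective*
    fractions (k/N) so discrete pixel counts and analytic bounds agree
    exactly.
    """
    sel1 = select_top_fraction(cell.signal1, f_t1)
    sel2 = select_top_fraction(cell.signal2, f_t2)
    ao1, ao2 = observed_overlap(sel1, sel2)
    e1, e2 = sel2.effective_fraction, sel1.effective_fraction
    r = ao_ratio(ao1, e1)
    rmin, rmax = ao_ratio_bounds(e2, e1)
    return OverlapResult(
        ao1=ao1,
        ao2=ao2,
        expected_ao1=e1,
        expected_ao2=e2,
        ao_ratio=r,
        ao_ratio_min=rmin,
        ao_ratio_max=rmax,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def selected_count(fraction: float, n: int) -> int:
    """Pixel count retained at ``fraction`` of ``n``: round half away from
    zero, never 0, never all ``n`` pixels."""
    return min(max(1, _round_half_away(fraction * n)), n - 1)


def select_top_fraction(pixels, fraction: float) -> ThresholdSelection:
    """Select the top ``fraction`` of pixels by intensity rank.

    Ties at the selection boundary are broken by ascending pixel index so
    the selection is deterministic across runs and platforms.

    Raises
    ------
    InvalidFractionError
        If ``fraction`` is outside (0, 1).  Fraction 1 is excluded: the
        selections then cover the whole cell, overlap is forced and the
        score is identically 0.
    DegenerateCellError
        If the vector has fewer than 2 pixels.
    """
    arr = np.asarray(pixels, dtype=float)
    if not (0.0 < fraction < 1.0):
        raise InvalidFractionError(f"fraction must be in (0, 1), got {fraction}")
    n = arr.size
    if n < 2:
        raise DegenerateCellError("need at least 2 pixels to threshold")
    k = selected_count(fraction, n)
    # stable sort on -intensity keeps ties in ascending index order
    order = np.argsort(-arr, kind="stable")
    degenerate = bool(arr.max() == arr.min())
    return ThresholdSelection(
        requested_fraction=float(fraction),
        selected_indices=np.sort(order[:k]),
        n_total=n,
        degenerate_channel=degenerate,
    )


def observed_overlap(
    sel1: ThresholdSelection, sel2: ThresholdSelection
) -> tuple[float, float]:
    """Fraction of each selection's pixels present in the other selection.

    Returns ``(ao1, ao2)`` where ``ao1 = |sel1 & sel2| / |sel1|`` and
    ``ao2 = |sel1 & sel2| / |sel2|``.
    """
    if sel1.n_total != sel2.n_total:
        raise IncompatibleSelectionError(
            f"selections come from different cells ({sel1.n_total} vs {sel2.n_total} pixels)"
        )
    overlap = np.intersect1d(
        sel1.selected_indices, sel2.selected_indices, assume_unique=True
    ).size
    return overlap / sel1.selected_count, overlap / sel2.selected_count


def ao_ratio(ao1: float, f_t2: float) -> float:
    """Observed overlap fraction divided by its null expectation.

    The expected AO1 under the uniform independent null equals the selected
    fraction of the *other* channel, so the same ratio is obtained from
    ``ao2 / f_t1``.
    """
    if not (0.0 < f_t2 < 1.0):
        raise InvalidFractionError(f"expected fraction must be in (0, 1), got {f_t2}")
    return ao1 / f_t2


def ao_ratio_bounds(f_t1: float, f_t2: float) -> tuple[float, float]:
    """Analytic (min, max) of the AO ratio at a fraction pair.

    The maximum is reached when the smaller selection is fully contained in
    the larger: ``1 / max(f1, f2)``.  The minimum is 0 when the selections
    can be disjoint (``f1 + f2 <= 1``) and ``(f1 + f2 - 1) / (f1 * f2)``
    otherwise.
    """
    if not (0.0 < f_t1 < 1.0 and 0.0 < f_t2 < 1.0):
        raise InvalidFractionError("fractions must be in (0, 1)")
    rmax = 1.0 / max(f_t1, f_t2)
    s = f_t1 + f_t2
    rmin = 0.0 if s <= 1.0 else (s - 1.0) / (f_t1 * f_t2)
    return rmin, rmax


def tos(ao_ratio_value: float, f_t1: float, f_t2: float) -> float:
    """Rescale an AO ratio to the threshold overlap score in [-1, 1].

    Piecewise-linear map anchored at the analytic minimum (-1), the null
    ratio 1 (0) and the analytic maximum (+1):

    * ``r >= 1`` -> ``(r - 1) / (max - 1)``
    * ``r <  1`` -> ``(r - 1) / (1 - min)``

    Ratios marginally outside the analytic bounds (possible because pixel
    counts are integers while the bounds assume continuous fractions) are
    clamped before rescaling.
    """
    rmin, rmax = ao_ratio_bounds(f_t1, f_t2)
    if rmax == 1.0:  # unreachable for fractions in (0,1), kept as a guard
        raise InvalidFractionError("maximum AO ratio of 1 leaves nothing to rescale")
    r = min(max(ao_ratio_value, rmin), rmax)
    if r >= 1.0:
        return (r - 1.0) / (rmax - 1.0)
    return (r - 1.0) / (1.0 - rmin)


def classify_localization(score: float, band: float = 0.1) -> str:
    """Categorize a score against a non-colocalization band.

    Scores strictly above ``band`` are ``"colocalization"``, strictly below
    ``-band`` are ``"anti-colocalization"``; the closed band (endpoints
    included) is ``"non-colocalization"``.
    """
    if band < 0:
        raise InvalidFractionError("band must be >= 0")
    if score > band:
        return "colocalization"
    if score < -band:
        return "anti-colocalization"
    return "non-colocalization"


@dataclass(frozen=True)
class TOSMatrix:
    """TOS over the fraction grid, plus extracted scalar features.

    ``values[i][j]`` holds the score at ``(F_T1 = fractions[j],
    F_T2 = fractions[i])``; with the default 0.9 -> 0.1 ordering the
    (0.1, 0.1) element sits at ``values[-1][-1]``.
    """

    fractions: tuple[float, ...]
    values: np.ndarray
    cell_id: str = "cell"
    degenerate_channel: bool = False

    @property
    def tos_h(self) -> float:
        """Score at the lowest fraction pair (the highest thresholds)."""
        return float(self.values[-1, -1])

    @property
    def tos_max(self) -> float:
        return float(self.values.max())

    @property
    def tos_min(self) -> float:
        return float(self.values.min())

    def to_csv(self, path) -> None:
        """9x9 CSV with a header row/column of fractions (F_T1 across
        columns, F_T2 down rows)."""
        with open(path, "w") as fh:
            fh.write("f_t2\\f_t1," + ",".join(f"{f:g}" for f in self.fractions) + "\n")
            for i, f2 in enumerate(self.fractions):
                row = ",".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{f2:g},{row}\n")

    def to_json(self, path=None) -> str:
        payload = {
            "cell_id": self.cell_id,
            "fractions": list(self.fractions),
            "values": self.values.tolist(),
            "tos_h": self.tos_h,
            "tos_max": self.tos_max,
            "tos_min": self.tos_min,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def tos_matrix(
    cell: CellPixels, fractions: tuple[float, ...] = DEFAULT_FRACTIONS
) -> TOSMatrix:
    """Compute the TOS matrix of one cell over all fraction pairs.

    The default grid is 9 fractions per channel (81 combinations);
    fraction 1.0 is never part of a grid.
    """
    fractions = tuple(float(f) for f in fractions)
    for f in fractions:
        if not (0.0 < f < 1.0):
            raise InvalidFractionError(f"grid fraction {f} outside (0, 1)")
    n = cell.n_pixels
    rank1 = np.empty(n, dtype=np.intp)
    rank1[np.argsort(-cell.signal1, kind="stable")] = np.arange(n)
    rank2 = np.empty(n, dtype=np.intp)
    rank2[np.argsort(-cell.signal2, kind="stable")] = np.arange(n)

    ks = np.array([selected_count(f, n) for f in fractions])
    sel1 = rank1[None, :] < ks[:, None]  # (9, N) channel-1 membership
    sel2 = rank2[None, :] < ks[:, None]
    # overlap[i, j] = |sel2 at fractions[i]  &  sel1 at fractions[j]|
    overlap = sel2.astype(np.float64) @ sel1.astype(np.float64).T

    eff = ks / n
    values = np.empty((len(fractions), len(fractions)))
    for i, _ in enumerate(fractions):  # rows: F_T2
        for j, _ in enumerate(fractions):  # cols: F_T1
            r = (overlap[i, j] / ks[j]) / eff[i]
            values[i, j] = tos(r, eff[j], eff[i])
    degenerate = bool(
        cell.signal1.max() == cell.signal1.min()
        or cell.signal2.max() == cell.signal2.min()
    )
    return TOSMatrix(
        fractions=fractions,
        values=values,
        cell_id=cell.cell_id,
        degenerate_channel=degenerate,
    )
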