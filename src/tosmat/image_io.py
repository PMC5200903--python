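"""Per-cell pixel extraction from two-channel images.

Cell boundaries are *given* (hand-drawn ImageJ ROIs or an integer count
mask) — this module never segments.  Each labeled object becomes one
:class:`~tosmat.core.CellPixels` with the pixels of both channels in
row-major order, after size filtering and an optional background check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .core import CellPixels
from .errors import ImageFormatError
from .ijroi import PolygonROI, read_roi, read_roi_zip

__all__ = [
    "CountMask",
    "ObjectFilterConfig",
    "read_channel_image",
    "load_rois",
    "rois_to_count_mask",
    "read_count_mask",
    "extract_cells",
]


@dataclass(frozen=True)
class CountMask:
    """Integer-labeled image: 0 = background, k > 0 = object k."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ImageFormatError("count mask must be 2-D")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ImageFormatError("count mask must hold integer labels")
        if grid.min() < 0:
            raise ImageFormatError("labels must be nonnegative")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def labels(self) -> np.ndarray:
        values = np.unique(self.grid)
        return values[values > 0]


@dataclass(frozen=True)
class ObjectFilterConfig:
    """Object-level filters applied during extraction."""

    min_pixels: int = 400
    max_pixels: int = 5000
    background_check: bool = False
    #: optional floor on distinct intensities per channel; cells whose data
    #: were quantized/binned below it are dropped (default off)
    min_distinct_intensities: int = 0

    def __post_init__(self) -> None:
        if self.min_pixels >= self.max_pixels:
            raise ImageFormatError("min_pixels must be < max_pixels")


def read_channel_image(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as a nonnegative float grid."""
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises a zoo of types
        raise ImageFormatError(f"unreadable TIFF: {path}") from exc
    if arr.ndim != 2:
        raise ImageFormatError(
            f"expected a single-plane grayscale image, got shape {arr.shape}: {path}"
        )
    out = arr.astype(float)
    if not np.all(np.isfinite(out)) or out.min() < 0:
        raise ImageFormatError(f"image has negative or non-finite values: {path}")
    return out


def load_rois(path) -> list[PolygonROI]:
    """Load ROIs from a .roi file or a .zip ROI set."""
    path = Path(path)
    if path.suffix.lower() == ".zip":
        return read_roi_zip(path)
    return [read_roi(path)]


def _points_in_polygon(xs, ys, px, py) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over
    query points."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(xs)
    j = n - 1
    for i in range(n):
        xi, yi, xj, yj = xs[i], ys[i], xs[j], ys[j]
        crosses = (yi > py) != (yj > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = xi + (py - yi) * (xj - xi) / (yj - yi)
        inside ^= crosses & (px < x_at)
        j = i
    return inside


def rasterize_polygon(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels whose centers fall inside the polygon.

    Coordinates are 0-based with vertices on the pixel-corner lattice;
    pixel (r, c) has its center at (x, y) = (c + 0.5, r + 0.5); fill rule
    is even-odd.
    """
    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
    return _points_in_polygon(
        np.asarray(roi.x, dtype=float), np.asarray(roi.y, dtype=float), cc, rr
    )


def rois_to_count_mask(
    rois: list[PolygonROI], shape: tuple[int, int], invert: bool = False
) -> CountMask:
    """Rasterize polygons to a count mask with labels 1..n in input order.

    Overlapping polygons: the later one wins.  Empty polygons (no pixel
    center inside) are skipped with a warning.  With ``invert=True`` the
    polygons are taken to outline *background* (boundaries drawn around the
    space between cells): the complement of their union is split into
    connected components, which become the labeled objects.
    """
    grid = np.zeros(shape, dtype=np.int32)
    union = np.zeros(shape, dtype=bool)
    label = 0
    for roi in rois:
        mask = rasterize_polygon(roi, shape)
        if not mask.any():
            warnings.warn(f"ROI {roi.name!r} rasterizes to zero pixels; skipped")
            continue
        union |= mask
        label += 1
        grid[mask] = label
    if invert:
        inverted, _ = ndimage.label(~union)
        return CountMask(grid=inverted.astype(np.int32))
    return CountMask(grid=grid)


def read_count_mask(path) -> CountMask:
    """Read an integer label-TIFF count mask."""
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"count-mask file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ImageFormatError(f"unreadable TIFF: {path}") from exc
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise ImageFormatError(f"count mask must be a 2-D integer image: {path}")
    return CountMask(grid=arr.astype(np.int32))


def extract_cells(
    mask: CountMask,
    channel1: np.ndarray,
    channel2: np.ndarray,
    filters: ObjectFilterConfig | None = None,
    cell_prefix: str = "cell",
) -> list[CellPixels]:
    """One CellPixels per surviving mask label.

    Labels outside ``[min_pixels, max_pixels]`` are removed.  When
    ``background_check`` is on, a label is also removed if its mean
    intensity in *both* channels is at or below the mean of the unlabeled
    (background) pixels of the corresponding channel.  Pixels are emitted
    in row-major order.
    """
    if filters is None:
        filters = ObjectFilterConfig()
    ch1 = np.asarray(channel1, dtype=float)
    ch2 = np.asarray(channel2, dtype=float)
    if ch1.shape != mask.shape or ch2.shape != mask.shape:
        raise ImageFormatError(
            f"channel shapes {ch1.shape}/{ch2.shape} do not match mask {mask.shape}"
        )
    background = mask.grid == 0
    if filters.background_check and background.any():
        bg1 = ch1[background].mean()
        bg2 = ch2[background].mean()
    else:
        bg1 = bg2 = -np.inf

    cells: list[CellPixels] = []
    for label in mask.labels:
        inside = mask.grid == label  # row-major ordering via boolean indexing
        n = int(inside.sum())
        if n < filters.min_pixels or n > filters.max_pixels:
            continue
        s1, s2 = ch1[inside], ch2[inside]
        if filters.background_check and s1.mean() <= bg1 and s2.mean() <= bg2:
            continue
        if filters.min_distinct_intensities > 0 and (
            np.unique(s1).size < filters.min_distinct_intensities
            or np.unique(s2).size < filters.min_distinct_intensities
        ):
            continue
        cells.append(CellPixels(s1, s2, cell_id=f"{cell_prefix}-{int(label)}"))
    if not cells:
        warnings.warn("no objects survived the filters")
    return cells
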