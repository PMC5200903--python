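"""Minimal ImageJ ROI (.roi / .zip) reader and writer.

Only the polygon-family sub-types produced by hand tracing are supported:
polygon (0), rectangle (1), freehand (7) and traced (8).  Coordinates are
stored big-endian; vertex positions are 16-bit offsets relative to the
bounding box.  The writer emits the same dialect so fixtures can be
generated programmatically in tests.
"""

from __future__ import annotations

import io
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ImageFormatError

__all__ = ["PolygonROI", "read_roi", "read_roi_zip", "write_roi", "write_roi_zip"]

_MAGIC = b"Iout"
_POLYGON_TYPES = {0, 7, 8}  # polygon, freehand, traced
_RECT_TYPE = 1


@dataclass(frozen=True)
class PolygonROI:
    """A closed polygon boundary in (x=column, y=row) corner coordinates."""

    x: np.ndarray
    y: np.ndarray
    name: str = "roi"

    @property
    def n_vertices(self) -> int:
        return int(self.x.size)


def read_roi(source, name: str = "roi") -> PolygonROI:
    """Parse one ImageJ .roi file (path or bytes) into a polygon."""
    if isinstance(source, (str, Path)):
        name = Path(source).stem
        data = Path(source).read_bytes()
    else:
        data = bytes(source)
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ImageFormatError(f"not an ImageJ ROI file: {name}")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    (n_coords,) = struct.unpack(">h", data[16:18])
    if roi_type == _RECT_TYPE:
        x = np.array([left, right, right, left], dtype=float)
        y = np.array([top, top, bottom, bottom], dtype=float)
        return PolygonROI(x=x, y=y, name=name)
    if roi_type not in _POLYGON_TYPES:
        raise ImageFormatError(
            f"unsupported ROI type {roi_type} in {name}; only polygon/rectangle "
            "dialects are handled"
        )
    if n_coords < 1:
        raise ImageFormatError(f"empty polygon in {name}")
    end = 64 + 4 * n_coords
    if len(data) < end:
        raise ImageFormatError(f"truncated coordinate block in {name}")
    rel = np.frombuffer(data[64:end], dtype=">i2").astype(float)
    x = rel[:n_coords] + left
    y = rel[n_coords:] + top
    return PolygonROI(x=x, y=y, name=name)


def read_roi_zip(path) -> list[PolygonROI]:
    """Parse every .roi member of an ImageJ ROI-set zip archive."""
    rois = []
    try:
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if info.filename.lower().endswith(".roi"):
                    rois.append(
                        read_roi(zf.read(info), name=Path(info.filename).stem)
                    )
    except zipfile.BadZipFile as exc:
        raise ImageFormatError(f"not a zip archive: {path}") from exc
    return rois


def write_roi(roi: PolygonROI) -> bytes:
    """Serialize a polygon to ImageJ .roi bytes (polygon sub-type)."""
    x = np.asarray(roi.x)
    y = np.asarray(roi.y)
    left, top = int(np.floor(x.min())), int(np.floor(y.min()))
    right, bottom = int(np.ceil(x.max())), int(np.ceil(y.max()))
    header = bytearray(64)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = 0  # polygon
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, x.size)
    rel = np.concatenate([np.round(x - left), np.round(y - top)])
    body = rel.astype(">i2").tobytes()  # concatenate would drop the byte order
    return bytes(header) + body


def write_roi_zip(path, rois: list[PolygonROI]) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        for i, roi in enumerate(rois):
            zf.writestr(f"{roi.name or i}.roi", write_roi(roi))
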