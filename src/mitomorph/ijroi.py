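"""Minimal reader/writer for the ImageJ ROI binary format.

Supports the trace types produced by manual contouring in ImageJ — polygon,
freehand, traced (closed contours) and polyline/freeline (open traces) — which
is what membrane/region annotation workflows emit.  Point, line, oval and
rectangle ROIs are rejected with an explicit error.

The on-disk header is big-endian; vertex coordinates are stored as int16
offsets relative to the ROI bounding box, so coordinates written through this
module are rounded to integer pixels (sub-pixel float coordinates are read
when the file carries them).  ROI names are taken from the zip entry name /
file stem, which is where ImageJ's own ``RoiSet.zip`` archives keep them.
"""

from __future__ import annotations

import io
import struct
import zipfile
from pathlib import Path

import numpy as np

__all__ = ["RoiRecord", "read_roi_bytes", "read_roi_archive", "write_roi_bytes", "write_roi_archive"]

_MAGIC = b"Iout"
_VERSION = 227

# ROI type codes
POLYGON, RECT, OVAL, LINE, FREELINE, POLYLINE, NO_ROI, FREEHAND, TRACED, ANGLE, POINT = range(11)

_CLOSED_TYPES = {POLYGON, FREEHAND, TRACED}
_OPEN_TYPES = {FREELINE, POLYLINE}
_SUPPORTED = _CLOSED_TYPES | _OPEN_TYPES

_TYPE_NAMES = {
    POLYGON: "polygon", RECT: "rectangle", OVAL: "oval", LINE: "line",
    FREELINE: "freeline", POLYLINE: "polyline", NO_ROI: "no-roi",
    FREEHAND: "freehand", TRACED: "traced", ANGLE: "angle", POINT: "point",
}

_SUB_PIXEL_RESOLUTION = 128


class RoiFormatError(ValueError):
    pass


class RoiRecord:
    """One decoded ROI: a name, a vertex array and an open/closed flag."""

    def __init__(self, name: str, coords: np.ndarray, closed: bool):
        self.name = name
        self.coords = np.asarray(coords, dtype=float)
        self.closed = closed

    def __repr__(self) -> str:  # pragma: no cover
        kind = "closed" if self.closed else "open"
        return f"RoiRecord({self.name!r}, {len(self.coords)} pts, {kind})"


def read_roi_bytes(data: bytes, name: str) -> RoiRecord:
    if len(data) < 64 or data[:4] != _MAGIC:
        raise RoiFormatError(f"ROI {name!r}: not an ImageJ ROI stream")
    version, roi_type = struct.unpack(">h", data[4:6])[0], data[6]
    top, left, bottom, right, n = struct.unpack(">5h", data[8:18])
    options = struct.unpack(">h", data[50:52])[0]
    if roi_type not in _SUPPORTED:
        raise RoiFormatError(
            f"ROI {name!r}: unsupported type "
            f"{_TYPE_NAMES.get(roi_type, roi_type)!r}; only polygon/freehand/"
            "traced/polyline/freeline traces are accepted"
        )
    if n < 2:
        raise RoiFormatError(f"ROI {name!r}: fewer than 2 vertices")
    base = 64
    if options & _SUB_PIXEL_RESOLUTION and version >= 222:
        off = base + 4 * n
        xs = np.frombuffer(data, ">f4", count=n, offset=off)
        ys = np.frombuffer(data, ">f4", count=n, offset=off + 4 * n)
        coords = np.column_stack([xs, ys]).astype(float)
    else:
        xs = np.frombuffer(data, ">i2", count=n, offset=base)
        ys = np.frombuffer(data, ">i2", count=n, offset=base + 2 * n)
        coords = np.column_stack([xs + left, ys + top]).astype(float)
    return RoiRecord(name, coords, closed=roi_type in _CLOSED_TYPES)


def write_roi_bytes(coords: np.ndarray, closed: bool) -> bytes:
    coords = np.asarray(coords, dtype=float)
    xi = np.round(coords[:, 0]).astype(np.int64)
    yi = np.round(coords[:, 1]).astype(np.int64)
    left, top = int(xi.min()), int(yi.min())
    right, bottom = int(xi.max()), int(yi.max())
    n = len(coords)
    roi_type = POLYGON if closed else POLYLINE
    buf = io.BytesIO()
    buf.write(_MAGIC)
    buf.write(struct.pack(">h", _VERSION))
    buf.write(struct.pack(">bb", roi_type, 0))
    buf.write(struct.pack(">5h", top, left, bottom, right, n))
    buf.write(b"\x00" * (64 - buf.tell()))
    buf.write((xi - left).astype(">i2").tobytes())
    buf.write((yi - top).astype(">i2").tobytes())
    return buf.getvalue()


def read_roi_archive(path: str | Path) -> list[RoiRecord]:
    """Read a single ``.roi`` file or an ImageJ ``.zip`` ROI archive."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return [read_roi_bytes(path.read_bytes(), path.stem)]
    rois: list[RoiRecord] = []
    with zipfile.ZipFile(path) as zf:
        for entry in zf.namelist():
            if not entry.lower().endswith(".roi"):
                continue
            rois.append(read_roi_bytes(zf.read(entry), Path(entry).stem))
    if not rois:
        raise RoiFormatError(f"no ROIs found in {path}")
    return rois


def write_roi_archive(path: str | Path, rois: list[RoiRecord]) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in rois:
            zf.writestr(f"{roi.name}.roi", write_roi_bytes(roi.coords, roi.closed))
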