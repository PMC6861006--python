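"""File formats: calibrated TIFF stacks, ImageJ ROIs, trace/event CSV.

Stacks travel as multi-page TIFF with a JSON metadata sidecar carrying the
per-frame timestamps and pixel size.  ROIs use the ImageJ binary ``.roi``
format (and ``.zip`` bundles of them) so selections can be exchanged with
ImageJ/Fiji directly; the codec here covers the shape types the pipeline
uses — ovals, rectangles, polygons and polylines.
"""

from __future__ import annotations

import json
import struct
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .frap import FrapTrace, NormalizedFrapTrace
from .stacks import CircleRoi, ImageStack, PolygonRoi

__all__ = [
    "write_stack",
    "read_stack",
    "write_imagej_roi",
    "read_imagej_roi",
    "write_roi_zip",
    "read_roi_zip",
    "frap_traces_to_csv",
    "frap_traces_from_csv",
    "normalized_traces_to_csv",
    "events_to_csv",
]

# ---------------------------------------------------------------- stacks


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-page TIFF plus a ``<name>.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "timestamps_s": stack.timestamps.tolist(),
                "pixel_size_um": stack.pixel_size,
            }
        )
    )
    return path


def read_stack(path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise InvalidInputError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    return ImageStack(
        data, np.asarray(meta["timestamps_s"]), float(meta["pixel_size_um"])
    )


# ------------------------------------------------------------ ImageJ ROI
# Binary layout: 64-byte big-endian header starting with "Iout"; byte 6 is
# the shape type; bytes 8-15 the bounding box (top, left, bottom, right);
# bytes 16-17 the coordinate count; polygon/polyline vertices follow the
# header as int16 x-then-y offsets relative to (left, top).

_TYPE_POLYGON = 0
_TYPE_RECT = 1
_TYPE_OVAL = 2
_TYPE_POLYLINE = 5
_VERSION = 227


def write_imagej_roi(roi, path) -> Path:
    """Write a CircleRoi (as oval), PolygonRoi, or (N, 2) polyline array."""
    path = Path(path)
    path.write_bytes(_roi_bytes(roi))
    return path


def _roi_bytes(roi) -> bytes:
    if isinstance(roi, CircleRoi):
        top = int(round(roi.row - roi.radius))
        left = int(round(roi.col - roi.radius))
        bottom = int(round(roi.row + roi.radius))
        right = int(round(roi.col + roi.radius))
        header = _pack_header(_TYPE_OVAL, top, left, bottom, right, 0)
        payload = b""
    else:
        if isinstance(roi, PolygonRoi):
            verts = np.asarray(roi.vertices, float)
            roi_type = _TYPE_POLYGON
        else:
            verts = np.asarray(roi, float)
            if verts.ndim != 2 or verts.shape[1] != 2:
                raise InvalidInputError("polyline must be an (N, 2) array")
            roi_type = _TYPE_POLYLINE
        rows = np.round(verts[:, 0]).astype(int)
        cols = np.round(verts[:, 1]).astype(int)
        top, left = rows.min(), cols.min()
        header = _pack_header(
            roi_type, top, left, rows.max(), cols.max(), len(verts)
        )
        payload = struct.pack(
            f">{len(verts)}h", *(cols - left)
        ) + struct.pack(f">{len(verts)}h", *(rows - top))
    return header + payload


def _pack_header(roi_type, top, left, bottom, right, n_coords):
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n_coords)
    return bytes(header)


def read_imagej_roi(data_or_path):
    """Read one ImageJ ROI; returns CircleRoi, PolygonRoi or an (N, 2)
    polyline array depending on the stored shape type."""
    if isinstance(data_or_path, (str, Path)):
        blob = Path(data_or_path).read_bytes()
    else:
        blob = data_or_path
    if blob[0:4] != b"Iout":
        raise InvalidInputError("not an ImageJ ROI file (bad magic)")
    roi_type = blob[6]
    top, left, bottom, right = struct.unpack_from(">4h", blob, 8)
    (n,) = struct.unpack_from(">h", blob, 16)
    if roi_type == _TYPE_OVAL:
        radius = ((bottom - top) + (right - left)) / 4.0
        return CircleRoi((top + bottom) / 2.0, (left + right) / 2.0, radius)
    if roi_type == _TYPE_RECT:
        verts = ((top, left), (top, right), (bottom, right), (bottom, left))
        return PolygonRoi(verts)
    if roi_type in (_TYPE_POLYGON, _TYPE_POLYLINE):
        xs = struct.unpack_from(f">{n}h", blob, 64)
        ys = struct.unpack_from(f">{n}h", blob, 64 + 2 * n)
        verts = np.column_stack(
            [np.asarray(ys) + top, np.asarray(xs) + left]
        ).astype(float)
        if roi_type == _TYPE_POLYGON:
            return PolygonRoi(tuple(map(tuple, verts)))
        return verts
    raise InvalidInputError(f"unsupported ImageJ ROI type {roi_type}")


def write_roi_zip(named_rois, path) -> Path:
    """Write ``{name: roi}`` as an ImageJ ROI zip bundle."""
    path = Path(path)
    with zipfile.ZipFile(path, "w") as zf:
        for name, roi in named_rois.items():
            zf.writestr(f"{name}.roi", _roi_bytes(roi))
    return path


def read_roi_zip(path) -> dict:
    """Read an ImageJ ROI zip into ``{name: roi}``."""
    out = {}
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            if info.filename.lower().endswith(".roi"):
                out[Path(info.filename).stem] = read_imagej_roi(zf.read(info))
    return out


# ------------------------------------------------------------------ CSV


def frap_traces_to_csv(traces, path) -> Path:
    """Long-format raw trace CSV: frame, time_s, trace_id, bleach_index,
    bouton, cell_reference, background."""
    rows = []
    for tr in traces:
        for f, t in enumerate(tr.timestamps):
            rows.append(
                {
                    "frame": f,
                    "time_s": t,
                    "trace_id": tr.trace_id,
                    "bleach_index": tr.bleach_index,
                    "bouton": tr.bouton_raw[f],
                    "cell_reference": tr.cell_reference_raw[f],
                    "background": tr.background_raw[f],
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def frap_traces_from_csv(path) -> list:
    df = pd.read_csv(path)
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        traces.append(
            FrapTrace(
                timestamps=g["time_s"].to_numpy(),
                bouton_raw=g["bouton"].to_numpy(),
                cell_reference_raw=g["cell_reference"].to_numpy(),
                background_raw=g["background"].to_numpy(),
                bleach_index=int(g["bleach_index"].iloc[0]),
                trace_id=str(tid),
            )
        )
    return traces


def normalized_traces_to_csv(traces, path) -> Path:
    """Normalized trace CSV: frame, time_s (since bleach), trace_id, value,
    qc_pass."""
    rows = []
    for tr in traces:
        for f, (t, v) in enumerate(zip(tr.timestamps_post, tr.values)):
            rows.append(
                {
                    "frame": f,
                    "time_s": t,
                    "trace_id": tr.trace_id,
                    "value": v,
                    "qc_pass": tr.qc_pass,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def events_to_csv(events, path) -> Path:
    """Detected mini events as CSV: onset_s, amplitude_pA, score."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "onset_s": e.onset_time,
                "amplitude_pA": e.peak_amplitude,
                "score": e.detection_score,
            }
            for e in events
        ]
    ).to_csv(path, index=False)
    return path


def read_current_csv(path, sampling_rate: float | None = None):
    """Read a (time_s, current_pA) CSV into a CurrentTrace."""
    from .minis import CurrentTrace

    df = pd.read_csv(path)
    if sampling_rate is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        sampling_rate = 1.0 / dt
    return CurrentTrace(df["current_pA"].to_numpy(), sampling_rate)
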