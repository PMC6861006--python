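"""Axonal transport quantification from time-lapse stacks.

Builds distance-time kymographs along an axon polyline, traces moving
puncta as tracks and extracts their speeds, and computes the cumulative
cross-section traffic statistic: per-frame integrated density across a
line drawn perpendicular to the axon, background-subtracted, normalized
by the mean of the 10 lowest frames, and summed over the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy import signal

from .errors import (
    DegenerateNormalizationError,
    InvalidInputError,
    InvalidTrackError,
)
from .stacks import ImageStack

__all__ = [
    "Kymograph",
    "Track",
    "TrafficMeasure",
    "build_kymograph",
    "track_speed",
    "detect_tracks",
    "cumulative_traffic",
]


@dataclass
class Kymograph:
    """Distance-time map: rows are frames, columns positions along the path."""

    data: np.ndarray  # (time, path position)
    pixel_size: float  # µm per path step
    frame_interval: float  # s
    path: np.ndarray  # source polyline, (N, 2) (row, col)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[1]


@dataclass
class Track:
    """Traced motion of one punctum on a kymograph.

    ``points`` is an ordered array of (time s, path position µm) vertices.
    """

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or len(self.points) < 2:
            raise InvalidTrackError("a track needs at least 2 (time, position) points")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise InvalidTrackError("track times must be strictly increasing")

    @property
    def mean_speed(self) -> float:
        return track_speed(self)

    @property
    def signed_velocity(self) -> float:
        """Least-squares slope of position vs time (µm/s); sign is the
        direction along the path-vertex order."""
        t, x = self.points[:, 0], self.points[:, 1]
        return float(np.polyfit(t, x, 1)[0])


@dataclass
class TrafficMeasure:
    """Normalized per-frame cross-section density and its cumulative sum."""

    per_frame_normalized: np.ndarray
    cumulative: float
    line_roi: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _resample_polyline(path, step=1.0):
    p = np.asarray(path, float)
    if p.ndim != 2 or len(p) < 2:
        raise InvalidInputError("path needs at least 2 vertices")
    seg = np.diff(p, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if seglen.sum() <= 0:
        raise InvalidInputError("path length must be > 0")
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    si = np.arange(0.0, s[-1] + step / 2, step)
    return np.column_stack([np.interp(si, s, p[:, 0]), np.interp(si, s, p[:, 1])])


def build_kymograph(
    stack: ImageStack, path, width_px: int = 3, reduce: str = "max"
) -> Kymograph:
    """Sample the stack along ``path`` for every frame.

    The polyline is resampled at 1-pixel arc-length steps; at each step
    the intensity is reduced over a ``width_px``-wide segment normal to
    the path (``max`` by default — preserves dim puncta next to saturated
    boutons — or ``mean``), sampled by bilinear interpolation.
    """
    if width_px < 1:
        raise InvalidInputError("width_px must be >= 1")
    pts = _resample_polyline(path, step=1.0)
    h, w = stack.frame_shape
    if (
        pts[:, 0].min() < 0 or pts[:, 1].min() < 0
        or pts[:, 0].max() > h - 1 or pts[:, 1].max() > w - 1
    ):
        raise InvalidInputError("path leaves the frame")
    # unit normals from local tangents
    tang = np.gradient(pts, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    norm /= np.maximum(np.hypot(norm[:, 0], norm[:, 1])[:, None], 1e-12)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    rows = pts[:, 0][None, :] + offsets[:, None] * norm[:, 0][None, :]
    cols = pts[:, 1][None, :] + offsets[:, None] * norm[:, 1][None, :]
    coords = np.stack([rows, cols])  # (2, width, n_pos)
    data = np.empty((stack.n_frames, pts.shape[0]), dtype=np.float32)
    for k, frame in enumerate(stack.data):
        band = ndi.map_coordinates(frame, coords.reshape(2, -1), order=1, mode="nearest")
        band = band.reshape(len(offsets), -1)
        data[k] = band.max(axis=0) if reduce == "max" else band.mean(axis=0)
    dt = float(np.median(np.diff(stack.timestamps))) if stack.n_frames > 1 else 1.0
    return Kymograph(
        data=data, pixel_size=stack.pixel_size, frame_interval=dt, path=pts
    )


def track_speed(track: Track) -> float:
    """Segmental mean speed in µm/s: mean over consecutive vertex pairs of
    |Δposition| / Δtime (pauses count as zero-speed segments)."""
    t = track.points[:, 0]
    x = track.points[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidTrackError("zero or negative time step in track")
    return float(np.mean(np.abs(np.diff(x)) / dt))


def _subpixel_peak(row, i):
    """Parabolic refinement of a discrete peak position."""
    if 0 < i < len(row) - 1:
        a, b, c = row[i - 1], row[i], row[i + 1]
        denom = a - 2 * b + c
        if denom != 0:
            return i + 0.5 * (a - c) / denom
    return float(i)


def detect_tracks(
    kymo: Kymograph,
    min_frames: int = 5,
    max_speed: float = 3.0,
    rel_threshold: float = 0.3,
    max_gap: int = 2,
    exclude_static: bool = True,
    static_speed: float = 0.05,
) -> list[Track]:
    """Automated punctum tracing on a kymograph.

    Per frame (row), local maxima above ``rel_threshold`` times the
    kymograph maximum are detected and refined to sub-pixel position;
    peaks are linked across rows by nearest-neighbour association within
    the displacement a punctum moving at ``max_speed`` µm/s could make
    (bridging up to ``max_gap`` missing rows).  Tracks spanning fewer than
    ``min_frames`` rows are dropped; near-stationary ridges (boutons) are
    dropped when ``exclude_static``.
    """
    if kymo.data.size == 0:
        return []
    peak_floor = rel_threshold * float(kymo.data.max())
    if peak_floor <= 0:
        return []
    max_jump = max_speed * kymo.frame_interval / kymo.pixel_size  # px per frame
    active = []  # each: {"rows": [...], "cols": [...], "last_row": int}
    done = []
    for r in range(kymo.n_frames):
        row = kymo.data[r]
        idx, _ = signal.find_peaks(row, height=peak_floor)
        cols = [_subpixel_peak(row, i) for i in idx]
        used = set()
        for tr in active:
            gap = r - tr["rows"][-1]
            best, best_d = None, None
            for j, c in enumerate(cols):
                if j in used:
                    continue
                d = abs(c - tr["cols"][-1])
                if d <= max_jump * gap + 0.5 and (best is None or d < best_d):
                    best, best_d = j, d
            if best is not None:
                used.add(best)
                tr["rows"].append(r)
                tr["cols"].append(cols[best])
        still_active = []
        for tr in active:
            if r - tr["rows"][-1] > max_gap:
                done.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        for j, c in enumerate(cols):
            if j not in used:
                active.append({"rows": [r], "cols": [c]})
    done.extend(active)
    tracks = []
    for tr in done:
        if len(tr["rows"]) < max(2, min_frames):
            continue
        pts = np.column_stack(
            [
                np.asarray(tr["rows"], float) * kymo.frame_interval,
                np.asarray(tr["cols"], float) * kymo.pixel_size,
            ]
        )
        track = Track(points=pts)
        if exclude_static and track.mean_speed < static_speed:
            continue
        tracks.append(track)
    return tracks


def _sample_line(frame, line_pts):
    return ndi.map_coordinates(
        frame, [line_pts[:, 0], line_pts[:, 1]], order=1, mode="nearest"
    )


def cumulative_traffic(
    stack: ImageStack,
    cross_section_line,
    background_roi=None,
    background_value: float | None = None,
    n_lowest: int = 10,
    eps_rel: float = 1e-9,
) -> TrafficMeasure:
    """Cumulative cross-section traffic through a line ROI.

    Per frame: integrated density along the line (bilinear sampling at
    1-pixel steps) minus the per-pixel background times the line length;
    the whole per-frame series is then divided by the mean of its
    ``n_lowest`` lowest values (normalizing fluorescence differences
    between experiments) and summed.  A constant sequence therefore sums
    exactly to the frame count.
    """
    if stack.n_frames <= n_lowest:
        raise InvalidInputError(f"need more than {n_lowest} frames")
    pts = _resample_polyline(cross_section_line, step=1.0)
    h, w = stack.frame_shape
    if (
        pts[:, 0].min() < 0 or pts[:, 1].min() < 0
        or pts[:, 0].max() > h - 1 or pts[:, 1].max() > w - 1
    ):
        raise InvalidInputError("cross-section line leaves the frame")
    if background_value is None and background_roi is not None:
        mask = background_roi.mask(stack.frame_shape)
        bg_per_frame = stack.data[:, mask].mean(axis=1)
    else:
        bg_per_frame = np.full(stack.n_frames, background_value or 0.0)
    dens = np.array(
        [
            _sample_line(frame, pts).sum() - bg * len(pts)
            for frame, bg in zip(stack.data, bg_per_frame)
        ]
    )
    lowest = np.sort(dens)[:n_lowest]
    base = lowest.mean()
    if not base > eps_rel * max(abs(dens).max(), 1.0):
        raise DegenerateNormalizationError(
            "mean of the lowest frames is ~0; cannot normalize traffic"
        )
    normalized = dens / base
    return TrafficMeasure(
        per_frame_normalized=normalized,
        cumulative=float(normalized.sum()),
        line_roi=pts,
    )
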