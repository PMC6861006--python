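"""Synthetic-data generation with known ground truth.

Every downstream stage of the pipeline can be exercised without microscope
or patch-clamp data: this module emulates (i) FRAP experiments on
presynaptic boutons exchanging vesicles with the axonal super-pool —
both at trace level and as rendered image stacks, (ii) time-lapse movies
of fluorescent vesicle clusters moving along an axon, and (iii)
voltage-clamp recordings of miniature postsynaptic currents.  All
generators are pure functions of their configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .errors import InvalidParameterError
from .frap import FrapTrace, NormalizedFrapTrace
from .kinetics import RecoveryModel, recovery_curve
from .minis import CurrentTrace, MiniEvent, biexp_kernel
from .stacks import CircleRoi, ImageStack, RoiSet

__all__ = [
    "AcquisitionSchedule",
    "make_schedule",
    "SimConfig",
    "simulate_frap_trace",
    "simulate_normalized_traces",
    "FieldGeometry",
    "render_frap_stack",
    "MovieConfig",
    "render_axon_timelapse",
    "TransitLog",
    "MiniSimConfig",
    "simulate_mepsc_trace",
    "recovery_curve",
    "RecoveryModel",
]


# ------------------------------------------------------------- schedules


@dataclass(frozen=True)
class AcquisitionSchedule:
    """FRAP sampling protocol.

    ``baseline_times`` end at ``bleach_time``; the frame acquired at the
    bleach time is the immediately-post-bleach frame (the bleach pulse
    fires just before it), so the full timeline has
    ``len(baseline_times) - 1`` pre-bleach samples.  ``recovery_times``
    are offsets after the bleach (strictly positive).
    """

    baseline_times: tuple
    bleach_time: float
    recovery_times: tuple
    mode: str = "standard"

    def __post_init__(self):
        b = np.asarray(self.baseline_times, float)
        r = np.asarray(self.recovery_times, float)
        if b.size == 0 or r.size == 0:
            raise InvalidParameterError("baseline and recovery times must be nonempty")
        if np.any(b < 0) or np.any(r <= 0):
            raise InvalidParameterError("times must be >= 0 and recovery offsets > 0")
        if np.any(np.diff(b) <= 0) or np.any(np.diff(r) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.isclose(b[-1], self.bleach_time):
            raise InvalidParameterError("baseline_times must end at bleach_time")

    @property
    def full_times(self) -> np.ndarray:
        """Absolute acquisition times of the whole experiment."""
        return np.concatenate(
            [
                np.asarray(self.baseline_times, float),
                self.bleach_time + np.asarray(self.recovery_times, float),
            ]
        )

    @property
    def bleach_index(self) -> int:
        """Index of the first post-bleach frame in ``full_times``."""
        return len(self.baseline_times) - 1

    @property
    def post_times(self) -> np.ndarray:
        """Times since bleach of the post-bleach frames (starts at 0)."""
        return self.full_times[self.bleach_index :] - self.bleach_time


def make_schedule(mode: str = "standard", **params) -> AcquisitionSchedule:
    """Build the default acquisition schedules.

    ``standard``: baseline every 30 s spanning 3 min (7 frames including
    t=0, the last acquired immediately after the bleach), recovery sampled
    at 30, 60, ..., 180 s and then every 5 min from 480 s out to 4380 s
    (73 min).  ``fast``: 5-s sampling for short recordings of the fast
    component (baseline 30 s, recovery span 300 s by default).

    Keyword overrides: ``baseline_interval``, ``baseline_span``,
    ``early_interval``, ``early_span``, ``late_interval``, ``late_end``
    (standard) or ``recovery_interval``, ``recovery_span`` (fast), all in
    seconds.
    """
    if mode == "standard":
        bi = params.pop("baseline_interval", 30.0)
        bs = params.pop("baseline_span", 180.0)
        ei = params.pop("early_interval", 30.0)
        es = params.pop("early_span", 180.0)
        li = params.pop("late_interval", 300.0)
        le = params.pop("late_end", 4380.0)
        if params:
            raise InvalidParameterError(f"unknown schedule params {sorted(params)}")
        if min(bi, bs, ei, es, li, le) <= 0:
            raise InvalidParameterError("intervals and durations must be positive")
        baseline = np.arange(0.0, bs + bi / 2, bi)
        early = np.arange(ei, es + ei / 2, ei)
        late_start = es + li
        late = np.arange(late_start, le + li / 2, li)
        return AcquisitionSchedule(
            tuple(baseline), float(bs), tuple(np.concatenate([early, late])), mode
        )
    if mode == "fast":
        bi = params.pop("baseline_interval", 5.0)
        bs = params.pop("baseline_span", 30.0)
        ri = params.pop("recovery_interval", 5.0)
        rs = params.pop("recovery_span", 300.0)
        if params:
            raise InvalidParameterError(f"unknown schedule params {sorted(params)}")
        if min(bi, bs, ri, rs) <= 0:
            raise InvalidParameterError("intervals and durations must be positive")
        baseline = np.arange(0.0, bs + bi / 2, bi)
        recovery = np.arange(ri, rs + ri / 2, ri)
        return AcquisitionSchedule(tuple(baseline), float(bs), tuple(recovery), mode)
    raise InvalidParameterError(f"unknown schedule mode {mode!r}")


# ---------------------------------------------------------- FRAP traces


@dataclass(frozen=True)
class SimConfig:
    """Trace-level FRAP simulation parameters.

    ``bleach_depth`` is the fraction of bouton signal removed by the bleach
    pulse (0.5: half the initial fluorescence); ``acquisition_bleach_rate``
    the per-frame multiplicative retention shared by boutons and the cell
    reference; ``noise_sd`` the additive Gaussian noise sd as a fraction of
    the bouton baseline.
    """

    recovery_model: RecoveryModel = field(
        default_factory=lambda: RecoveryModel(0.7, 0.4, 60.0, 1200.0)
    )
    bleach_depth: float = 0.5
    acquisition_bleach_rate: float = 0.998
    noise_sd: float = 0.0
    n_boutons: int = 5
    seed: int = 0
    schedule: AcquisitionSchedule = field(default_factory=make_schedule)
    baseline_intensity: float = 1000.0
    cell_reference_intensity: float = 20000.0
    background_level: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.bleach_depth < 1.0:
            raise InvalidParameterError("bleach_depth must be in (0, 1)")
        if not 0.0 < self.acquisition_bleach_rate <= 1.0:
            raise InvalidParameterError("acquisition_bleach_rate must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_boutons < 1:
            raise InvalidParameterError("n_boutons must be >= 1")


def simulate_frap_trace(config: SimConfig):
    """Simulate raw FRAP traces for one imaged field.

    Each bouton follows ``baseline * (1 - d + d * R(t))`` after the bleach
    (``d`` = bleach depth), every acquired frame is attenuated cumulatively
    by ``acquisition_bleach_rate``, and Gaussian noise of sd ``noise_sd *
    baseline`` is added.  A whole-cell reference trace carrying the same
    per-frame attenuation and a constant background trace are shared by all
    boutons of the field.  Returns ``(traces, ground_truth_model)``.
    """
    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    times = sched.full_times
    bi = sched.bleach_index
    n = len(times)
    g = config.acquisition_bleach_rate ** np.arange(n)
    amp = np.ones(n)
    d = config.bleach_depth
    amp[bi:] = 1.0 - d + d * recovery_curve(config.recovery_model, sched.post_times)
    noise_abs = config.noise_sd * config.baseline_intensity
    cell = config.background_level + config.cell_reference_intensity * g
    if noise_abs > 0:
        cell = cell + rng.normal(0.0, noise_abs, n)
    background = np.full(n, config.background_level)
    traces = []
    for b in range(config.n_boutons):
        bouton = config.background_level + config.baseline_intensity * amp * g
        if noise_abs > 0:
            bouton = bouton + rng.normal(0.0, noise_abs, n)
        traces.append(
            FrapTrace(
                timestamps=times,
                bouton_raw=bouton,
                cell_reference_raw=cell.copy(),
                background_raw=background.copy(),
                bleach_index=bi,
                trace_id=f"sim_bouton_{b}",
            )
        )
    return traces, config.recovery_model


def simulate_normalized_traces(
    model: RecoveryModel,
    schedule: AcquisitionSchedule | None = None,
    noise_sd: float = 0.05,
    n_traces: int = 20,
    rng=None,
    n_pre: int = 6,
):
    """Draw normalized recovery traces with i.i.d. Gaussian noise.

    Convenience generator for fitting / power studies in normalized-
    recovery units: each post-bleach sample is ``R(t) + N(0, noise_sd)``
    except the immediately-post-bleach sample, pinned to 0 as the
    normalization guarantees; pre-bleach samples sit at ``1 + noise``.
    """
    if schedule is None:
        schedule = make_schedule()
    rng = np.random.default_rng(rng)
    post = schedule.post_times
    pre = np.asarray(schedule.baseline_times[:-1], float) - schedule.bleach_time
    r = recovery_curve(model, post)
    out = []
    for i in range(n_traces):
        v_pre = 1.0 + rng.normal(0.0, noise_sd, len(pre))
        v_post = r + rng.normal(0.0, noise_sd, len(post))
        v_post[0] = 0.0
        out.append(
            NormalizedFrapTrace(
                timestamps_post=np.concatenate([pre, post]),
                values=np.concatenate([v_pre, v_post]),
                bleach_index=len(pre),
                trace_id=f"norm_sim_{i}",
            )
        )
    return out


# ----------------------------------------------------------- FRAP stacks


def _gaussian_spot(shape, center, sigma, mass):
    """Pixel-integrated isotropic Gaussian of total mass ``mass``."""
    r = np.arange(shape[0] + 1) - 0.5
    c = np.arange(shape[1] + 1) - 0.5
    s = sigma * np.sqrt(2.0)
    pr = 0.5 * np.diff(erf((r - center[0]) / s))
    pc = 0.5 * np.diff(erf((c - center[1]) / s))
    return mass * np.outer(pr, pc)


@dataclass(frozen=True)
class FieldGeometry:
    """Spatial layout of a rendered FRAP field (pixel units)."""

    frame_shape: tuple = (160, 160)
    bouton_centers: tuple = ((24.0, 30.0), (40.0, 70.0), (60.0, 24.0),
                             (72.0, 90.0), (30.0, 120.0))
    spot_sigma: float = 1.5
    roi_radius: float | None = None  # default 4 * spot_sigma
    cell_center: tuple = (112.0, 112.0)
    cell_sigma: float = 7.0
    background_center: tuple = (140.0, 24.0)
    background_radius: float = 8.0
    drift_per_frame: tuple = (0.0, 0.0)
    pixel_size: float = 0.2  # µm/pixel
    pixel_offset: float = 0.0  # constant per-pixel camera offset
    camera_noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "poisson"


def render_frap_stack(config: SimConfig, geometry: FieldGeometry | None = None):
    """Render a FRAP field as an image stack with ground truth.

    Boutons are pixel-integrated 2-D Gaussian spots whose total intensity
    follows :func:`simulate_frap_trace`; the whole-cell reference is a
    broad Gaussian blob placed away from the boutons.  Optional global
    per-frame drift and camera noise are applied.  Returns
    ``(stack, roi_set, ground_truth)`` where ``ground_truth`` holds the
    underlying traces, the drift actually applied and the recovery model.
    """
    geometry = geometry or FieldGeometry()
    n_boutons = len(geometry.bouton_centers)
    config = replace(config, n_boutons=n_boutons, noise_sd=0.0)
    traces, model = simulate_frap_trace(config)
    shape = geometry.frame_shape
    roi_r = geometry.roi_radius or 4.0 * geometry.spot_sigma
    for cr, cc in geometry.bouton_centers:
        if not (roi_r <= cr <= shape[0] - roi_r and roi_r <= cc <= shape[1] - roi_r):
            raise InvalidParameterError("bouton center too close to the frame edge")
    if geometry.spot_sigma <= 0:
        raise InvalidParameterError("spot_sigma must be > 0")
    rng = np.random.default_rng(config.seed + 1)
    times = config.schedule.full_times
    n_frames = len(times)
    drift = np.array(geometry.drift_per_frame, float) * np.arange(n_frames)[:, None]
    data = np.empty((n_frames, *shape), dtype=np.float32)
    for k in range(n_frames):
        frame = np.full(shape, geometry.pixel_offset, dtype=float)
        for b, (cr, cc) in enumerate(geometry.bouton_centers):
            mass = traces[b].bouton_raw[k] - config.background_level
            frame += _gaussian_spot(
                shape, (cr + drift[k, 0], cc + drift[k, 1]), geometry.spot_sigma, mass
            )
        cell_mass = traces[0].cell_reference_raw[k] - config.background_level
        frame += _gaussian_spot(
            shape,
            (geometry.cell_center[0] + drift[k, 0], geometry.cell_center[1] + drift[k, 1]),
            geometry.cell_sigma,
            cell_mass,
        )
        if geometry.camera_noise_sd > 0:
            if geometry.noise_model == "poisson":
                frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
            else:
                frame = frame + rng.normal(0.0, geometry.camera_noise_sd, shape)
        data[k] = frame
    rois = RoiSet(
        bouton_rois=[
            CircleRoi(cr, cc, roi_r, name=f"bouton_{i}")
            for i, (cr, cc) in enumerate(geometry.bouton_centers)
        ],
        cell_rois=[
            CircleRoi(*geometry.cell_center, 4.0 * geometry.cell_sigma, name="cell_0")
        ],
        background_roi=CircleRoi(
            *geometry.background_center, geometry.background_radius, name="background"
        ),
    )
    stack = ImageStack(data, times, geometry.pixel_size)
    ground_truth = {"traces": traces, "model": model, "drift": drift}
    return stack, rois, ground_truth


# ------------------------------------------------------ axonal movies


@dataclass(frozen=True)
class MovieConfig:
    """Axonal time-lapse simulation parameters.

    Defaults reproduce the transport-imaging protocol: 5 frames/s for
    30 s, i.e. 151 frames.  ``axon_path`` is a polyline in pixel (row,
    col) coordinates (default: a horizontal line through the frame);
    punctum speeds are in µm/s (sign = direction along the path) and
    offsets in µm along the path.
    """

    frame_rate: float = 5.0
    duration: float = 30.0
    pixel_size: float = 0.2
    frame_shape: tuple = (64, 256)
    axon_path: tuple | None = None
    bouton_positions: tuple = ()  # path offsets, µm
    bouton_amplitude: float = 2000.0
    punctum_speeds: tuple = (1.5,)
    punctum_amplitudes: tuple | float = 400.0
    punctum_start_offsets: tuple | None = None
    spot_sigma: float = 1.2
    baseline_level: float = 10.0
    axon_level: float = 40.0  # diffuse fluorescence per µm of axon
    noise_sd: float = 0.0
    drift_per_frame: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.duration <= 0:
            raise InvalidParameterError("frame_rate and duration must be positive")
        if not all(np.isfinite(self.punctum_speeds)):
            raise InvalidParameterError("punctum speeds must be finite")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration)) + 1


@dataclass
class TransitLog:
    """Ground truth of punctum motion: straight-line transits along the path.

    Each entry is ``(punctum_id, start_offset_um, speed_um_s)``; a punctum
    crosses path position ``x`` (µm) at ``t = (x - start) / speed``.
    """

    entries: list
    path_length_um: float
    duration: float

    def crossings(self, position_um: float):
        """Puncta crossing ``position_um`` within the movie, as
        ``[(punctum_id, time_s), ...]``."""
        out = []
        for pid, start, speed in self.entries:
            if speed == 0:
                continue
            t = (position_um - start) / speed
            if 0.0 <= t <= self.duration:
                out.append((pid, t))
        return out


def _resample_path(path, step=1.0):
    """Resample a polyline at ``step``-pixel arc-length intervals."""
    p = np.asarray(path, float)
    if p.ndim != 2 or len(p) < 2:
        raise InvalidParameterError("path needs at least 2 vertices")
    seg = np.diff(p, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if seglen.sum() <= 0:
        raise InvalidParameterError("path length must be > 0")
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    si = np.arange(0.0, total + step / 2, step)
    rows = np.interp(si, s, p[:, 0])
    cols = np.interp(si, s, p[:, 1])
    return np.column_stack([rows, cols]), si


def _point_on_path(path_pts, arc, offset_px):
    rows = np.interp(offset_px, arc, path_pts[:, 0])
    cols = np.interp(offset_px, arc, path_pts[:, 1])
    return rows, cols


def render_axon_timelapse(config: MovieConfig):
    """Render a time-lapse movie of puncta moving along an axon.

    Stationary boutons sit at fixed path offsets; each punctum advances
    ``speed * dt`` per frame along the path and is rendered only while its
    offset lies on the path.  Returns ``(stack, transit_log)``.
    """
    shape = config.frame_shape
    if config.axon_path is None:
        mid = shape[0] / 2.0
        path = ((mid, 4.0), (mid, shape[1] - 4.0))
    else:
        path = config.axon_path
    path_pts, arc = _resample_path(path, step=0.25)
    length_um = arc[-1] * config.pixel_size
    n = config.n_frames
    dt = 1.0 / config.frame_rate
    speeds = np.atleast_1d(np.asarray(config.punctum_speeds, float))
    amps = np.broadcast_to(
        np.asarray(config.punctum_amplitudes, float), speeds.shape
    ).astype(float)
    if config.punctum_start_offsets is None:
        # anterograde puncta enter at the path start, retrograde at the end;
        # multiple puncta are staggered inward so their tracks separate
        inset = np.linspace(0.0, 0.3 * length_um, len(speeds))
        starts = np.where(speeds >= 0, inset, length_um - inset)
    else:
        starts = np.asarray(config.punctum_start_offsets, float)
    rng = np.random.default_rng(config.seed)
    drift = np.asarray(config.drift_per_frame, float) * np.arange(n)[:, None]
    # static diffuse axon fluorescence: a dim ridge along the path
    ridge = np.zeros(shape, dtype=float)
    if config.axon_level > 0:
        step_um = (arc[1] - arc[0]) * config.pixel_size
        for r, c in path_pts:
            ridge += _gaussian_spot(
                shape, (r, c), config.spot_sigma, config.axon_level * step_um
            )
    data = np.empty((n, *shape), dtype=np.float32)
    for k in range(n):
        frame = config.baseline_level + ridge
        t = k * dt
        for off_um in config.bouton_positions:
            r, c = _point_on_path(path_pts, arc, off_um / config.pixel_size)
            frame += _gaussian_spot(
                shape, (r + drift[k, 0], c + drift[k, 1]),
                config.spot_sigma, config.bouton_amplitude,
            )
        for i, (s0, v, a) in enumerate(zip(starts, speeds, amps)):
            off = s0 + v * t
            if 0.0 <= off <= length_um:
                r, c = _point_on_path(path_pts, arc, off / config.pixel_size)
                frame += _gaussian_spot(
                    shape, (r + drift[k, 0], c + drift[k, 1]), config.spot_sigma, a
                )
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, shape)
        data[k] = frame
    log = TransitLog(
        entries=[(i, float(s0), float(v)) for i, (s0, v) in enumerate(zip(starts, speeds))],
        path_length_um=float(length_um),
        duration=config.duration,
    )
    stack = ImageStack(data, np.arange(n) * dt, config.pixel_size)
    return stack, log


# ---------------------------------------------------------- mEPSC traces


@dataclass(frozen=True)
class MiniSimConfig:
    """Miniature-current simulation: homogeneous Poisson event train of
    biexponential currents plus Gaussian recording noise."""

    rate: float = 3.0  # Hz
    amplitude_mean: float = -15.0  # pA, negative = inward
    amplitude_cv: float = 0.2
    rise_tau: float = 0.5  # ms
    decay_tau: float = 5.0  # ms
    noise_sd: float = 2.0  # pA
    duration: float = 120.0  # s
    sampling_rate: float = 10_000.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise InvalidParameterError("rate must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise InvalidParameterError("need 0 < rise_tau < decay_tau")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidParameterError("duration and sampling_rate must be positive")


def simulate_mepsc_trace(config: MiniSimConfig):
    """Simulate a voltage-clamp trace of miniature events.

    Event onsets are a homogeneous Poisson process; each event adds a
    biexponential kernel whose peak equals its drawn amplitude (Gaussian
    around ``amplitude_mean`` with cv ``amplitude_cv``, sign preserved).
    Returns ``(trace, ground_truth_events)``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    samples = np.zeros(n)
    n_events = rng.poisson(config.rate * config.duration)
    onsets = np.sort(rng.uniform(0.0, config.duration, n_events))
    amp_sd = abs(config.amplitude_mean) * config.amplitude_cv
    amps = rng.normal(config.amplitude_mean, amp_sd, n_events)
    kernel = biexp_kernel(
        config.rise_tau, config.decay_tau, config.sampling_rate,
        length_ms=config.decay_tau * 10.0,
    )
    events = []
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * config.sampling_rate))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        samples[i0 : i0 + len(seg)] += amp * seg
        events.append(MiniEvent(onset_time=float(onset), peak_amplitude=float(amp)))
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, n)
    trace = CurrentTrace(
        samples=samples, sampling_rate=config.sampling_rate, holding_potential=-70.0
    )
    return trace, events
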