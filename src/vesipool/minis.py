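"""Miniature postsynaptic current analysis.

Detects quantal events in voltage-clamp traces by sliding scaled-template
matching (Clements-Bekkers criterion: fitted template scale divided by the
standard error of the fit), summarizes amplitude and frequency per cell,
derives passive-membrane quality-control measures from seal-test step
responses, and dispatches the usual two-or-more-group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "CurrentTrace",
    "EventTemplate",
    "MiniEvent",
    "CellQc",
    "MiniSummary",
    "biexp_kernel",
    "make_template",
    "detect_events",
    "qc_cell",
    "qc_decision",
    "summarize_minis",
    "compare_groups",
]


@dataclass
class CurrentTrace:
    """Voltage-clamp current recording in pA."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    holding_potential: float = -70.0  # mV

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class EventTemplate:
    """Biexponential event shape used for template matching.

    Defaults follow typical mEPSC kinetics (fast rise, ~5 ms decay);
    mIPSCs are slower (rise 1 ms, decay 10 ms).  ``polarity`` sets the
    sign of the matched deflection: inward events are negative.
    """

    rise_tau: float = 0.5  # ms
    decay_tau: float = 5.0  # ms
    length: float = 30.0  # ms
    polarity: str = "inward"

    def __post_init__(self):
        if not 0 < self.rise_tau < self.decay_tau < self.length:
            raise InvalidParameterError(
                "need 0 < rise_tau < decay_tau < length (all ms)"
            )
        if self.polarity not in ("inward", "outward"):
            raise InvalidParameterError("polarity must be 'inward' or 'outward'")

    def waveform(self, sampling_rate: float) -> np.ndarray:
        """Unit-peak template sampled at ``sampling_rate``; sign follows
        polarity (inward -> trough of -1)."""
        w = biexp_kernel(self.rise_tau, self.decay_tau, sampling_rate, self.length)
        return -w if self.polarity == "inward" else w


@dataclass
class MiniEvent:
    """One detected (or simulated) miniature event."""

    onset_time: float  # s
    peak_amplitude: float  # pA, signed
    detection_score: float = np.inf


@dataclass
class CellQc:
    """Passive properties and the inclusion decision for one cell."""

    leak_current: float  # pA
    membrane_resistance: float  # MΩ
    tau: float = np.nan  # ms
    capacitance: float = np.nan  # pF
    access_resistance: float = np.nan  # MΩ
    include: bool = True
    flags: list = field(default_factory=list)


@dataclass
class MiniSummary:
    """Frequency / amplitude summary of one recording."""

    frequency: float  # Hz
    mean_amplitude: float  # pA (nan when no events)
    n_events: int
    duration_analyzed: float  # s


def biexp_kernel(
    rise_tau: float, decay_tau: float, sampling_rate: float, length_ms: float
) -> np.ndarray:
    """Unit-peak biexponential ``exp(-t/decay) - exp(-t/rise)`` (tau in ms)."""
    if not 0 < rise_tau < decay_tau:
        raise InvalidParameterError("need 0 < rise_tau < decay_tau")
    t = np.arange(0.0, length_ms / 1e3, 1.0 / sampling_rate)
    rd, dd = rise_tau / 1e3, decay_tau / 1e3
    w = np.exp(-t / dd) - np.exp(-t / rd)
    return w / w.max()


def make_template(kind: str = "mepsc", **overrides) -> EventTemplate:
    """Default templates: ``mepsc`` (inward, rise 0.5 ms / decay 5 ms) or
    ``mipsc`` (outward at 0 mV, rise 1 ms / decay 10 ms)."""
    if kind == "mepsc":
        base = dict(rise_tau=0.5, decay_tau=5.0, length=30.0, polarity="inward")
    elif kind == "mipsc":
        base = dict(rise_tau=1.0, decay_tau=10.0, length=60.0, polarity="outward")
    else:
        raise InvalidParameterError(f"unknown template kind {kind!r}")
    base.update(overrides)
    return EventTemplate(**base)


def detect_events(
    trace: CurrentTrace,
    template: EventTemplate | None = None,
    criterion_threshold: float = 4.0,
    refractory_ms: float | None = None,
) -> list[MiniEvent]:
    """Sliding scaled-template event detection.

    At every lag the template is fitted to the trace window by optimal
    scale and offset; the detection criterion is the fitted scale divided
    by the standard error of the fit.  Events are local maxima of the
    criterion above ``criterion_threshold`` separated by at least the
    refractory interval (template rise time + 2 ms unless given).  Peak
    amplitude is the fitted baseline-to-peak deflection (signed).
    """
    template = template or make_template("mepsc")
    w = template.waveform(trace.sampling_rate)
    x = trace.samples
    n, m = len(x), len(w)
    if m >= n:
        raise InvalidInputError("template longer than trace")
    ones = np.ones(m)
    sum_w = w.sum()
    sum_ww = float(w @ w)
    # windowed sums via correlation; 'valid' gives one value per lag
    sx = signal.fftconvolve(x, ones[::-1], mode="valid")
    sxx = signal.fftconvolve(x * x, ones[::-1], mode="valid")
    sxw = signal.fftconvolve(x, w[::-1], mode="valid")
    denom = sum_ww - sum_w * sum_w / m
    scale = (sxw - sx * sum_w / m) / denom
    sse = sxx - sx * sx / m - scale * scale * denom
    sse = np.clip(sse, 0.0, None)
    # floors guard the noise-free limit, where round-off in the windowed
    # sums would otherwise produce huge criteria at negligible scales
    amp_scale = float(np.abs(x).max()) or 1.0
    se = np.maximum(np.sqrt(sse / (m - 1)), 1e-9 * amp_scale)
    crit = scale / se
    crit[scale < 1e-6 * amp_scale] = 0.0
    refractory = (
        refractory_ms if refractory_ms is not None else template.rise_tau + 2.0
    )
    distance = max(1, int(round(refractory / 1e3 * trace.sampling_rate)))
    # a prominence floor suppresses the shallow secondary maxima the
    # criterion develops along the decay of a single large event
    kept, _ = signal.find_peaks(
        crit,
        height=criterion_threshold,
        distance=distance,
        prominence=0.5 * criterion_threshold,
    )
    sign = -1.0 if template.polarity == "inward" else 1.0
    return [
        MiniEvent(
            onset_time=p / trace.sampling_rate,
            peak_amplitude=float(sign * scale[p]),
            detection_score=float(crit[p]),
        )
        for p in kept
    ]


def qc_cell(
    seal_test_trace: CurrentTrace,
    step_start: float,
    step_duration: float,
    v_step: float = -5.0,
    leak_limit: float = 200.0,
    rm_limit: float = 100.0,
) -> CellQc:
    """Passive-membrane QC from a voltage-step (seal test) response.

    ``v_step`` is the command step in mV.  Leak = pre-step holding
    current; access resistance from the peak capacitive transient;
    membrane resistance from the steady-state step current; tau from a
    mono-exponential fit of the transient decay; capacitance = tau / Ra.
    A cell is included iff |leak| <= ``leak_limit`` pA and Rm >=
    ``rm_limit`` MΩ (both configurable).
    """
    x = seal_test_trace.samples
    fs = seal_test_trace.sampling_rate
    i0 = int(round(step_start * fs))
    i1 = int(round((step_start + step_duration) * fs))
    if not 0 < i0 < i1 <= len(x):
        raise InvalidInputError("step window outside the trace")
    leak = float(np.mean(x[: i0]))
    steady = float(np.mean(x[i0 + (i1 - i0) * 3 // 4 : i1]))
    step_seg = x[i0:i1] - steady
    ipk = int(np.argmax(np.abs(step_seg)))
    peak = float(x[i0 + ipk])
    flags = []
    # mV / pA = GΩ -> MΩ
    ra = v_step / (peak - leak) * 1e3 if peak != leak else np.nan
    dI_ss = steady - leak
    rm = v_step / dI_ss * 1e3 - ra if dI_ss != 0 else np.inf
    tau = cm = np.nan
    t_seg = np.arange(len(step_seg) - ipk) / fs
    y_seg = step_seg[ipk:]
    if len(y_seg) > 10 and abs(y_seg[0]) > 0:
        try:
            popt, _ = optimize.curve_fit(
                lambda t, a, tau_s: a * np.exp(-t / tau_s),
                t_seg,
                y_seg,
                p0=(y_seg[0], max(1.0 / fs * 5, 1e-4)),
                maxfev=2000,
            )
            tau = float(popt[1] * 1e3)  # ms
            if tau <= 0 or not np.isfinite(tau):
                raise RuntimeError("nonpositive tau")
            cm = tau / ra * 1e3  # ms/MΩ = nF; *1e3 -> pF
        except Exception:
            tau = cm = np.nan
            flags.append("transient_fit_failed")
    include = qc_decision(leak, rm, leak_limit, rm_limit)
    return CellQc(
        leak_current=leak,
        membrane_resistance=float(rm),
        tau=tau,
        capacitance=float(cm),
        access_resistance=float(ra),
        include=bool(include),
        flags=flags,
    )


def qc_decision(
    leak_pa: float, rm_mohm: float, leak_limit: float = 200.0, rm_limit: float = 100.0
) -> bool:
    """Cell inclusion rule: |leak| within ``leak_limit`` pA AND membrane
    resistance at least ``rm_limit`` MΩ (leaky or low-resistance cells are
    excluded as compromised seals)."""
    return (abs(leak_pa) <= leak_limit) and (rm_mohm >= rm_limit)


def summarize_minis(events, duration: float) -> MiniSummary:
    """Event frequency (count/duration) and mean signed peak amplitude."""
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    n = len(events)
    amps = [e.peak_amplitude for e in events]
    return MiniSummary(
        frequency=n / duration,
        mean_amplitude=float(np.mean(amps)) if n else float("nan"),
        n_events=n,
        duration_analyzed=duration,
    )


def compare_groups(groups, test: str = "t"):
    """Two-or-more-sample comparison of per-cell summary values.

    ``test`` is one of ``t`` (unpaired), ``mann_whitney``, ``anova``
    (one-way) or ``kruskal``.  Returns ``(statistic, p_value,
    descriptives)`` where descriptives holds per-group mean, SEM and n.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if test == "t":
        if len(arrays) != 2:
            raise InvalidParameterError("t test requires exactly 2 groups")
        r = stats.ttest_ind(arrays[0], arrays[1])
    elif test == "mann_whitney":
        if len(arrays) != 2:
            raise InvalidParameterError("Mann-Whitney requires exactly 2 groups")
        r = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
    elif test == "anova":
        r = stats.f_oneway(*arrays)
    elif test == "kruskal":
        r = stats.kruskal(*arrays)
    else:
        raise InvalidParameterError(f"unknown test {test!r}")
    desc = [
        {
            "mean": float(a.mean()),
            "sem": float(a.std(ddof=1) / np.sqrt(len(a))),
            "n": len(a),
        }
        for a in arrays
    ]
    return float(r.statistic), float(r.pvalue), desc
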