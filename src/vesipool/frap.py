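"""Trace-level FRAP analysis.

Takes raw integrated-intensity traces (bouton, whole-cell reference,
background) and produces normalized recovery curves, quality-control
decisions, biexponential recovery fits, nested-model comparisons via the
extra sum-of-squares F test, and fixed-timepoint group comparisons.

Normalization convention: after background subtraction and ratio
photobleaching correction against the cell reference, traces are scaled so
the pre-bleach mean is 1 and the immediately-post-bleach sample is 0; the
recovery value is then directly the fraction of the bleached signal
replenished by exchange with the axonal super-pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    CorrectionFailureError,
    DegenerateBleachError,
    FitFailureError,
    InvalidInputError,
    MissingTimepointError,
)
from .kinetics import RecoveryModel, recovery_curve

__all__ = [
    "FrapTrace",
    "NormalizedFrapTrace",
    "DoubleExpFit",
    "FTestResult",
    "TimepointComparison",
    "normalize_trace",
    "qc_photobleaching",
    "fit_double_exponential",
    "extra_ss_f_test",
    "recovery_at_timepoint",
]


@dataclass
class FrapTrace:
    """Raw per-bouton FRAP series.

    ``bleach_index`` marks the first post-bleach sample: the frame acquired
    immediately after the bleach pulse, at the bleach time itself.
    """

    timestamps: np.ndarray
    bouton_raw: np.ndarray
    cell_reference_raw: np.ndarray
    background_raw: np.ndarray
    bleach_index: int
    trace_id: str = ""

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.bouton_raw = np.asarray(self.bouton_raw, dtype=float)
        self.cell_reference_raw = np.asarray(self.cell_reference_raw, dtype=float)
        self.background_raw = np.asarray(self.background_raw, dtype=float)
        n = len(self.timestamps)
        for name in ("bouton_raw", "cell_reference_raw", "background_raw"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"{name} length must match timestamps")
        if not 0 < self.bleach_index < n:
            raise InvalidInputError("bleach_index must satisfy 0 < index < length")


@dataclass
class NormalizedFrapTrace:
    """Corrected and full-scale-normalized recovery trace.

    ``timestamps_post`` are seconds since bleach (pre-bleach samples carry
    negative times); ``values[bleach_index] == 0`` by construction and the
    pre-bleach mean is 1.
    """

    timestamps_post: np.ndarray
    values: np.ndarray
    bleach_index: int
    photobleach_fraction: float = 0.0
    qc_pass: bool = True
    trace_id: str = ""

    def __post_init__(self):
        self.timestamps_post = np.asarray(self.timestamps_post, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.timestamps_post):
            raise InvalidInputError("values length must match timestamps_post")

    @property
    def post_times(self) -> np.ndarray:
        return self.timestamps_post[self.bleach_index :]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.bleach_index :]


@dataclass
class DoubleExpFit:
    """Best-fit biexponential recovery parameters."""

    plateau: float
    fast_fraction: float
    half_fast: float
    half_slow: float
    residual_ss: float
    n_points: int
    n_params: int = 4
    param_sd: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def model(self) -> RecoveryModel:
        return RecoveryModel(
            min(self.plateau, 1.05), self.fast_fraction, self.half_fast, self.half_slow
        )

    def predict(self, t) -> np.ndarray:
        return _biexp(np.asarray(t, float), self.plateau, self.fast_fraction,
                      self.half_fast, self.half_slow)


@dataclass
class FTestResult:
    """Extra sum-of-squares comparison of shared vs per-group fits."""

    f_ratio: float
    df_num: int
    df_den: int
    p_value: float
    ss_shared: float
    ss_separate: float
    verdict: str  # "shared" | "divergent"
    shared_fit: DoubleExpFit | None = None
    group_fits: list = field(default_factory=list)


@dataclass
class TimepointComparison:
    """Per-trace recovery at the sample nearest a query time, compared
    between groups (two-sample or each-vs-reference for >2 groups)."""

    query_time: float
    group_values: list
    test: str
    statistic: object
    p_value: object
    group_means: list = field(default_factory=list)
    group_sems: list = field(default_factory=list)


def normalize_trace(trace: FrapTrace, n_edge: int = 3) -> NormalizedFrapTrace:
    """Background-subtract, bleach-correct and full-scale normalize.

    Steps: (1) subtract the background trace from bouton and cell series;
    (2) divide the bouton by the cell reference rescaled to its own
    pre-bleach mean (ratio correction — cancels acquisition photobleaching
    shared by bouton and cell); (3) map the corrected pre-bleach mean to 1
    and the corrected immediately-post-bleach value to 0.

    ``photobleach_fraction`` is the fraction of cell-reference signal lost
    between the first and last ``n_edge`` frames of the experiment.
    """
    bi = trace.bleach_index
    b = trace.bouton_raw - trace.background_raw
    c = trace.cell_reference_raw - trace.background_raw
    if np.any(c <= 0):
        raise CorrectionFailureError(
            "cell reference nonpositive after background subtraction"
        )
    corrected = b / (c / c[:bi].mean())
    f_pre = corrected[:bi].mean()
    f_post0 = corrected[bi]
    if f_pre <= f_post0:
        raise DegenerateBleachError(
            f"no bleach step: pre-bleach mean {f_pre:.4g} <= "
            f"post-bleach value {f_post0:.4g}"
        )
    values = (corrected - f_post0) / (f_pre - f_post0)
    k = min(n_edge, len(c))
    photobleach = 1.0 - c[-k:].mean() / c[:k].mean()
    return NormalizedFrapTrace(
        timestamps_post=trace.timestamps - trace.timestamps[bi],
        values=values,
        bleach_index=bi,
        photobleach_fraction=float(photobleach),
        trace_id=trace.trace_id,
    )


def qc_photobleaching(trace: NormalizedFrapTrace, threshold: float = 0.60) -> bool:
    """Keep the experiment unless photobleaching *exceeded* the threshold
    (strictly greater); discarded recordings risk phototoxicity artifacts."""
    ok = not trace.photobleach_fraction > threshold
    trace.qc_pass = ok
    return ok


# ---------------------------------------------------------------- fitting

_BOUNDS_LO = np.array([0.0, 0.0, 1.0, 1.0])
_BOUNDS_HI = np.array([1.2, 1.0, 1e5, 1e5])

# log-spaced (half_fast, half_slow) start pairs; P and f start at data-driven
# values. Tie-break among converged starts: lowest SS, then lowest half_fast.
_HALF_LIFE_STARTS = [
    (10.0, 300.0),
    (10.0, 3000.0),
    (30.0, 1000.0),
    (30.0, 10000.0),
    (100.0, 1000.0),
    (100.0, 10000.0),
    (300.0, 3000.0),
    (300.0, 10000.0),
]


def _biexp(t, P, f, hf, hs):
    return P * (f * (1.0 - np.exp2(-t / hf)) + (1.0 - f) * (1.0 - np.exp2(-t / hs)))


def _pool_points(traces, mode):
    ts, vs = [], []
    for tr in traces:
        ts.append(tr.post_times)
        vs.append(tr.post_values)
    if mode == "pooled":
        return np.concatenate(ts), np.concatenate(vs)
    if mode == "averaged":
        t0 = ts[0]
        for t in ts[1:]:
            if len(t) != len(t0) or not np.allclose(t, t0):
                raise InvalidInputError(
                    "averaged mode requires a common acquisition schedule"
                )
        return t0, np.mean(np.stack(vs), axis=0)
    raise InvalidInputError(f"unknown fit mode {mode!r}")


def _fit_from_starts(t, v, starts, tol=1e-12):
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                lambda x: _biexp(t, *x) - v,
                x0=np.clip(x0, _BOUNDS_LO, _BOUNDS_HI),
                bounds=(_BOUNDS_LO, _BOUNDS_HI),
                ftol=tol, xtol=tol, gtol=tol, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append((x0, repr(exc)))
            continue
        if not res.success:
            diagnostics.append((x0, res.message))
            continue
        ss = float(res.cost * 2.0)
        hf = min(res.x[2], res.x[3])
        if best is None or ss < best[0] - 1e-15 * max(1.0, best[0]) or (
            np.isclose(ss, best[0], rtol=1e-12, atol=1e-300) and hf < best[2]
        ):
            best = (ss, res, hf)
    if best is None:
        raise FitFailureError("all fit starts failed to converge", diagnostics)
    return best[0], best[1]


def fit_double_exponential(
    traces,
    mode: str = "pooled",
    n_starts: int = 8,
    extra_starts=(),
) -> DoubleExpFit:
    """Nonlinear least-squares biexponential fit of normalized recovery.

    ``mode='pooled'`` fits all post-bleach points of all traces jointly
    (well-defined residual degrees of freedom); ``mode='averaged'`` fits
    the mean trace.  Multi-start over log-spaced half-life pairs guards
    against the local minima of the two-timescale model; ``extra_starts``
    may supply additional ``(P, f, h_f, h_s)`` starting vectors.
    Half-life order ``h_f < h_s`` is enforced by relabelling components.
    """
    traces = [tr for tr in traces if tr.qc_pass]
    if not traces:
        raise InvalidInputError("no QC-passing traces to fit")
    t, v = _pool_points(traces, mode)
    if len(t) <= 5:
        raise InvalidInputError("need more than 5 post-bleach samples to fit")
    p0 = float(np.clip(np.mean(v[t >= 0.8 * t.max()]), 0.05, 1.2))
    starts = [
        np.array([p0, 0.5, hf, hs]) for hf, hs in _HALF_LIFE_STARTS[:n_starts]
    ] + [np.asarray(x, float) for x in extra_starts]
    ss, res = _fit_from_starts(t, v, starts)
    P, f, hf, hs = res.x
    if hf > hs:  # relabel so the fast component is first
        hf, hs = hs, hf
        f = 1.0 - f
    flags = []
    if f > 0.999:
        flags.append("slow_component_unidentifiable")
    if f < 0.001:
        flags.append("fast_component_unidentifiable")
    if hs < 1.05 * hf:
        # hf == hs makes f unidentifiable: the model collapses to a
        # single exponential regardless of the fast fraction
        flags.append("half_lives_degenerate")
    n = len(t)
    param_sd = {}
    dof = n - 4
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (ss / dof)
            sds = np.sqrt(np.clip(np.diag(cov), 0, None))
            param_sd = dict(zip(("plateau", "fast_fraction", "half_fast", "half_slow"), sds))
        except np.linalg.LinAlgError:
            flags.append("singular_covariance")
    return DoubleExpFit(
        plateau=float(P), fast_fraction=float(f), half_fast=float(hf),
        half_slow=float(hs), residual_ss=ss, n_points=n,
        param_sd=param_sd, flags=flags,
    )


def fit_double_exponential_points(t, v, n_starts: int = 8, extra_starts=()):
    """Fit the biexponential directly to pooled (t, v) arrays."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    p0 = float(np.clip(np.mean(v[t >= 0.8 * t.max()]), 0.05, 1.2))
    starts = [
        np.array([p0, 0.5, hf, hs]) for hf, hs in _HALF_LIFE_STARTS[:n_starts]
    ] + [np.asarray(x, float) for x in extra_starts]
    ss, res = _fit_from_starts(t, v, starts)
    P, f, hf, hs = res.x
    if hf > hs:
        hf, hs = hs, hf
        f = 1.0 - f
    return DoubleExpFit(
        plateau=float(P), fast_fraction=float(f), half_fast=float(hf),
        half_slow=float(hs), residual_ss=ss, n_points=len(t),
    )


def extra_ss_f_test(
    groups,
    alpha: float = 0.05,
    mode: str = "pooled",
    n_starts: int = 8,
) -> FTestResult:
    """Extra sum-of-squares F test: shared vs per-group recovery fits.

    Fits one biexponential to the pooled points of all groups and one per
    group, and asks whether the per-group fits reduce residual SS enough,
    relative to the degrees of freedom spent, to reject the shared model:

        F = ((ss_shared - ss_separate) / (df_shared - df_separate))
            / (ss_separate / df_separate)

    with df_shared = N - 4 and df_separate = N - 4k for k groups.
    """
    if len(groups) < 2:
        raise InvalidInputError("extra_ss_f_test needs at least 2 groups")
    pts = [_pool_points([tr for tr in g if tr.qc_pass], mode) for g in groups]
    t_all = np.concatenate([t for t, _ in pts])
    v_all = np.concatenate([v for _, v in pts])
    shared = fit_double_exponential_points(t_all, v_all, n_starts=n_starts)
    shared_x = (shared.plateau, shared.fast_fraction, shared.half_fast, shared.half_slow)
    # seeding each group fit from the shared optimum guarantees
    # ss_separate <= ss_shared up to round-off
    group_fits = [
        fit_double_exponential_points(t, v, n_starts=n_starts, extra_starts=[shared_x])
        for t, v in pts
    ]
    ss_shared = shared.residual_ss
    ss_separate = float(sum(g.residual_ss for g in group_fits))
    n = len(t_all)
    k = len(groups)
    df_shared = n - 4
    df_separate = n - 4 * k
    if df_separate <= 0:
        raise InvalidInputError("too few points for per-group fits")
    extra = ss_shared - ss_separate
    data_scale = float(v_all @ v_all)
    if ss_shared <= 1e-12 * max(data_scale, 1e-300):
        # the shared model already fits to round-off: exact null
        f_ratio, p = 0.0, 1.0
    elif extra <= 1e-12 * ss_shared:
        f_ratio, p = 0.0, 1.0
    elif ss_separate <= 0.0:
        f_ratio, p = np.inf, 0.0
    else:
        f_ratio = (extra / (df_shared - df_separate)) / (ss_separate / df_separate)
        p = float(stats.f.sf(f_ratio, df_shared - df_separate, df_separate))
    return FTestResult(
        f_ratio=float(f_ratio),
        df_num=df_shared - df_separate,
        df_den=df_separate,
        p_value=p,
        ss_shared=ss_shared,
        ss_separate=ss_separate,
        verdict="divergent" if p < alpha else "shared",
        shared_fit=shared,
        group_fits=group_fits,
    )


def _value_near(trace: NormalizedFrapTrace, query_time: float) -> float:
    t = trace.post_times
    i = int(np.argmin(np.abs(t - query_time)))
    gaps = np.diff(t)
    local = max(
        gaps[i - 1] if i > 0 else 0.0, gaps[i] if i < len(gaps) else 0.0
    )
    if abs(t[i] - query_time) > 0.5 * local and not np.isclose(t[i], query_time):
        raise MissingTimepointError(
            f"no sample within half an interval of t={query_time} s"
        )
    return float(trace.post_values[i])


def recovery_at_timepoint(
    groups,
    query_time: float = 4080.0,
    test: str = "t",
) -> TimepointComparison:
    """Compare per-trace recovery at the sample nearest ``query_time``.

    Default query is 68 min (4080 s) post-bleach.  Two groups: unpaired t
    test or Mann-Whitney U; more than two: each group against the first
    (reference), returning lists of statistics and p values.
    """
    if any(len(g) < 2 for g in groups):
        raise InvalidInputError("each group needs at least 2 traces")
    vals = [np.array([_value_near(tr, query_time) for tr in g]) for g in groups]

    def _two(a, b):
        if test == "t":
            r = stats.ttest_ind(a, b)
        elif test == "mann_whitney":
            r = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise InvalidInputError(f"unknown test {test!r}")
        return float(r.statistic), float(r.pvalue)

    if len(vals) == 2:
        statistic, p = _two(vals[0], vals[1])
    else:
        pairs = [_two(vals[0], v) for v in vals[1:]]
        statistic = [s for s, _ in pairs]
        p = [q for _, q in pairs]
    return TimepointComparison(
        query_time=query_time,
        group_values=[v.tolist() for v in vals],
        test=test,
        statistic=statistic,
        p_value=p,
        group_means=[float(v.mean()) for v in vals],
        group_sems=[float(v.std(ddof=1) / np.sqrt(len(v))) for v in vals],
    )
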