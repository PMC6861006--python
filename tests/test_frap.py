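"""Normalization, QC, biexponential fitting and nested-model comparison."""

import numpy as np
import pytest

from vesipool.errors import (
    CorrectionFailureError,
    DegenerateBleachError,
    MissingTimepointError,
)
from vesipool.frap import (
    FrapTrace,
    extra_ss_f_test,
    fit_double_exponential,
    normalize_trace,
    qc_photobleaching,
    recovery_at_timepoint,
)
from vesipool.kinetics import RecoveryModel, recovery_curve
from vesipool.sim import (
    SimConfig,
    make_schedule,
    simulate_frap_trace,
    simulate_normalized_traces,
)


def _grid_search_ss(t, v, n=20):
    """Brute-force residual SS over a coarse 4-D parameter grid."""
    P = np.linspace(0.05, 1.2, n)
    f = np.linspace(0.0, 1.0, n)
    hf = np.geomspace(2.0, 2000.0, n)
    hs = np.geomspace(50.0, 5e4, n)
    best = np.inf
    for p_ in P:
        for f_ in f:
            fast = 1.0 - np.exp2(-t[None, :] / hf[:, None])
            slow = 1.0 - np.exp2(-t[None, :] / hs[:, None])
            pred = p_ * (f_ * fast[:, None, :] + (1 - f_) * slow[None, :, :])
            ss = ((pred - v[None, None, :]) ** 2).sum(axis=-1)
            best = min(best, ss.min())
    return best


class TestNormalize:
    def test_pinned_scale(self, standard_model):
        traces, _ = simulate_frap_trace(
            SimConfig(recovery_model=standard_model, noise_sd=0.03, seed=3)
        )
        nt = normalize_trace(traces[0])
        assert nt.post_values[0] == 0.0
        assert nt.values[: nt.bleach_index].mean() == pytest.approx(1.0, abs=1e-12)

    def test_ratio_correction_cancels_shared_bleaching(self, standard_model):
        for rate in (1.0, 0.99, 0.95):
            cfg = SimConfig(recovery_model=standard_model, acquisition_bleach_rate=rate)
            traces, model = simulate_frap_trace(cfg)
            nt = normalize_trace(traces[0])
            expected = recovery_curve(model, nt.post_times)
            assert np.abs(nt.post_values - expected).max() < 1e-9

    def test_idempotent_on_normalized_values(self, standard_model, schedule):
        r = recovery_curve(standard_model, schedule.post_times)
        values = np.concatenate([np.ones(schedule.bleach_index), r])
        tr = FrapTrace(
            timestamps=schedule.full_times,
            bouton_raw=values,
            cell_reference_raw=np.ones_like(values),
            background_raw=np.zeros_like(values),
            bleach_index=schedule.bleach_index,
        )
        nt = normalize_trace(tr)
        assert np.abs(nt.values - values).max() < 1e-12

    def test_no_bleach_is_degenerate(self, schedule):
        n = len(schedule.full_times)
        tr = FrapTrace(
            timestamps=schedule.full_times,
            bouton_raw=np.full(n, 5.0),
            cell_reference_raw=np.full(n, 50.0),
            background_raw=np.zeros(n),
            bleach_index=schedule.bleach_index,
        )
        with pytest.raises(DegenerateBleachError):
            normalize_trace(tr)

    def test_nonpositive_cell_reference_fails(self, schedule):
        n = len(schedule.full_times)
        tr = FrapTrace(
            timestamps=schedule.full_times,
            bouton_raw=np.full(n, 5.0),
            cell_reference_raw=np.full(n, 1.0),
            background_raw=np.full(n, 2.0),
            bleach_index=schedule.bleach_index,
        )
        with pytest.raises(CorrectionFailureError):
            normalize_trace(tr)


class TestQc:
    @pytest.mark.parametrize(
        "fraction,expected", [(0.65, False), (0.0, True), (0.60, True)]
    )
    def test_discard_rule_boundary(self, standard_model, fraction, expected):
        traces = simulate_normalized_traces(standard_model, n_traces=1, noise_sd=0.0)
        traces[0].photobleach_fraction = fraction
        assert qc_photobleaching(traces[0]) is expected
        assert traces[0].qc_pass is expected


class TestFit:
    def test_noiseless_parameter_recovery(self, standard_model):
        traces = simulate_normalized_traces(standard_model, n_traces=3, noise_sd=0.0)
        fit = fit_double_exponential(traces)
        assert fit.plateau == pytest.approx(0.7, rel=1e-6)
        assert fit.fast_fraction == pytest.approx(0.4, rel=1e-6)
        assert fit.half_fast == pytest.approx(60.0, rel=1e-6)
        assert fit.half_slow == pytest.approx(1200.0, rel=1e-6)

    def test_single_exponential_data_flagged_degenerate(self):
        # single-exponential truth is reachable as f->1 or h_f == h_s;
        # either way the fitted curve must collapse to the single
        # exponential and the unidentifiable component must be flagged
        m = RecoveryModel(0.7, 1.0, 60.0, 1200.0)  # slow component absent
        traces = simulate_normalized_traces(m, n_traces=3, noise_sd=0.0)
        fit = fit_double_exponential(traces)
        assert fit.plateau == pytest.approx(0.7, rel=1e-4)
        t = np.linspace(0.0, 4380.0, 300)
        single = 0.7 * (1.0 - np.exp2(-t / 60.0))
        assert np.abs(fit.predict(t) - single).max() < 1e-4
        assert any(
            flag in fit.flags
            for flag in ("slow_component_unidentifiable", "half_lives_degenerate")
        )

    def test_fit_beats_coarse_grid_search(self, standard_model, schedule):
        rng = np.random.default_rng(5)
        for _ in range(3):
            traces = simulate_normalized_traces(
                standard_model, schedule, noise_sd=0.08, n_traces=1, rng=rng
            )
            t, v = traces[0].post_times, traces[0].post_values
            fit = fit_double_exponential(traces)
            assert fit.residual_ss <= _grid_search_ss(t, v) + 1e-12

    def test_averaged_mode_on_common_schedule(self, standard_model):
        traces = simulate_normalized_traces(standard_model, n_traces=5, noise_sd=0.0)
        fit = fit_double_exponential(traces, mode="averaged")
        assert fit.plateau == pytest.approx(0.7, rel=1e-6)
        assert fit.n_points == len(traces[0].post_times)


class TestExtraSsFTest:
    def test_identical_noiseless_groups_accept_shared_model(self, standard_model):
        g1 = simulate_normalized_traces(standard_model, n_traces=4, noise_sd=0.0)
        g2 = simulate_normalized_traces(standard_model, n_traces=4, noise_sd=0.0)
        res = extra_ss_f_test([g1, g2])
        assert res.f_ratio == 0.0
        assert res.p_value == 1.0
        assert res.verdict == "shared"

    def test_duplicated_group_gives_exact_null(self, standard_model, rng):
        g = simulate_normalized_traces(standard_model, noise_sd=0.05, n_traces=8, rng=rng)
        res = extra_ss_f_test([g, g])
        assert res.ss_shared == pytest.approx(res.ss_separate, rel=1e-9)
        assert res.f_ratio == 0.0
        assert res.p_value == 1.0

    def test_nesting_inequality(self, standard_model, rng):
        m2 = RecoveryModel(0.55, 0.5, 40.0, 900.0)
        for _ in range(3):
            g1 = simulate_normalized_traces(standard_model, noise_sd=0.07, n_traces=6, rng=rng)
            g2 = simulate_normalized_traces(m2, noise_sd=0.07, n_traces=6, rng=rng)
            res = extra_ss_f_test([g1, g2], n_starts=3)
            assert res.ss_shared >= res.ss_separate - 1e-9 * res.ss_shared

    def test_f_invariant_under_rescaling(self, standard_model, rng):
        m2 = RecoveryModel(0.6, 0.4, 60.0, 1200.0)
        g1 = simulate_normalized_traces(standard_model, noise_sd=0.05, n_traces=6, rng=rng)
        g2 = simulate_normalized_traces(m2, noise_sd=0.05, n_traces=6, rng=rng)
        res = extra_ss_f_test([g1, g2], n_starts=3)
        for g in g1 + g2:
            g.values = 0.5 * g.values
        scaled = extra_ss_f_test([g1, g2], n_starts=3)
        assert scaled.f_ratio == pytest.approx(res.f_ratio, rel=1e-4)

    def test_power_nondecreasing_in_plateau_separation(self):
        rng = np.random.default_rng(2024)
        base = dict(fast_fraction=0.4, half_fast=60.0, half_slow=1200.0)
        rates = []
        for delta in (0.02, 0.10, 0.25):
            hits = 0
            reps = 25
            for _ in range(reps):
                g1 = simulate_normalized_traces(
                    RecoveryModel(0.55, **base), noise_sd=0.1, n_traces=6, rng=rng
                )
                g2 = simulate_normalized_traces(
                    RecoveryModel(0.55 + delta, **base), noise_sd=0.1, n_traces=6, rng=rng
                )
                hits += extra_ss_f_test([g1, g2], n_starts=2).p_value < 0.05
            rates.append(hits / reps)
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05
        assert rates[2] > rates[0]


class TestRecoveryAtTimepoint:
    def test_identical_groups_null(self, standard_model, rng):
        g = simulate_normalized_traces(standard_model, noise_sd=0.05, n_traces=10, rng=rng)
        res = recovery_at_timepoint([g, g], test="t")
        assert res.p_value > 0.99

    def test_group_means_recover_truth(self, rng):
        models = [
            RecoveryModel(0.53, 0.4, 60.0, 1200.0),
            RecoveryModel(0.73, 0.4, 60.0, 1200.0),
        ]
        groups = [
            simulate_normalized_traces(m, noise_sd=0.05, n_traces=25, rng=rng)
            for m in models
        ]
        res = recovery_at_timepoint(groups, query_time=4080.0)
        for mean, sem, model in zip(res.group_means, res.group_sems, models):
            truth = float(recovery_curve(model, 4080.0))
            assert abs(mean - truth) < 2 * sem + 1e-9

    def test_selects_68_min_sample_exactly(self, standard_model):
        traces = simulate_normalized_traces(standard_model, n_traces=2, noise_sd=0.0)
        res = recovery_at_timepoint([traces, traces], query_time=4080.0, test="t")
        truth = float(recovery_curve(standard_model, 4080.0))
        assert res.group_means[0] == pytest.approx(truth, abs=1e-12)

    def test_missing_timepoint_raises(self, standard_model):
        traces = simulate_normalized_traces(standard_model, n_traces=2, noise_sd=0.0)
        with pytest.raises(MissingTimepointError):
            recovery_at_timepoint([traces, traces], query_time=9000.0)

    def test_mann_whitney_dispatch(self, standard_model, rng):
        g1 = simulate_normalized_traces(standard_model, noise_sd=0.05, n_traces=8, rng=rng)
        g2 = simulate_normalized_traces(standard_model, noise_sd=0.05, n_traces=8, rng=rng)
        res = recovery_at_timepoint([g1, g2], test="mann_whitney")
        assert 0.0 <= res.p_value <= 1.0
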