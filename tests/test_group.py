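"""Group analysis: mean/SEM traces, window means, correlations, thresholds."""

import numpy as np
import pytest

from ftcdlat.group_analysis import (
    critical_r,
    group_trace,
    li_correlation,
    moving_window_correlation,
    window_mean,
)
from ftcdlat.lateralize import DeltaVTrace


def make_trace(dv, subject="S001", fs=25.0):
    dv = np.asarray(dv, dtype=float)
    t = np.arange(len(dv)) / fs - 5.0
    return DeltaVTrace(subject_id=subject, task_label="t", time_axis_s=t, delta_v_pct=dv)


def constant_traces(values):
    return [make_trace(np.full(751, v), subject=f"S{i:03d}") for i, v in enumerate(values)]


class TestGroupTrace:
    def test_identical_subjects_have_zero_sem(self):
        traces = [make_trace(np.linspace(0, 5, 751), subject=s) for s in ("a", "b", "c")]
        out = group_trace(traces)
        assert np.allclose(out.sem_delta_v_pct, 0.0)

    def test_two_constant_subjects(self):
        out = group_trace(constant_traces([1.0, 3.0]))
        assert np.allclose(out.mean_delta_v_pct, 2.0)
        assert np.allclose(out.sem_delta_v_pct, 1.0)  # SD sqrt(2) / sqrt(2)

    def test_negating_cohort_negates_mean(self):
        traces = constant_traces([1.0, 2.0, 4.0])
        neg = [
            DeltaVTrace(t.subject_id, t.task_label, t.time_axis_s, -t.delta_v_pct)
            for t in traces
        ]
        assert np.allclose(
            group_trace(neg).mean_delta_v_pct, -group_trace(traces).mean_delta_v_pct
        )

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_trace(constant_traces([1.0]))


class TestWindowMean:
    def test_constant_trace(self):
        trace = make_trace(np.full(751, 3.3))
        assert window_mean(trace, -2.0, 5.0) == pytest.approx(3.3)

    def test_linear_trace_half_open_mean(self):
        t = np.arange(-125, 626) / 25.0
        trace = make_trace(np.where(t >= 0, t, 0.0))
        # samples 0, 0.04, ..., 4.96 average to 2.5 minus half a step
        assert window_mean(trace, 0.0, 5.0) == pytest.approx(2.48)

    def test_single_sample_window(self):
        t = np.arange(-125, 626) / 25.0
        trace = make_trace(t.copy())
        assert window_mean(trace, 1.0, 1 / 25.0) == pytest.approx(1.0)

    def test_window_outside_trace_raises(self):
        trace = make_trace(np.zeros(751))
        with pytest.raises(ValueError):
            window_mean(trace, 22.0, 5.0)


class TestMovingWindowCorrelation:
    def test_identical_tasks_give_unit_correlation(self):
        a = constant_traces([1.0, 2.0, 3.0, 4.0])
        series = moving_window_correlation(a, a, window_starts_s=np.array([-5.0, 0.0, 5.0]))
        assert np.allclose(series.r_values, 1.0)
        assert np.all(series.p_values <= 1e-12)

    def test_linear_relation_gives_unit_correlation(self):
        a = constant_traces([1.0, 2.0, 3.0, 4.0])
        b = constant_traces([2.0, 4.0, 6.0, 8.0])
        series = moving_window_correlation(a, b, window_starts_s=np.array([0.0]))
        assert series.r_values[0] == pytest.approx(1.0)

    def test_pearson_worked_example(self):
        a = constant_traces([1.0, 2.0, 3.0, 4.0])
        b = constant_traces([1.0, 3.0, 2.0, 4.0])
        series = moving_window_correlation(a, b, window_starts_s=np.array([0.0]))
        assert series.r_values[0] == pytest.approx(0.8)

    def test_zero_variance_window_recorded_as_missing(self):
        a = constant_traces([2.0, 2.0, 2.0, 2.0])  # no between-subject variance
        b = constant_traces([1.0, 2.0, 3.0, 4.0])
        series = moving_window_correlation(a, b, window_starts_s=np.array([0.0]))
        assert np.isnan(series.r_values[0]) and np.isnan(series.p_values[0])

    def test_shift_invariance_of_window_means(self):
        rng = np.random.default_rng(3)
        a = [make_trace(rng.normal(size=751), subject=f"S{i}") for i in range(5)]
        b = [make_trace(rng.normal(size=751), subject=f"S{i}") for i in range(5)]
        starts = np.array([-2.0, 1.0, 8.0])
        base = moving_window_correlation(a, b, window_starts_s=starts)
        shifted_a = [
            DeltaVTrace(t.subject_id, t.task_label, t.time_axis_s, t.delta_v_pct + 7.5)
            for t in a
        ]
        shifted = moving_window_correlation(shifted_a, b, window_starts_s=starts)
        assert np.allclose(base.r_values, shifted.r_values, atol=1e-9)

    def test_unpaired_subjects_rejected(self):
        a = constant_traces([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            moving_window_correlation(a, a[:2])

    def test_agrees_with_li_correlation_on_fixed_window(self):
        rng = np.random.default_rng(4)
        a = [make_trace(np.cumsum(rng.normal(size=751)), subject=f"S{i}") for i in range(6)]
        b = [make_trace(np.cumsum(rng.normal(size=751)), subject=f"S{i}") for i in range(6)]
        start = 2.0
        series = moving_window_correlation(a, b, window_starts_s=np.array([start]))
        wa = np.array([window_mean(t, start, 5.0) for t in a])
        wb = np.array([window_mean(t, start, 5.0) for t in b])
        corr = li_correlation(wa, wb)
        assert corr.r == pytest.approx(series.r_values[0], abs=1e-12)
        assert corr.p == pytest.approx(series.p_values[0], abs=1e-12)


class TestLICorrelation:
    def test_identity_relation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        corr = li_correlation(a, a)
        assert corr.r == pytest.approx(1.0)
        assert corr.slope == pytest.approx(1.0)
        assert corr.intercept == pytest.approx(0.0)

    def test_negation_flips_sign(self):
        a = np.array([1.0, 2.0, 5.0])
        assert li_correlation(a, -a).r == pytest.approx(-1.0)

    def test_pearson_worked_example(self):
        corr = li_correlation(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert corr.r == pytest.approx(0.9819805060619659, abs=1e-9)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            li_correlation(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))


class TestCriticalR:
    def test_monotone_in_n(self):
        values = [critical_r(n) for n in range(3, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_alpha_to_one_limit(self):
        assert critical_r(10, alpha=0.9999) < 1e-3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2)
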