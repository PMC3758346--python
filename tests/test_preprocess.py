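"""Preprocessing chain: cycle detection, integration, epochs, QC, filtering."""

import numpy as np
import pytest

from ftcdlat.preprocess import (
    NoCardiacSignalError,
    NoUsableEpochsError,
    average_and_filter,
    detect_cardiac_cycles,
    integrate_cardiac,
    qc_subject,
    reject_artifacts,
    segment_epochs,
    zero_phase_lowpass,
)
from ftcdlat.synthetic import cardiac_waveform

from conftest import make_carrier_session, make_epochs


class TestDetectCardiacCycles:
    def test_cycle_count_at_sixty_bpm(self):
        session = make_carrier_session(duration_s=120.0, heart_rate_bpm=60.0)
        beats = detect_cardiac_cycles(session)
        # 120 peaks bound 119 inter-peak minima, i.e. 118 complete cycles
        assert abs(beats.n_valid - 119) <= 1

    def test_constant_signal_raises(self):
        n = 25 * 30 + 1
        flat = np.full(n, 50.0)
        session = make_carrier_session(duration_s=30.0, left=flat, right=flat.copy())
        with pytest.raises(NoCardiacSignalError):
            detect_cardiac_cycles(session)

    def test_cycle_means_recover_baseline(self):
        session = make_carrier_session(
            duration_s=60.0, heart_rate_bpm=60.0, baseline_cm_s=50.0
        )
        beats = detect_cardiac_cycles(session)
        assert np.all(np.abs(beats.cycle_mean_left - 50.0) < 0.5)
        assert np.all(np.abs(beats.cycle_mean_right - 50.0) < 0.5)

    def test_short_recording_rejected(self):
        session = make_carrier_session(
            duration_s=8.0, events=((0.0, "control"), (4.0, "target"), (6.0, "control"))
        )
        with pytest.raises(ValueError):
            detect_cardiac_cycles(session)

    def test_boundaries_strictly_increasing_and_physiological(self):
        session = make_carrier_session(duration_s=60.0, heart_rate_bpm=75.0)
        beats = detect_cardiac_cycles(session)
        assert np.all(np.diff(beats.cycle_boundaries_s) > 0)
        durations = np.diff(beats.cycle_boundaries_s)[beats.valid]
        assert np.all(durations >= 60.0 / 200.0) and np.all(durations <= 60.0 / 30.0)


class TestIntegrateCardiac:
    def test_pure_carrier_integrates_to_baseline(self):
        session = make_carrier_session(duration_s=60.0, baseline_cm_s=50.0)
        out = integrate_cardiac(session, detect_cardiac_cycles(session))
        assert out.n_samples == session.n_samples
        assert np.all(np.abs(out.left_velocity - 50.0) <= 0.5)  # within 1 %

    def test_linear_ramp_reproduced_within_one_cycle(self):
        session = make_carrier_session(duration_s=60.0, heart_rate_bpm=60.0)
        t = session.time_s
        ramp = 0.2 * t  # cm/s per s
        session = make_carrier_session(
            duration_s=60.0,
            heart_rate_bpm=60.0,
            left=session.left_velocity + ramp,
            right=session.right_velocity + ramp,
        )
        out = integrate_cardiac(session, detect_cardiac_cycles(session))
        interior = (t > 2) & (t < 58)
        expected = 50.0 + 0.2 * t
        # one cycle lasts 1 s -> tolerate one cycle's worth of ramp lag
        assert np.all(np.abs(out.left_velocity[interior] - expected[interior]) <= 0.2)


class TestSegmentEpochs:
    def test_percent_change_definition(self):
        # constant 50 cm/s with a +10 % step inside the target interval
        session = make_carrier_session(duration_s=120.0, pulsatility_fraction=0.0)
        onset = session.target_onsets_s[0]
        fs = session.sample_rate_hz
        i0 = int(round(onset * fs))
        left = session.left_velocity.copy()
        left[i0 + 100 : i0 + 200] = 55.0
        session = make_carrier_session(
            duration_s=120.0, pulsatility_fraction=0.0, left=left
        )
        epochs = segment_epochs(session)
        assert epochs.n_total == 1
        assert epochs.baseline_left_cm_s[0] == pytest.approx(50.0)
        assert epochs.dv_left_pct[0, 125 + 150] == pytest.approx(10.0)
        assert np.allclose(epochs.dv_right_pct[0], 0.0)

    def test_baseline_mean_of_dv_is_zero(self):
        session = make_carrier_session(duration_s=120.0)
        epochs = segment_epochs(session)
        base = epochs.time_axis_s < 0
        assert abs(epochs.dv_left_pct[0, base].mean()) < 1e-9

    def test_target_count_matches_events(self):
        from ftcdlat.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_subjects=1, n_epochs=20, seed=2)
        sessions, _ = simulate_cohort(cfg)
        epochs = segment_epochs(sessions[0])
        assert epochs.n_total == 20

    def test_onset_too_close_to_edge_is_dropped(self):
        session = make_carrier_session(
            duration_s=40.0,
            events=((0.0, "control"), (2.0, "target"), (30.0, "control")),
        )
        epochs = segment_epochs(session)  # only 2 s of pre-onset signal
        assert epochs.n_total == 0


class TestRejectArtifacts:
    def test_all_zero_epochs_all_good(self):
        epochs = make_epochs(np.zeros((3, 751)), np.zeros((3, 751)))
        out = reject_artifacts(epochs)
        assert out.n_good == 3

    def test_single_sample_over_threshold_rejects_epoch(self):
        dv = np.zeros((2, 751))
        dv[1, 400] = 31.0
        out = reject_artifacts(make_epochs(np.zeros((2, 751)), dv))
        assert list(out.good_flag) == [True, False]

    def test_exactly_thirty_percent_is_kept(self):
        dv = np.zeros((1, 751))
        dv[0, 10] = 30.0
        dv[0, 20] = -30.0
        out = reject_artifacts(make_epochs(dv, np.zeros((1, 751))))
        assert out.n_good == 1

    def test_rejection_is_idempotent(self):
        rng = np.random.default_rng(0)
        dv = rng.normal(0, 20, size=(10, 751))
        epochs = make_epochs(dv, np.zeros((10, 751)))
        once = reject_artifacts(epochs)
        twice = reject_artifacts(once)
        assert np.array_equal(once.good_flag, twice.good_flag)
        assert once.bad_reason == twice.bad_reason


class TestQCSubject:
    def _epochs_with(self, n_good, n_total):
        dv = np.zeros((n_total, 751))
        dv[n_good:, 0] = 100.0
        return reject_artifacts(make_epochs(dv, np.zeros((n_total, 751))))

    def test_exactly_eighty_percent_is_kept(self):
        decision = qc_subject(
            {"a": self._epochs_with(16, 20), "b": self._epochs_with(20, 20)}
        )
        assert decision.keep
        assert decision.fractions == {"a": 0.8, "b": 1.0}

    def test_below_eighty_percent_excludes(self):
        decision = qc_subject(
            {"a": self._epochs_with(15, 20), "b": self._epochs_with(20, 20)}
        )
        assert not decision.keep
        assert "a" in decision.reason

    def test_empty_condition_excludes_with_reason(self):
        decision = qc_subject({"a": self._epochs_with(0, 0)})
        assert not decision.keep and decision.reason is not None

    def test_fractions_match_flag_counts(self):
        epochs = self._epochs_with(7, 10)
        decision = qc_subject({"a": epochs})
        assert decision.n_good["a"] == epochs.n_good == 7
        assert decision.fractions["a"] == pytest.approx(0.7)


class TestFilter:
    def test_unit_dc_gain_on_constant(self):
        y = zero_phase_lowpass(np.full(751, 3.7), 25.0)
        assert np.all(np.abs(y - 3.7) < 1e-6)

    def test_half_amplitude_at_cutoff(self):
        t = np.arange(0, 60, 1 / 25)
        y = zero_phase_lowpass(np.sin(2 * np.pi * 1.0 * t), 25.0, cutoff_hz=1.0)
        interior = y[(t > 10) & (t < 50)]
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(interior**2))
        assert amplitude == pytest.approx(0.5, abs=0.02)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(size=751)) / 10.0
        forward = zero_phase_lowpass(x, 25.0)
        reverse = zero_phase_lowpass(x[::-1], 25.0)
        assert np.allclose(forward, reverse[::-1], atol=1e-9)

    def test_symmetric_input_gives_symmetric_output(self):
        t = np.arange(-375, 376) / 25.0
        x = np.exp(-0.5 * (t / 3.0) ** 2)
        y = zero_phase_lowpass(x, 25.0)
        assert np.allclose(y, y[::-1], atol=1e-9)


class TestAverageAndFilter:
    def test_no_good_epochs_raises(self):
        dv = np.full((2, 751), 100.0)
        epochs = reject_artifacts(make_epochs(dv, dv.copy()))
        with pytest.raises(NoUsableEpochsError):
            average_and_filter(epochs)

    def test_constant_epochs_average_to_constant(self):
        dv = np.stack([np.full(751, 2.0), np.full(751, 4.0)])
        response = average_and_filter(make_epochs(dv, np.zeros((2, 751))))
        assert np.all(np.abs(response.mean_dv_left_pct - 3.0) < 1e-6)
        assert response.n_good_epochs == 2
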