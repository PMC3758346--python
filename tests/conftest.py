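import numpy as np
import pytest

from ftcdlat.preprocess import EpochSet
from ftcdlat.synthetic import RecordingSession, cardiac_waveform


def make_carrier_session(
    duration_s=120.0,
    heart_rate_bpm=60.0,
    baseline_cm_s=50.0,
    sample_rate_hz=25.0,
    pulsatility_fraction=0.5,
    left=None,
    right=None,
    events=None,
):
    """Session whose channels default to a pure constant-rate cardiac carrier."""
    t = np.arange(int(duration_s * sample_rate_hz) + 1) / sample_rate_hz
    carrier = cardiac_waveform(t, heart_rate_bpm, baseline_cm_s, pulsatility_fraction)
    if events is None:
        events = (
            (0.0, "control"),
            (duration_s / 3.0, "target"),
            (2.0 * duration_s / 3.0, "control"),
        )
    return RecordingSession(
        subject_id="S001",
        task_label="carrier",
        sample_rate_hz=sample_rate_hz,
        left_velocity=carrier.copy() if left is None else left,
        right_velocity=carrier.copy() if right is None else right,
        events=events,
    )


def make_epochs(dv_left, dv_right, sample_rate_hz=25.0, subject="S001", task="task"):
    """EpochSet straight from percent-change matrices (epochs x samples)."""
    dv_left = np.asarray(dv_left, dtype=float)
    dv_right = np.asarray(dv_right, dtype=float)
    n, m = dv_left.shape
    t = np.arange(m) / sample_rate_hz - 5.0
    return EpochSet(
        subject_id=subject,
        task_label=task,
        time_axis_s=t,
        dv_left_pct=dv_left,
        dv_right_pct=dv_right,
        baseline_left_cm_s=np.full(n, 50.0),
        baseline_right_cm_s=np.full(n, 50.0),
        good_flag=np.ones(n, dtype=bool),
        bad_reason=(None,) * n,
    )


@pytest.fixture
def epoch_time_axis():
    return np.arange(-125, 626) / 25.0
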