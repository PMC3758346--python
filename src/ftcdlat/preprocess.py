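"""Single-session fTCD preprocessing chain.

Raw bilateral velocity envelopes are turned into epoch-averaged percent
change traces in five steps:

1. cardiac cycle detection on the left (reference) channel,
2. integration over cardiac cycles (per-cycle means, linearly
   interpolated back onto the 25 Hz grid) to strip pulsatility,
3. segmentation into [-5, +25] s epochs around each target onset with
   baseline normalization against the mean velocity over the 5 s
   preceding the onset,
4. rejection of epochs containing physiologically implausible changes
   (|dV| > 30 % on either channel) and a subject-level quality gate
   (every condition needs at least 80 % good epochs),
5. pointwise averaging of the good epochs followed by a second-order
   zero-phase Butterworth low-pass at 1 Hz.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .synthetic import RecordingSession

logger = logging.getLogger(__name__)

#: epoch window relative to target onset, seconds
EPOCH_WINDOW_S = (-5.0, 25.0)
#: baseline window relative to target onset, seconds (half-open)
BASELINE_WINDOW_S = (-5.0, 0.0)
#: physiological cardiac cycle duration bounds, seconds (30-200 bpm)
CYCLE_DURATION_BOUNDS_S = (60.0 / 200.0, 60.0 / 30.0)
#: default epoch rejection threshold, percent change from baseline
REJECT_THRESHOLD_PCT = 30.0
#: default minimum fraction of good epochs per condition
MIN_GOOD_FRACTION = 0.80

__all__ = [
    "BeatSeries",
    "EpochSet",
    "SubjectTaskResponse",
    "QCDecision",
    "NoCardiacSignalError",
    "NoUsableEpochsError",
    "detect_cardiac_cycles",
    "integrate_cardiac",
    "segment_epochs",
    "reject_artifacts",
    "qc_subject",
    "average_and_filter",
    "zero_phase_lowpass",
    "preprocess_session",
]


class NoCardiacSignalError(ValueError):
    """Raised when no plausible cardiac cycles can be detected."""


class NoUsableEpochsError(ValueError):
    """Raised when a session retains zero good epochs."""


@dataclass(frozen=True)
class BeatSeries:
    """Detected cardiac cycles with per-cycle mean velocities.

    ``cycle_boundaries_s`` are successive systolic onsets (waveform feet);
    cycle ``i`` spans ``[boundaries[i], boundaries[i+1])`` and has one mean
    per channel, located at ``cycle_midpoints_s[i]``.  ``valid`` marks
    cycles whose duration lies within physiological heart-rate bounds;
    spurious or merged cycles (e.g. around large artifacts) are flagged
    invalid and skipped by the integration stage.
    """

    cycle_boundaries_s: np.ndarray
    cycle_midpoints_s: np.ndarray
    cycle_mean_left: np.ndarray
    cycle_mean_right: np.ndarray
    valid: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_midpoints_s)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass(frozen=True)
class EpochSet:
    """Onset-locked, baseline-normalized percent-change epochs."""

    subject_id: str
    task_label: str
    time_axis_s: np.ndarray
    dv_left_pct: np.ndarray  # (n_epochs, n_samples)
    dv_right_pct: np.ndarray
    baseline_left_cm_s: np.ndarray
    baseline_right_cm_s: np.ndarray
    good_flag: np.ndarray
    bad_reason: tuple[str | None, ...]

    @property
    def n_total(self) -> int:
        return len(self.good_flag)

    @property
    def n_good(self) -> int:
        return int(np.count_nonzero(self.good_flag))


@dataclass(frozen=True)
class SubjectTaskResponse:
    """Averaged, low-pass-filtered percent-change traces for one session."""

    subject_id: str
    task_label: str
    time_axis_s: np.ndarray
    mean_dv_left_pct: np.ndarray
    mean_dv_right_pct: np.ndarray
    n_good_epochs: int


@dataclass(frozen=True)
class QCDecision:
    """Subject-level keep/exclude decision with per-condition fractions."""

    keep: bool
    fractions: dict[str, float]
    n_good: dict[str, int]
    n_total: dict[str, int]
    reason: str | None = None


def detect_cardiac_cycles(session: RecordingSession) -> BeatSeries:
    """Detect cardiac cycles on the left channel and integrate both channels.

    Systolic peaks are located with a minimum spacing of 0.3 s (200 bpm)
    and a prominence threshold of one quarter of the robust signal range;
    cycle boundaries are the velocity minima (systolic onsets) between
    successive peaks.  Both channels share the same heart, so the left
    channel's boundaries are applied to both, guaranteeing identical
    integration windows for the later left-minus-right subtraction.
    """
    fs = session.sample_rate_hz
    if session.duration_s < 10.0:
        raise ValueError("need at least 10 s of signal for cycle detection")
    x = session.left_velocity
    prominence = 0.25 * (np.percentile(x, 95) - np.percentile(x, 5))
    if prominence <= 0:
        raise NoCardiacSignalError("constant signal: no cardiac pulsatility")
    peaks, _ = find_peaks(
        x,
        distance=max(1, int(round(CYCLE_DURATION_BOUNDS_S[0] * fs))),
        prominence=prominence,
    )
    if len(peaks) < 2:
        raise NoCardiacSignalError("fewer than 5 detectable cardiac cycles")
    boundaries = np.empty(len(peaks) - 1, dtype=np.intp)
    for i in range(len(peaks) - 1):
        seg = x[peaks[i] : peaks[i + 1]]
        boundaries[i] = peaks[i] + int(np.argmin(seg))
    if len(boundaries) < 6:  # need >= 5 inter-boundary cycles
        raise NoCardiacSignalError("fewer than 5 detectable cardiac cycles")
    durations = np.diff(boundaries) / fs
    lo, hi = CYCLE_DURATION_BOUNDS_S
    valid = (durations >= lo) & (durations <= hi)
    if np.count_nonzero(valid) < 5:
        raise NoCardiacSignalError("fewer than 5 detectable cardiac cycles")
    mean_left = np.array(
        [session.left_velocity[a:b].mean() for a, b in zip(boundaries, boundaries[1:])]
    )
    mean_right = np.array(
        [session.right_velocity[a:b].mean() for a, b in zip(boundaries, boundaries[1:])]
    )
    boundaries_s = boundaries / fs
    midpoints_s = 0.5 * (boundaries_s[:-1] + boundaries_s[1:])
    return BeatSeries(
        cycle_boundaries_s=boundaries_s,
        cycle_midpoints_s=midpoints_s,
        cycle_mean_left=mean_left,
        cycle_mean_right=mean_right,
        valid=valid,
    )


def integrate_cardiac(session: RecordingSession, beats: BeatSeries) -> RecordingSession:
    """Replace both channels by cycle means interpolated on the original grid.

    Per-cycle means are placed at cycle midpoints, linearly interpolated
    between them, and held constant before the first / after the last
    midpoint.  Pulsatility is removed; slow hemodynamics are preserved.
    Cycles flagged invalid by the detector are skipped.
    """
    t = session.time_s
    mids = beats.cycle_midpoints_s[beats.valid]
    left = np.interp(t, mids, beats.cycle_mean_left[beats.valid])
    right = np.interp(t, mids, beats.cycle_mean_right[beats.valid])
    return dataclasses.replace(session, left_velocity=left, right_velocity=right)


def segment_epochs(session: RecordingSession) -> EpochSet:
    """Extract [-5, +25] s epochs around target onsets and normalize.

    Per epoch and channel the baseline V_b is the mean velocity over the
    five seconds preceding the onset, and the trace is converted to
    percent change dv(t) = 100 (V(t) - V_b) / V_b.  Target onsets without
    5 s of preceding or 25 s of following signal are dropped with a
    warning; epochs with non-positive baselines are flagged bad.
    """
    fs = session.sample_rate_hz
    pre = int(round(-EPOCH_WINDOW_S[0] * fs))
    post = int(round(EPOCH_WINDOW_S[1] * fs))
    time_axis = np.arange(-pre, post + 1) / fs
    n_base = int(round((BASELINE_WINDOW_S[1] - BASELINE_WINDOW_S[0]) * fs))

    dv_left, dv_right, base_left, base_right, good, reasons = [], [], [], [], [], []
    for onset in session.target_onsets_s:
        i0 = int(round(onset * fs))
        if i0 - pre < 0 or i0 + post >= session.n_samples:
            logger.warning(
                "dropping target onset at %.2f s in %s/%s: epoch window "
                "outside the recording",
                onset,
                session.subject_id,
                session.task_label,
            )
            continue
        epoch_ok = True
        reason = None
        dvs, bases = [], []
        for chan in (session.left_velocity, session.right_velocity):
            seg = chan[i0 - pre : i0 + post + 1]
            vb = seg[:n_base].mean()
            bases.append(vb)
            if vb <= 0:
                epoch_ok = False
                reason = "invalid baseline"
                dvs.append(np.zeros_like(seg))
            else:
                dvs.append(100.0 * (seg - vb) / vb)
        dv_left.append(dvs[0])
        dv_right.append(dvs[1])
        base_left.append(bases[0])
        base_right.append(bases[1])
        good.append(epoch_ok)
        reasons.append(reason)

    n = len(good)
    shape = (n, len(time_axis))
    return EpochSet(
        subject_id=session.subject_id,
        task_label=session.task_label,
        time_axis_s=time_axis,
        dv_left_pct=np.array(dv_left).reshape(shape),
        dv_right_pct=np.array(dv_right).reshape(shape),
        baseline_left_cm_s=np.array(base_left),
        baseline_right_cm_s=np.array(base_right),
        good_flag=np.array(good, dtype=bool),
        bad_reason=tuple(reasons),
    )


def reject_artifacts(
    epochs: EpochSet, threshold_pct: float = REJECT_THRESHOLD_PCT
) -> EpochSet:
    """Flag epochs with physiologically implausible velocity changes.

    An epoch is bad if |dv| strictly exceeds ``threshold_pct`` at any
    sample of either channel anywhere in the epoch window (a sample at
    exactly the threshold is kept).  Idempotent; previously bad epochs
    (e.g. invalid baseline) stay bad.
    """
    exceeded = (
        np.abs(epochs.dv_left_pct).max(axis=1) > threshold_pct
    ) | (np.abs(epochs.dv_right_pct).max(axis=1) > threshold_pct)
    good = epochs.good_flag & ~exceeded
    reasons = tuple(
        old if old is not None else ("artifact" if bad else None)
        for old, bad in zip(epochs.bad_reason, exceeded)
    )
    for i in np.nonzero(exceeded)[0]:
        logger.debug(
            "epoch %d of %s/%s rejected: |dv| > %.0f%%",
            i,
            epochs.subject_id,
            epochs.task_label,
            threshold_pct,
        )
    return dataclasses.replace(epochs, good_flag=good, bad_reason=reasons)


def qc_subject(
    per_condition: Mapping[str, EpochSet],
    min_good_fraction: float = MIN_GOOD_FRACTION,
) -> QCDecision:
    """Subject-level quality gate across conditions.

    The subject is excluded iff any condition has strictly fewer than
    ``min_good_fraction`` good epochs (exactly 80 % is retained).
    """
    fractions: dict[str, float] = {}
    n_good: dict[str, int] = {}
    n_total: dict[str, int] = {}
    reason = None
    keep = True
    for task, epochs in per_condition.items():
        n_good[task] = epochs.n_good
        n_total[task] = epochs.n_total
        if epochs.n_total == 0:
            fractions[task] = 0.0
            keep = False
            reason = f"condition '{task}' has no epochs"
            continue
        frac = epochs.n_good / epochs.n_total
        fractions[task] = frac
        if frac < min_good_fraction:
            keep = False
            reason = (
                f"condition '{task}' has {epochs.n_good}/{epochs.n_total} good "
                f"epochs (< {min_good_fraction:.0%})"
            )
    return QCDecision(
        keep=keep, fractions=fractions, n_good=n_good, n_total=n_total, reason=reason
    )


def zero_phase_lowpass(
    x: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 1.0,
    order: int = 2,
    pad_s: float = 5.0,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass with reflective edge padding.

    The forward-backward pass squares the magnitude response (gain 1/2 at
    the cutoff for two passes of -3 dB) and cancels phase, so the output
    of a time-reversed input is the time-reversed output.  Reflective
    padding of ``pad_s`` seconds on each side keeps the filter transient
    off the short epoch window; Gustafsson initial conditions make the
    forward-backward and backward-forward results identical.
    """
    b, a = butter(order, cutoff_hz, fs=sample_rate_hz)
    pad = int(round(pad_s * sample_rate_hz))
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="reflect")
    y = filtfilt(b, a, xp, method="gust")
    return y[pad : len(y) - pad]


def average_and_filter(
    epochs: EpochSet, cutoff_hz: float = 1.0, order: int = 2
) -> SubjectTaskResponse:
    """Average the good epochs pointwise, then low-pass the averages."""
    if epochs.n_good == 0:
        raise NoUsableEpochsError(
            f"no usable epochs for {epochs.subject_id}/{epochs.task_label}"
        )
    fs = 1.0 / float(epochs.time_axis_s[1] - epochs.time_axis_s[0])
    mean_left = epochs.dv_left_pct[epochs.good_flag].mean(axis=0)
    mean_right = epochs.dv_right_pct[epochs.good_flag].mean(axis=0)
    return SubjectTaskResponse(
        subject_id=epochs.subject_id,
        task_label=epochs.task_label,
        time_axis_s=epochs.time_axis_s,
        mean_dv_left_pct=zero_phase_lowpass(mean_left, fs, cutoff_hz, order),
        mean_dv_right_pct=zero_phase_lowpass(mean_right, fs, cutoff_hz, order),
        n_good_epochs=epochs.n_good,
    )


def preprocess_session(
    session: RecordingSession,
    cutoff_hz: float = 1.0,
    order: int = 2,
    threshold_pct: float = REJECT_THRESHOLD_PCT,
) -> tuple[EpochSet, SubjectTaskResponse]:
    """Run the full single-session chain; returns the screened epochs too."""
    beats = detect_cardiac_cycles(session)
    integrated = integrate_cardiac(session, beats)
    epochs = reject_artifacts(segment_epochs(integrated), threshold_pct)
    return epochs, average_and_filter(epochs, cutoff_hz, order)
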