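"""Synthetic bilateral CBFV cohort simulator.

Generates recordings that emulate a dual-probe functional transcranial
Doppler (fTCD) experiment: blood-flow-velocity envelopes for the left and
right middle cerebral arteries, sampled at 25 Hz, with

* a pulsatile cardiac carrier riding on a subject-specific baseline
  velocity (sharp systolic upstroke, slower diastolic decay, slow
  heart-rate drift within a session),
* an alternating control/target event schedule (targets 25-35 s, controls
  15-25 s, a fixed number of target epochs per block),
* task-locked hemodynamic responses with per-hemisphere amplitudes whose
  left-minus-right difference carries a subject-level lateralization
  trait shared (with configurable correlation) across two tasks,
* white measurement noise, and occasional large square-pulse artifacts
  big enough to trip a +/-30 % rejection rule downstream.

Every draw flows from ``SimulationConfig.seed`` so identical configs give
bit-identical cohorts, and the generator returns the injected ground
truth so downstream estimators can be validated against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

TARGET = "target"
CONTROL = "control"

#: fraction of the cardiac cycle taken by the systolic upstroke
SYSTOLIC_RISE_FRACTION = 0.25

#: period of the slow within-session heart-rate drift, seconds
HEART_RATE_DRIFT_PERIOD_S = 120.0

__all__ = [
    "SimulationConfig",
    "RecordingSession",
    "SubjectPhysiology",
    "cardiac_waveform",
    "hemodynamic_response",
    "simulate_session",
    "simulate_cohort",
    "inject_square_artifact",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions this simulator emulates:
    20 target epochs per block, targets 25-35 s and controls 15-25 s,
    envelopes sampled at 25 Hz, and two tasks (cued word generation,
    left-dominant; Acheulean knapping, right-dominant) whose subject
    lateralization traits are positively correlated.
    """

    n_subjects: int = 10
    sample_rate_hz: float = 25.0
    n_epochs: int = 20
    target_duration_range_s: tuple[float, float] = (25.0, 35.0)
    control_duration_range_s: tuple[float, float] = (15.0, 25.0)
    heart_rate_bpm_range: tuple[float, float] = (55.0, 85.0)
    baseline_velocity_cm_s_range: tuple[float, float] = (45.0, 65.0)
    pulsatility_fraction: float = 0.5
    heart_rate_drift_fraction: float = 0.05
    hrf_peak_delay_s: float = 6.0
    hrf_width_s: float = 4.0
    hrf_plateau_fraction: float = 0.8
    initial_dip_pct: float = 0.0
    effect_left_pct: dict[str, float] = field(
        default_factory=lambda: {"word_generation": 5.0, "knapping": 2.0}
    )
    effect_right_pct: dict[str, float] = field(
        default_factory=lambda: {"word_generation": 2.0, "knapping": 6.0}
    )
    trait_sd_pct: float = 2.5
    trait_cross_task_correlation: float = 0.75
    noise_sd_pct: float = 3.0
    artifact_rate_per_epoch: float = 0.05
    artifact_amplitude_pct: float = 60.0
    artifact_duration_range_s: tuple[float, float] = (1.2, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        for name in (
            "target_duration_range_s",
            "control_duration_range_s",
            "heart_rate_bpm_range",
            "baseline_velocity_cm_s_range",
            "artifact_duration_range_s",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval (lo <= hi)")
        if not 0 <= self.pulsatility_fraction < 1:
            raise ValueError("pulsatility_fraction must be in [0, 1)")
        if not -1 <= self.trait_cross_task_correlation <= 1:
            raise ValueError("trait_cross_task_correlation must be in [-1, 1]")
        if self.trait_sd_pct < 0 or self.noise_sd_pct < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.artifact_rate_per_epoch <= 1:
            raise ValueError("artifact_rate_per_epoch must be a probability")
        if self.artifact_amplitude_pct <= 30:
            raise ValueError(
                "artifact_amplitude_pct must exceed 30 so injected artifacts "
                "trip the rejection rule"
            )
        if self.hrf_width_s <= 0 or self.hrf_peak_delay_s <= 0:
            raise ValueError("hemodynamic response delay and width must be positive")
        if set(self.effect_left_pct) != set(self.effect_right_pct):
            raise ValueError("effect_left_pct and effect_right_pct must list the same tasks")

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(self.effect_left_pct)


@dataclass(frozen=True)
class SubjectPhysiology:
    """Per-subject physiology and injected per-task response amplitudes."""

    subject_id: str
    heart_rate_bpm: float
    baseline_left_cm_s: float
    baseline_right_cm_s: float
    latent_trait: float
    amp_left_pct: dict[str, float]
    amp_right_pct: dict[str, float]


@dataclass(frozen=True)
class RecordingSession:
    """One subject x one task: bilateral velocity envelopes plus events.

    ``events`` is an ordered list of ``(onset_s, kind)`` with kinds
    strictly alternating control/target; the first and last intervals are
    controls so that every target epoch has a full 5 s pre-onset baseline.
    """

    subject_id: str
    task_label: str
    sample_rate_hz: float
    left_velocity: np.ndarray
    right_velocity: np.ndarray
    events: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        if len(self.left_velocity) != len(self.right_velocity):
            raise ValueError("left and right channels must have equal length")
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        kinds = [k for _, k in self.events]
        if kinds and (kinds[0] != CONTROL or kinds[-1] != CONTROL):
            raise ValueError("first and last intervals must be controls")
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValueError("event kinds must strictly alternate")

    @property
    def n_samples(self) -> int:
        return len(self.left_velocity)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def target_onsets_s(self) -> np.ndarray:
        return np.array([t for t, k in self.events if k == TARGET])


def _cardiac_shape(phase: np.ndarray) -> np.ndarray:
    """Within-cycle waveform shape on phase in [0, 1): zero-mean, unit peak-to-trough.

    Fast systolic upstroke over the first quarter cycle (half raised
    cosine 0 -> 1), slower diastolic decay over the remaining three
    quarters (half raised cosine 1 -> 0).  Each half-cosine segment
    averages 0.5 over its support, so the cycle mean is exactly 0.5
    before centring, independent of the rise fraction.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    a = SYSTOLIC_RISE_FRACTION
    rising = phase < a
    s = np.empty_like(phase)
    s[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / a))
    s[~rising] = 0.5 * (1.0 + np.cos(np.pi * (phase[~rising] - a) / (1.0 - a)))
    return s - 0.5


def cardiac_waveform(
    time_s: np.ndarray,
    heart_rate_bpm: float,
    baseline_cm_s: float,
    pulsatility_fraction: float,
) -> np.ndarray:
    """Pulsatile velocity carrier at a constant heart rate.

    Strictly positive and periodic with period ``60 / heart_rate_bpm``;
    peak-to-trough modulation is ``pulsatility_fraction`` of the baseline
    and the cycle mean equals ``baseline_cm_s`` exactly.
    """
    if heart_rate_bpm <= 0:
        raise ValueError("heart_rate_bpm must be positive")
    if baseline_cm_s <= 0:
        raise ValueError("baseline_cm_s must be positive")
    if not 0 <= pulsatility_fraction < 1:
        raise ValueError("pulsatility_fraction must be in [0, 1)")
    phase = np.asarray(time_s, dtype=float) * (heart_rate_bpm / 60.0)
    return baseline_cm_s * (1.0 + pulsatility_fraction * _cardiac_shape(phase))


def hemodynamic_response(
    time_since_onset_s: np.ndarray,
    amplitude_pct: float,
    peak_delay_s: float = 6.0,
    width_s: float = 4.0,
    plateau_fraction: float = 0.8,
) -> np.ndarray:
    """Task-locked percent velocity change as a function of time since onset.

    Shape: zero for negative times, half-raised-cosine ramp from 0 at
    onset to ``amplitude_pct`` at ``peak_delay_s``, then a Gaussian settle
    (scale ``width_s``) from the peak down to a sustained plateau of
    ``plateau_fraction * amplitude_pct``.  The curve is C1 at the peak and
    its maximum magnitude sits exactly at ``peak_delay_s``.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    if peak_delay_s <= 0:
        raise ValueError("peak_delay_s must be positive")
    if not 0 <= plateau_fraction <= 1:
        raise ValueError("plateau_fraction must be in [0, 1]")
    t = np.asarray(time_since_onset_s, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t <= peak_delay_s)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / peak_delay_s))
    after = t > peak_delay_s
    out[after] = plateau_fraction + (1.0 - plateau_fraction) * np.exp(
        -0.5 * ((t[after] - peak_delay_s) / width_s) ** 2
    )
    return amplitude_pct * out


def _offset_decay(time_since_offset_s: np.ndarray, width_s: float) -> np.ndarray:
    """Smooth return to baseline after the target interval ends."""
    t = np.asarray(time_since_offset_s, dtype=float)
    out = np.ones_like(t)
    after = t > 0
    out[after] = np.exp(-0.5 * (t[after] / width_s) ** 2)
    return out


def _draw_intervals(config: SimulationConfig, rng: Generator) -> list[tuple[float, str]]:
    """Alternating (duration, kind) schedule: control, (target, control) x n."""
    lo_c, hi_c = config.control_duration_range_s
    lo_t, hi_t = config.target_duration_range_s
    intervals = [(rng.uniform(lo_c, hi_c), CONTROL)]
    for _ in range(config.n_epochs):
        intervals.append((rng.uniform(lo_t, hi_t), TARGET))
        intervals.append((rng.uniform(lo_c, hi_c), CONTROL))
    return intervals


def simulate_session(
    config: SimulationConfig,
    subject: SubjectPhysiology,
    task_label: str,
    rng: Generator,
) -> RecordingSession:
    """Simulate one recording session (one subject performing one task)."""
    fs = config.sample_rate_hz
    intervals = _draw_intervals(config, rng)
    durations = np.array([d for d, _ in intervals])
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    events = tuple((float(t), kind) for t, (_, kind) in zip(onsets, intervals))
    total_s = float(durations.sum())
    n = int(np.floor(total_s * fs)) + 1
    t = np.arange(n) / fs

    # cardiac carrier with slow heart-rate drift, shared by both arteries
    drift_phase = rng.uniform(0, 2 * np.pi)
    rate_hz = (subject.heart_rate_bpm / 60.0) * (
        1.0
        + config.heart_rate_drift_fraction
        * np.sin(2 * np.pi * t / HEART_RATE_DRIFT_PERIOD_S + drift_phase)
    )
    phase = np.cumsum(rate_hz) / fs
    carrier = 1.0 + config.pulsatility_fraction * _cardiac_shape(phase)

    # task-locked hemodynamic modulation, percent of baseline per channel
    mod_left = np.zeros(n)
    mod_right = np.zeros(n)
    amp_left = subject.amp_left_pct[task_label]
    amp_right = subject.amp_right_pct[task_label]
    for onset, (dur, kind) in zip(onsets, intervals):
        if kind != TARGET:
            continue
        t_rel = t - onset
        shape = hemodynamic_response(
            t_rel,
            1.0,
            config.hrf_peak_delay_s,
            config.hrf_width_s,
            config.hrf_plateau_fraction,
        ) * _offset_decay(t_rel - dur, config.hrf_width_s)
        if config.initial_dip_pct > 0:
            dip = np.zeros(n)
            early = (t_rel >= 0) & (t_rel <= 4.0)
            dip[early] = np.exp(-0.5 * ((t_rel[early] - 1.0) / 0.5) ** 2)
            mod_left -= config.initial_dip_pct * dip
            mod_right -= config.initial_dip_pct * dip
        mod_left += amp_left * shape
        mod_right += amp_right * shape

    noise_sd = config.noise_sd_pct / 100.0
    left = subject.baseline_left_cm_s * (
        (1.0 + mod_left / 100.0) * carrier + noise_sd * rng.standard_normal(n)
    )
    right = subject.baseline_right_cm_s * (
        (1.0 + mod_right / 100.0) * carrier + noise_sd * rng.standard_normal(n)
    )

    # occasional large square-pulse artifacts within target intervals
    lo_d, hi_d = config.artifact_duration_range_s
    for onset, (dur, kind) in zip(onsets, intervals):
        if kind != TARGET:
            continue
        if rng.random() >= config.artifact_rate_per_epoch:
            continue
        d = rng.uniform(lo_d, min(hi_d, dur))
        start = onset + rng.uniform(0.0, dur - d)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        channel, base = (
            (left, subject.baseline_left_cm_s)
            if rng.random() < 0.5
            else (right, subject.baseline_right_cm_s)
        )
        i0 = int(np.round(start * fs))
        i1 = int(np.round((start + d) * fs))
        channel[i0:i1] += sign * (config.artifact_amplitude_pct / 100.0) * base

    # envelope velocities never cross zero in vivo
    np.maximum(left, 0.1, out=left)
    np.maximum(right, 0.1, out=right)

    return RecordingSession(
        subject_id=subject.subject_id,
        task_label=task_label,
        sample_rate_hz=fs,
        left_velocity=left,
        right_velocity=right,
        events=events,
    )


def inject_square_artifact(
    session: RecordingSession,
    start_s: float,
    duration_s: float,
    amplitude_pct: float,
    channel: str = "left",
) -> RecordingSession:
    """Return a copy of ``session`` with a square velocity pulse added.

    The pulse amplitude is ``amplitude_pct`` percent of the affected
    channel's median velocity, which downstream baseline normalization
    maps onto (approximately) the same percent change.
    """
    if channel not in ("left", "right"):
        raise ValueError("channel must be 'left' or 'right'")
    fs = session.sample_rate_hz
    i0 = int(np.round(start_s * fs))
    i1 = int(np.round((start_s + duration_s) * fs))
    if not (0 <= i0 < i1 <= session.n_samples):
        raise ValueError("artifact window outside the recording")
    left = session.left_velocity.copy()
    right = session.right_velocity.copy()
    target = left if channel == "left" else right
    target[i0:i1] += (amplitude_pct / 100.0) * np.median(target)
    return dataclasses.replace(session, left_velocity=left, right_velocity=right)


def _draw_subjects(config: SimulationConfig, rng: Generator) -> list[SubjectPhysiology]:
    tasks = config.tasks
    rho = config.trait_cross_task_correlation
    subjects = []
    for i in range(config.n_subjects):
        z = rng.standard_normal()
        e = rng.standard_normal()
        traits = {tasks[0]: config.trait_sd_pct * z}
        for extra in tasks[1:]:
            traits[extra] = config.trait_sd_pct * (
                rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * e
            )
        hr = rng.uniform(*config.heart_rate_bpm_range)
        base_l = rng.uniform(*config.baseline_velocity_cm_s_range)
        base_r = rng.uniform(*config.baseline_velocity_cm_s_range)
        subjects.append(
            SubjectPhysiology(
                subject_id=f"S{i + 1:03d}",
                heart_rate_bpm=hr,
                baseline_left_cm_s=base_l,
                baseline_right_cm_s=base_r,
                latent_trait=z,
                amp_left_pct={
                    task: config.effect_left_pct[task] + traits[task] / 2.0
                    for task in tasks
                },
                amp_right_pct={
                    task: config.effect_right_pct[task] - traits[task] / 2.0
                    for task in tasks
                },
            )
        )
    return subjects


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[RecordingSession], pd.DataFrame]:
    """Simulate one session per subject per task, plus the injected truth.

    Returns ``(sessions, truth)`` where ``truth`` holds one row per
    subject x task with the injected left-minus-right response amplitude
    (``true_delta_v_pct``) and the subject's latent lateralization trait.
    """
    root = SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects + 1)
    subjects = _draw_subjects(config, default_rng(subject_seeds[0]))
    sessions: list[RecordingSession] = []
    rows = []
    for subject, seed in zip(subjects, subject_seeds[1:]):
        task_seeds = seed.spawn(len(config.tasks))
        for task, task_seed in zip(config.tasks, task_seeds):
            sessions.append(
                simulate_session(config, subject, task, default_rng(task_seed))
            )
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "task_label": task,
                    "true_delta_v_pct": subject.amp_left_pct[task]
                    - subject.amp_right_pct[task],
                    "latent_trait": subject.latent_trait,
                }
            )
    return sessions, pd.DataFrame(rows)
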