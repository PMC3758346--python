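"""Group-level analysis: mean traces, LI correlation, moving-window correlation.

Three group results are computed over a cohort of per-subject dV traces:

* the pointwise mean dV trace per task with its SEM band,
* the cross-task Pearson correlation of the subjects' lateralization
  indices, with a least-squares fit for scatter plotting,
* the Pearson correlation, across subjects, of the two tasks' mean dV
  computed over a moving 5 s window whose start offset slides from 5 s
  before to 15 s after task onset, together with the uncorrected
  two-sided significance threshold for the cohort size.

p-values are two-sided and uncorrected across window offsets; windows
with zero variance in either task are recorded as missing (NaN), not 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lateralize import DeltaVTrace

#: moving-window start offsets, seconds relative to target onset
WINDOW_START_RANGE_S = (-5.0, 15.0)
#: moving analysis window length, seconds
WINDOW_LENGTH_S = 5.0

__all__ = [
    "GroupTrace",
    "WindowCorrelationSeries",
    "LICorrelation",
    "group_trace",
    "window_mean",
    "moving_window_correlation",
    "li_correlation",
    "critical_r",
]


@dataclass(frozen=True)
class GroupTrace:
    """Mean dV trace across subjects with pointwise SEM."""

    task_label: str
    time_axis_s: np.ndarray
    mean_delta_v_pct: np.ndarray
    sem_delta_v_pct: np.ndarray
    n_subjects: int


@dataclass(frozen=True)
class WindowCorrelationSeries:
    """Cross-task correlation of subject window means vs. window start."""

    window_starts_s: np.ndarray
    window_length_s: float
    r_values: np.ndarray
    p_values: np.ndarray
    r_critical: float
    n_subjects: int
    window_means_a: np.ndarray  # (n_subjects, n_windows)
    window_means_b: np.ndarray


@dataclass(frozen=True)
class LICorrelation:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def group_trace(traces: list[DeltaVTrace], task_label: str | None = None) -> GroupTrace:
    """Pointwise mean and SEM of dV across subjects for one task."""
    if len(traces) < 2:
        raise ValueError("SEM needs at least 2 subjects")
    t = traces[0].time_axis_s
    for tr in traces[1:]:
        if len(tr.time_axis_s) != len(t) or not np.allclose(tr.time_axis_s, t):
            raise ValueError("all traces must share one time grid")
    stacked = np.vstack([tr.delta_v_pct for tr in traces])
    return GroupTrace(
        task_label=task_label or traces[0].task_label,
        time_axis_s=t,
        mean_delta_v_pct=stacked.mean(axis=0),
        sem_delta_v_pct=stacked.std(axis=0, ddof=1) / np.sqrt(len(traces)),
        n_subjects=len(traces),
    )


def window_mean(trace: DeltaVTrace, start_s: float, length_s: float) -> float:
    """Mean of dV over the half-open sample interval [start, start + length)."""
    t = trace.time_axis_s
    dt = float(t[1] - t[0])
    eps = 1e-9
    if start_s < t[0] - eps or start_s + length_s > t[-1] + dt + eps:
        raise ValueError("window outside the trace span")
    sel = (t >= start_s - eps) & (t < start_s + length_s - eps)
    if not np.any(sel):
        raise ValueError("window contains no samples")
    return float(trace.delta_v_pct[sel].mean())


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p via the t transform with n - 2 df."""
    n = len(a)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((da * db).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(tval), n - 2)
    return r, float(p)


def moving_window_correlation(
    traces_a: list[DeltaVTrace],
    traces_b: list[DeltaVTrace],
    window_starts_s: np.ndarray | None = None,
    window_length_s: float = WINDOW_LENGTH_S,
    alpha: float = 0.05,
) -> WindowCorrelationSeries:
    """Cross-task Pearson r of subject window means at each start offset.

    ``traces_a`` and ``traces_b`` are paired by position (one subject per
    index, two tasks).  The default start grid runs from -5 to +15 s in
    steps of one sample.
    """
    if len(traces_a) != len(traces_b):
        raise ValueError("tasks must be paired by subject")
    n = len(traces_a)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    for ta, tb in zip(traces_a, traces_b):
        if ta.subject_id != tb.subject_id:
            raise ValueError("tasks must be paired by subject")
    t = traces_a[0].time_axis_s
    dt = float(t[1] - t[0])
    if window_starts_s is None:
        lo, hi = WINDOW_START_RANGE_S
        window_starts_s = np.arange(lo, hi + dt / 2, dt)
    n_win = len(window_starts_s)
    means_a = np.empty((n, n_win))
    means_b = np.empty((n, n_win))
    for j, start in enumerate(window_starts_s):
        for i in range(n):
            means_a[i, j] = window_mean(traces_a[i], start, window_length_s)
            means_b[i, j] = window_mean(traces_b[i], start, window_length_s)
    r_values = np.empty(n_win)
    p_values = np.empty(n_win)
    for j in range(n_win):
        r_values[j], p_values[j] = _pearson(means_a[:, j], means_b[:, j])
    return WindowCorrelationSeries(
        window_starts_s=np.asarray(window_starts_s, dtype=float),
        window_length_s=window_length_s,
        r_values=r_values,
        p_values=p_values,
        r_critical=critical_r(n, alpha),
        n_subjects=n,
        window_means_a=means_a,
        window_means_b=means_b,
    )


def li_correlation(
    li_task_a: np.ndarray, li_task_b: np.ndarray
) -> LICorrelation:
    """Pearson correlation of paired subject LIs with a linear fit."""
    a = np.asarray(li_task_a, dtype=float)
    b = np.asarray(li_task_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("LI lists must be paired 1-d arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    fit = stats.linregress(a, b)
    r, p = _pearson(a, b)
    return LICorrelation(
        r=r, p=p, slope=float(fit.slope), intercept=float(fit.intercept), n=len(a)
    )


def critical_r(n_subjects: int, alpha: float = 0.05) -> float:
    """|r| above which the two-sided p < alpha with n - 2 degrees of freedom."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = n_subjects - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))
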