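"""Lateralization measures: the left-minus-right trace and the LI.

The relative blood-flow lateralization dV(t) is the pointwise difference
between the left and right hemisphere percent-change traces.  The
lateralization index (LI) is the mean of dV over a short integration
window (default 2 s) centred at the time of peak |dV| within an
activation window (default 2-18 s after target onset).  Positive LI
means left-hemisphere dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SubjectTaskResponse

#: default activation window for the peak search, seconds after onset
ACTIVATION_WINDOW_S = (2.0, 18.0)
#: default LI integration interval, seconds
T_INT_S = 2.0

__all__ = ["DeltaVTrace", "LIResult", "delta_v", "lateralization_index"]


@dataclass(frozen=True)
class DeltaVTrace:
    """Left-minus-right percent-change trace for one subject and task."""

    subject_id: str
    task_label: str
    time_axis_s: np.ndarray
    delta_v_pct: np.ndarray


@dataclass(frozen=True)
class LIResult:
    """Signed lateralization index with its peak time and window."""

    subject_id: str
    task_label: str
    li_pct: float
    t_max_s: float
    window_s: tuple[float, float]
    activation_window_s: tuple[float, float]
    t_int_s: float


def delta_v(response: SubjectTaskResponse) -> DeltaVTrace:
    """Pointwise left-minus-right difference; no filtering or rescaling."""
    if len(response.mean_dv_left_pct) != len(response.mean_dv_right_pct) or len(
        response.mean_dv_left_pct
    ) != len(response.time_axis_s):
        raise ValueError("left/right traces must share one time grid")
    return DeltaVTrace(
        subject_id=response.subject_id,
        task_label=response.task_label,
        time_axis_s=response.time_axis_s,
        delta_v_pct=response.mean_dv_left_pct - response.mean_dv_right_pct,
    )


def lateralization_index(
    trace: DeltaVTrace,
    activation_window_s: tuple[float, float] = ACTIVATION_WINDOW_S,
    t_int_s: float = T_INT_S,
) -> LIResult:
    """Signed LI: integral mean of dV over a window centred at the peak.

    The peak time ``t_max`` is the argmax of |dV| over the activation
    window (earliest sample on ties); the LI is the trapezoidal mean of
    dV over ``[t_max - t_int/2, t_max + t_int/2]``, clipped to the trace
    extent if the peak sits near an edge.  The trapezoidal (integral)
    mean is exact for piecewise-linear traces and reduces to the
    arithmetic mean for slowly varying ones.
    """
    if t_int_s <= 0:
        raise ValueError("t_int_s must be positive")
    t = trace.time_axis_s
    dv = trace.delta_v_pct
    lo, hi = activation_window_s
    eps = 1e-9
    mask = (t >= lo - eps) & (t <= hi + eps)
    if not np.any(mask):
        raise ValueError("activation window contains no samples")
    idx_window = np.nonzero(mask)[0]
    i_max = idx_window[int(np.argmax(np.abs(dv[mask])))]
    t_max = float(t[i_max])
    half = t_int_s / 2.0
    w_lo = max(t_max - half, float(t[0]))
    w_hi = min(t_max + half, float(t[-1]))
    sel = (t >= w_lo - eps) & (t <= w_hi + eps)
    t_sel = t[sel]
    li = float(np.trapezoid(dv[sel], t_sel) / (t_sel[-1] - t_sel[0]))
    return LIResult(
        subject_id=trace.subject_id,
        task_label=trace.task_label,
        li_pct=li,
        t_max_s=t_max,
        window_s=(w_lo, w_hi),
        activation_window_s=(lo, hi),
        t_int_s=t_int_s,
    )
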