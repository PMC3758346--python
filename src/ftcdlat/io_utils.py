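"""CSV/JSON/YAML dialects shared by all pipeline stages.

All times are serialized in seconds with three decimals (the 25 Hz grid
is exact at that precision); velocities and percent changes use %.17g so
a write-read round trip reproduces values bit-exactly.  Files are UTF-8
CSV with a header row, '.' decimal separator and no thousands separators.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .group_analysis import GroupTrace, LICorrelation, WindowCorrelationSeries
from .lateralize import LIResult
from .preprocess import SubjectTaskResponse
from .synthetic import RecordingSession, SimulationConfig

__all__ = [
    "PipelineError",
    "RunManifest",
    "load_config",
    "session_paths",
    "write_session",
    "read_session",
    "write_truth",
    "write_response",
    "read_response",
    "response_path",
    "write_qc_report",
    "read_qc_report",
    "write_li_results",
    "read_li_results",
    "write_group_trace",
    "write_window_correlation",
    "write_li_correlation",
    "write_manifest",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _write_csv(path: Path, header: str, columns: list[np.ndarray], fmts: list[str]) -> None:
    data = np.column_stack(columns)
    np.savetxt(path, data, fmt=fmts, delimiter=",", header=header, comments="")


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise naming the file
        raise PipelineError(f"failed to read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"{path} is missing required columns {missing}")
    return df


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a flat YAML key: value file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
    tuple_fields = {
        "target_duration_range_s",
        "control_duration_range_s",
        "heart_rate_bpm_range",
        "baseline_velocity_cm_s_range",
        "artifact_duration_range_s",
    }
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        kwargs[key] = tuple(value) if key in tuple_fields else value
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"{path}: invalid configuration: {exc}") from exc


def session_paths(directory: str | Path, subject_id: str, task_label: str) -> tuple[Path, Path]:
    d = Path(directory)
    stem = f"{subject_id}_{task_label}"
    return d / f"{stem}_signal.csv", d / f"{stem}_events.csv"


def write_session(session: RecordingSession, directory: str | Path) -> tuple[Path, Path]:
    """Write one session as the two-file CSV dialect (signal + events)."""
    signal_path, events_path = session_paths(
        directory, session.subject_id, session.task_label
    )
    signal_path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(
        signal_path,
        "time_s,left_cm_s,right_cm_s",
        [session.time_s, session.left_velocity, session.right_velocity],
        ["%.3f", "%.17g", "%.17g"],
    )
    with open(events_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s,kind\n")
        for onset, kind in session.events:
            fh.write(f"{onset:.3f},{kind}\n")
    return signal_path, events_path


def read_session(
    directory: str | Path, subject_id: str, task_label: str
) -> RecordingSession:
    """Read a session back from the CSV dialect written by write_session."""
    signal_path, events_path = session_paths(directory, subject_id, task_label)
    sig = _read_csv(signal_path, ["time_s", "left_cm_s", "right_cm_s"])
    ev = _read_csv(events_path, ["onset_s", "kind"])
    time = sig["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise PipelineError(f"{signal_path}: need at least two samples")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], atol=1e-6):
        raise PipelineError(f"{signal_path}: time grid is not uniform")
    fs = 1.0 / float(np.round(dt[0], 9))
    left = sig["left_cm_s"].to_numpy(dtype=float)
    right = sig["right_cm_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(left)) or not np.all(np.isfinite(right)):
        raise PipelineError(f"{signal_path}: non-finite velocities")
    events = tuple(
        (float(row.onset_s), str(row.kind)) for row in ev.itertuples(index=False)
    )
    try:
        return RecordingSession(
            subject_id=subject_id,
            task_label=task_label,
            sample_rate_hz=float(np.round(fs, 6)),
            left_velocity=left,
            right_velocity=right,
            events=events,
        )
    except ValueError as exc:
        raise PipelineError(f"{events_path}: invalid event list: {exc}") from exc


def write_truth(truth: pd.DataFrame, directory: str | Path) -> Path:
    path = Path(directory) / "truth.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(
        path,
        index=False,
        columns=["subject_id", "task_label", "true_delta_v_pct", "latent_trait"],
        float_format="%.17g",
    )
    return path


def response_path(directory: str | Path, subject_id: str, task_label: str) -> Path:
    return Path(directory) / f"response_{subject_id}_{task_label}.csv"


def write_response(response: SubjectTaskResponse, directory: str | Path) -> Path:
    path = response_path(directory, response.subject_id, response.task_label)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(
        path,
        "time_s,mean_dv_left_pct,mean_dv_right_pct",
        [response.time_axis_s, response.mean_dv_left_pct, response.mean_dv_right_pct],
        ["%.3f", "%.17g", "%.17g"],
    )
    return path


def read_response(
    directory: str | Path, subject_id: str, task_label: str, n_good_epochs: int = -1
) -> SubjectTaskResponse:
    path = response_path(directory, subject_id, task_label)
    df = _read_csv(path, ["time_s", "mean_dv_left_pct", "mean_dv_right_pct"])
    return SubjectTaskResponse(
        subject_id=subject_id,
        task_label=task_label,
        time_axis_s=df["time_s"].to_numpy(dtype=float),
        mean_dv_left_pct=df["mean_dv_left_pct"].to_numpy(dtype=float),
        mean_dv_right_pct=df["mean_dv_right_pct"].to_numpy(dtype=float),
        n_good_epochs=n_good_epochs,
    )


def write_qc_report(report: pd.DataFrame, directory: str | Path) -> Path:
    path = Path(directory) / "qc_report.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(
        path,
        index=False,
        columns=["subject_id", "task_label", "n_total", "n_good", "kept"],
    )
    return path


def read_qc_report(directory: str | Path) -> pd.DataFrame:
    return _read_csv(
        Path(directory) / "qc_report.csv",
        ["subject_id", "task_label", "n_total", "n_good", "kept"],
    )


def write_li_results(results: list[LIResult], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "subject_id": r.subject_id,
            "task_label": r.task_label,
            "li_pct": r.li_pct,
            "t_max_s": r.t_max_s,
            "win_lo_s": r.window_s[0],
            "win_hi_s": r.window_s[1],
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["subject_id", "task_label", "li_pct", "t_max_s", "win_lo_s", "win_hi_s"],
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_li_results(path: str | Path) -> pd.DataFrame:
    return _read_csv(
        Path(path),
        ["subject_id", "task_label", "li_pct", "t_max_s", "win_lo_s", "win_hi_s"],
    )


def write_group_trace(trace: GroupTrace, directory: str | Path) -> Path:
    path = Path(directory) / f"group_trace_{trace.task_label}.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(
        path,
        "time_s,mean_dv,sem",
        [trace.time_axis_s, trace.mean_delta_v_pct, trace.sem_delta_v_pct],
        ["%.3f", "%.17g", "%.17g"],
    )
    return path


def write_window_correlation(series: WindowCorrelationSeries, directory: str | Path) -> Path:
    path = Path(directory) / "window_correlation.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    n_col = np.full(len(series.window_starts_s), series.n_subjects, dtype=float)
    r_crit = np.full(len(series.window_starts_s), series.r_critical)
    _write_csv(
        path,
        "start_s,r,p,r_critical,n",
        [series.window_starts_s, series.r_values, series.p_values, r_crit, n_col],
        ["%.3f", "%.17g", "%.17g", "%.17g", "%d"],
    )
    return path


def write_li_correlation(corr: LICorrelation, directory: str | Path) -> Path:
    path = Path(directory) / "li_correlation.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "r": corr.r,
                "p": corr.p,
                "slope": corr.slope,
                "intercept": corr.intercept,
                "n": corr.n,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return path


@dataclass
class RunManifest:
    """Provenance record for one end-to-end pipeline run."""

    config: dict[str, Any]
    seed: int
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)
    exclusions: list[dict[str, Any]] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[tuple[Path, int]]) -> None:
        self.stages.append(
            {
                "name": name,
                "outputs": [{"path": str(p), "rows": int(r)} for p, r in outputs],
            }
        )


def write_manifest(manifest: RunManifest, directory: str | Path) -> Path:
    path = Path(directory) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")
    return path
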