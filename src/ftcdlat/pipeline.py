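"""End-to-end orchestration: simulate -> preprocess -> li -> correlate.

``run_pipeline`` executes every stage on one simulated cohort, writing
each stage's CSV/JSON outputs and a provenance manifest.  The run is
idempotent: the same config file (hence the same seed) gives
byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .group_analysis import group_trace, li_correlation, moving_window_correlation
from .io_utils import (
    PipelineError,
    RunManifest,
    load_config,
    read_session,
    write_group_trace,
    write_li_correlation,
    write_li_results,
    write_manifest,
    write_qc_report,
    write_response,
    write_session,
    write_truth,
    write_window_correlation,
)
from .lateralize import delta_v, lateralization_index
from .preprocess import (
    average_and_filter,
    detect_cardiac_cycles,
    integrate_cardiac,
    qc_subject,
    reject_artifacts,
    segment_epochs,
)
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return decorator


@_stage("simulate")
def _simulate_stage(config, out_dir: Path, manifest: RunManifest):
    sessions, truth = simulate_cohort(config)
    signals_dir = out_dir / "signals"
    outputs = []
    for session in sessions:
        signal_path, events_path = write_session(session, signals_dir)
        outputs.append((signal_path, session.n_samples))
        outputs.append((events_path, len(session.events)))
    truth_path = write_truth(truth, signals_dir)
    outputs.append((truth_path, len(truth)))
    manifest.add_stage("simulate", outputs)
    logger.info("simulated %d sessions", len(sessions))
    return sessions, truth, signals_dir


@_stage("preprocess")
def _preprocess_stage(config, signals_dir: Path, out_dir: Path, manifest: RunManifest,
                      cutoff_hz: float, order: int, threshold_pct: float,
                      min_good_fraction: float, subject_tasks):
    responses_dir = out_dir / "responses"
    qc_rows = []
    responses = {}
    outputs = []
    for subject_id, tasks in subject_tasks.items():
        epoch_sets = {}
        for task in tasks:
            session = read_session(signals_dir, subject_id, task)
            beats = detect_cardiac_cycles(session)
            integrated = integrate_cardiac(session, beats)
            epoch_sets[task] = reject_artifacts(
                segment_epochs(integrated), threshold_pct
            )
        decision = qc_subject(epoch_sets, min_good_fraction)
        for task, epochs in epoch_sets.items():
            qc_rows.append(
                {
                    "subject_id": subject_id,
                    "task_label": task,
                    "n_total": epochs.n_total,
                    "n_good": epochs.n_good,
                    "kept": decision.keep,
                }
            )
        if not decision.keep:
            logger.info("excluding %s: %s", subject_id, decision.reason)
            manifest.exclusions.append(
                {"subject_id": subject_id, "reason": decision.reason}
            )
            continue
        for task, epochs in epoch_sets.items():
            response = average_and_filter(epochs, cutoff_hz, order)
            path = write_response(response, responses_dir)
            outputs.append((path, len(response.time_axis_s)))
            responses[(subject_id, task)] = response
    qc_report = pd.DataFrame(
        qc_rows, columns=["subject_id", "task_label", "n_total", "n_good", "kept"]
    )
    qc_path = write_qc_report(qc_report, out_dir)
    outputs.append((qc_path, len(qc_report)))
    manifest.add_stage("preprocess", outputs)
    return responses


@_stage("li")
def _li_stage(responses, out_dir: Path, manifest: RunManifest,
              activation_window_s, t_int_s):
    traces = {key: delta_v(resp) for key, resp in responses.items()}
    results = [
        lateralization_index(trace, activation_window_s, t_int_s)
        for trace in traces.values()
    ]
    li_path = write_li_results(results, out_dir / "li_results.csv")
    manifest.add_stage("li", [(li_path, len(results))])
    return traces, results


@_stage("correlate")
def _correlate_stage(config, traces, results, out_dir: Path, manifest: RunManifest,
                     alpha: float):
    tasks = list(config.tasks)
    subjects = sorted({sid for sid, _ in traces})
    paired = [s for s in subjects if all((s, t) in traces for t in tasks)]
    outputs = []
    for task in tasks:
        task_traces = [traces[(s, task)] for s in paired]
        if len(task_traces) >= 2:
            outputs.append((write_group_trace(group_trace(task_traces, task), out_dir),
                            len(task_traces[0].time_axis_s)))
    if len(tasks) >= 2 and len(paired) >= 3:
        a_task, b_task = tasks[0], tasks[1]
        li_by = {(r.subject_id, r.task_label): r.li_pct for r in results}
        li_a = np.array([li_by[(s, a_task)] for s in paired])
        li_b = np.array([li_by[(s, b_task)] for s in paired])
        corr = li_correlation(li_a, li_b)
        outputs.append((write_li_correlation(corr, out_dir), 1))
        series = moving_window_correlation(
            [traces[(s, a_task)] for s in paired],
            [traces[(s, b_task)] for s in paired],
            alpha=alpha,
        )
        outputs.append(
            (write_window_correlation(series, out_dir), len(series.window_starts_s))
        )
    else:
        logger.info(
            "skipping correlation outputs: %d paired subjects retained", len(paired)
        )
    manifest.add_stage("correlate", outputs)


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    cutoff_hz: float = 1.0,
    order: int = 2,
    threshold_pct: float = 30.0,
    min_good_fraction: float = 0.80,
    activation_window_s: tuple[float, float] = (2.0, 18.0),
    t_int_s: float = 2.0,
    alpha: float = 0.05,
) -> RunManifest:
    """Execute all stages in order on one simulated cohort."""
    config = load_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses_asdict(config), seed=config.seed, version=__version__
    )
    sessions, truth, signals_dir = _simulate_stage(config, out_dir, manifest)
    subject_tasks: dict[str, list[str]] = {}
    for session in sessions:
        subject_tasks.setdefault(session.subject_id, []).append(session.task_label)
    responses = _preprocess_stage(
        config, signals_dir, out_dir, manifest, cutoff_hz, order, threshold_pct,
        min_good_fraction, subject_tasks,
    )
    traces, results = _li_stage(
        responses, out_dir, manifest, activation_window_s, t_int_s
    )
    _correlate_stage(config, traces, results, out_dir, manifest, alpha)
    write_manifest(manifest, out_dir)
    return manifest


def dataclasses_asdict(config) -> dict:
    import dataclasses

    raw = dataclasses.asdict(config)
    return {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in raw.items()
    }
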