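"""End-to-end task orchestration: benchmark → split → run → collate → account.

``run_task`` is the one call behind both the library examples and the CLI's
``submit`` command.  It times a single repeat (unless overridden), packs
repeats into jobs aiming at the configured per-job runtime, runs the bundle
on the configured backend, collates the per-job outputs into the artifacts a
serial run would have produced, appends a usage record, and fires exactly
one completion or failure notification.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .accounting import UsageStore, record_usage
from .backend import poll_states, run_bundle, write_submit_description
from .balance import benchmark_single_repeat, repeats_per_job
from .collate import (
    best_algorithms,
    concatenate_scan_outputs,
    select_best,
    sensitivity_report,
    summarize_ensemble,
)
from .config import GlobalConfig, setup_logging
from .failures import FileSink, LogSink, Notifier, classify_failure, package_failure_bundle
from .objectives import parse_dataset
from .optimize import OptimizationProblem, run_optimization
from .simulate import simulate_ssa
from .tasks import REPEAT_TASK_TYPES, JobBundle, TaskSpec, materialize_scan_grid, split_task
from .worker import read_moments, repeat_seed, result_from_dict
from . import objectives as _objectives

__all__ = ["TaskResult", "run_task", "single_repeat_callable"]


@dataclass
class TaskResult:
    bundle: JobBundle
    state: str  # finished | error
    task_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    usage: object = None
    failure_report: object = None
    repeats_per_job: int | None = None


def single_repeat_callable(task: TaskSpec):
    """One benchmarkable repeat of a repeat-style task, run locally."""
    if task.task_type == "stochastic_repeat":
        def repeat(deadline=None):
            simulate_ssa(task.model, t_end=task.t_end, n_points=task.n_points,
                         seed=repeat_seed(task.base_seed, 0))
    elif task.task_type in ("optimization_repeat", "parameter_estimation_repeat"):
        names = [p[0] for p in task.optimization_parameters]
        bounds = [(lo, hi) for _, lo, hi in task.optimization_parameters]
        if task.task_type == "parameter_estimation_repeat":
            objective = _objectives.make_estimation_objective(
                task.model, parse_dataset(task.dataset_tsv), names)
            direction = "minimize"
        else:
            objective = _objectives.make_target_objective(
                task.model, task.target_spec, names, mode=task.target_mode,
                t_end=task.t_end, n_points=task.n_points)
            direction = task.direction
        problem = OptimizationProblem(objective=objective, bounds=bounds,
                                      direction=direction)

        def repeat(deadline=None):
            run_optimization(problem, task.algorithm, dict(task.algorithm_settings),
                             seed=repeat_seed(task.base_seed, 0))
    else:
        raise ValueError(f"{task.task_type!r} is not a repeat-style task")
    return repeat


def _split_parameter(task: TaskSpec, config: GlobalConfig, logger) -> dict:
    """Work out the split parameter (repeats per job or scan chunk count)."""
    if task.task_type in REPEAT_TASK_TYPES:
        if config.balance.override_one_per_job:
            return {"repeats_per_job": 1}
        bench = benchmark_single_repeat(single_repeat_callable(task), config.balance)
        rpj = repeats_per_job(bench, config.balance)
        logger.info("benchmark: single repeat %.3fs%s -> %d repeats/job",
                    bench.seconds, " (timed out)" if bench.timed_out else "", rpj)
        return {"repeats_per_job": rpj}
    if task.task_type == "scan":
        grid = materialize_scan_grid(task)
        if config.balance.override_one_per_job:
            return {"chunk_count": len(grid)}
        # benchmark one grid point by running a single-point scan job locally
        from .worker import execute_job  # local import avoids a cycle at module load

        probe_task = TaskSpec(**{**task.__dict__, "scan_grid": [list(grid[0])]})
        probe = split_task(probe_task, chunk_count=1)

        def one_point(deadline=None):
            import tempfile
            with tempfile.TemporaryDirectory() as tmp:
                execute_job(probe.jobs[0].document, Path(tmp))

        bench = benchmark_single_repeat(one_point, config.balance)
        per_job = repeats_per_job(bench, config.balance)
        chunk_count = max(1, -(-len(grid) // per_job))
        logger.info("benchmark: one grid point %.3fs -> %d chunks", bench.seconds, chunk_count)
        return {"chunk_count": chunk_count}
    return {}


def _collate(task: TaskSpec, bundle: JobBundle, task_dir: Path,
             config: GlobalConfig) -> dict[str, Path]:
    artifacts: dict[str, Path] = {}
    outputs = [task_dir / job.output_filename for job in bundle.jobs]
    if task.task_type == "stochastic_repeat":
        chunks = [read_moments(p) for p in outputs]
        summary = summarize_ensemble(chunks, sd_divisor=config.sd_divisor)
        path = task_dir / "ensemble_summary.tsv"
        summary.to_tsv(path)
        artifacts["ensemble_summary"] = path
    elif task.task_type == "scan":
        path = task_dir / "scan_results.tsv"
        concatenate_scan_outputs(outputs, path)
        artifacts["scan_results"] = path
    elif task.task_type in ("optimization_repeat", "parameter_estimation_repeat"):
        results, names = [], None
        for p in outputs:
            for entry in yaml.safe_load(p.read_text()):
                names = entry["parameter_names"]
                results.append(result_from_dict(entry))
        direction = ("minimize" if task.task_type == "parameter_estimation_repeat"
                     else task.direction)
        winner, model_doc = select_best(results, direction, model=task.model,
                                        parameter_names=names)
        best_path = task_dir / "best_result.yaml"
        best_path.write_text(yaml.safe_dump({
            "best_value": float(winner.best_value),
            "best_parameters": dict(zip(names, map(float, winner.best_parameters))),
            "algorithm": winner.algorithm,
        }, sort_keys=True))
        model_path = task_dir / "best_model.txt"
        model_path.write_text(model_doc)
        artifacts["best_result"] = best_path
        artifacts["best_model"] = model_path
    elif task.task_type == "sensitivity":
        entries = [yaml.safe_load(p.read_text()) for p in outputs]
        results = [result_from_dict(e) for e in entries]
        report = sensitivity_report([p[0] for p in task.sensitivity_parameters], results)
        path = task_dir / "sensitivity_report.tsv"
        path.write_text(report.to_tsv())
        artifacts["sensitivity_report"] = path
    elif task.task_type == "algorithm_sweep":
        per_algo = {}
        for p in outputs:
            entry = yaml.safe_load(p.read_text())
            per_algo[entry["algorithm"]] = result_from_dict(entry)
        best = sorted(best_algorithms(per_algo, task.direction))
        path = task_dir / "best_algorithms.yaml"
        path.write_text(yaml.safe_dump({"best_algorithms": best}, sort_keys=True))
        artifacts["best_algorithms"] = path
    # raw mode: per-job outputs are the artifacts; nothing to merge
    return artifacts


def _persist_state(bundle: JobBundle, task_dir: Path) -> None:
    state = {
        "task": bundle.task.name,
        "jobs": [{"job_index": j.job_index, "state": j.state,
                  "exit_status": j.exit_status, "attempts": j.attempts,
                  "cpu_time": j.cpu_time} for j in bundle.jobs],
    }
    (task_dir / "task_state.yaml").write_text(yaml.safe_dump(state, sort_keys=True))


def run_task(task: TaskSpec, config: GlobalConfig | None = None) -> TaskResult:
    """Execute one task end to end and return its collated artifacts."""
    config = config or GlobalConfig()
    task.validate()
    task.balance = config.balance
    task_dir = Path(config.work_dir) / task.name
    task_dir.mkdir(parents=True, exist_ok=True)
    logger = setup_logging(config.resolved_log_path())
    logger.info("task %s (%s) submitted", task.name, task.task_type)
    submission = time.time()

    split_kw = _split_parameter(task, config, logger)
    bundle = split_task(task, **split_kw)
    logger.info("task %s split into %d jobs (%s)", task.name, len(bundle.jobs),
                split_kw or "unit split")

    if config.backend.backend == "submit_files_only":
        for job in bundle.jobs:
            (task_dir / job.document_filename()).write_text(job.document_yaml())
            write_submit_description(
                job, {"executable": sys.executable,
                      "arguments": f"-m simfarm.worker {job.document_filename()} ."},
                task_dir)
        _persist_state(bundle, task_dir)
        return TaskResult(bundle=bundle, state="finished", task_dir=task_dir,
                          repeats_per_job=split_kw.get("repeats_per_job"))

    bundle = run_bundle(bundle, config.backend, task_dir)
    summary = poll_states(bundle)
    end = time.time()

    usage = record_usage(bundle, submission, end, task_id=task.name)
    store = UsageStore(Path(config.work_dir) / "usage.tsv")
    store.append(usage)

    sink = LogSink() if config.notification == "log" else FileSink(config.notification)
    notifier = Notifier(sink)

    artifacts: dict[str, Path] = {}
    failure_report = None
    if summary.task_state == "finished":
        artifacts = _collate(task, bundle, task_dir, config)
        notifier.notify(task.name, "finished")
        logger.info("task %s finished: %d jobs, %.4f CPU h, speed-up %.3g",
                    task.name, usage.n_jobs, usage.cpu_hours, usage.speedup)
    else:
        failure_report = classify_failure(bundle, task_dir, task_id=task.name)
        archive = package_failure_bundle(task_dir)
        failure_report.bundle_path = str(archive)
        artifacts["failure_bundle"] = archive
        notifier.notify(task.name, "failed", report=failure_report)
        logger.error("task %s failed: %s", task.name, failure_report.summary())

    _persist_state(bundle, task_dir)
    return TaskResult(bundle=bundle, state=summary.task_state, task_dir=task_dir,
                      artifacts=artifacts, usage=usage, failure_report=failure_report,
                      repeats_per_job=split_kw.get("repeats_per_job"))
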