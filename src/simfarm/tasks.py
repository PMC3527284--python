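"""Task descriptions and their decomposition into independent parallel jobs.

Seven task types are supported:

==========================  =====================================================
sensitivity                 one bounded max + one bounded min per parameter
stochastic_repeat           N repeats of a stochastic time course
scan                        a parameter grid, split into contiguous chunks
optimization_repeat         N restarts of a stochastic optimizer
parameter_estimation_repeat N restarts of a fit against a dataset
algorithm_sweep             one job per (algorithm, settings) entry
raw                         N jobs running a user-supplied argument template
==========================  =====================================================

Every job carries a self-contained job document (model + task fragment +
seed + output filename), so a job can run anywhere with no shared state —
the analogue of writing a custom model file per parallel job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .balance import LoadBalanceConfig
from .model import ReactionNetworkModel, write_native_model

__all__ = [
    "TaskSpec",
    "Job",
    "JobBundle",
    "TaskValidationError",
    "split_sensitivity",
    "split_repeats",
    "split_scan",
    "split_algorithm_sweep",
    "split_raw",
    "split_task",
    "materialize_scan_grid",
]

TASK_TYPES = (
    "sensitivity", "stochastic_repeat", "scan", "optimization_repeat",
    "parameter_estimation_repeat", "algorithm_sweep", "raw",
)

REPEAT_TASK_TYPES = ("stochastic_repeat", "optimization_repeat",
                     "parameter_estimation_repeat")

# lifecycle states a job can be in
JOB_STATES = ("created", "idle", "running", "held", "evicted", "completed", "failed")


class TaskValidationError(ValueError):
    """A TaskSpec is missing or misusing a field for its task type."""


@dataclass
class TaskSpec:
    """User-facing description of one parallel task.

    Only the fields relevant to ``task_type`` need to be set; ``validate``
    enforces which ones those are.
    """

    task_type: str
    model: ReactionNetworkModel | None = None
    name: str = "task"
    # simulation window used by time-course style work
    t_end: float = 10.0
    n_points: int = 101
    # objective description (sensitivity / optimization / estimation)
    target_spec: str = ""
    target_mode: str = "final_time"  # or "steady_state"
    direction: str = "minimize"
    algorithm: str = "particle_swarm"
    algorithm_settings: dict = field(default_factory=dict)
    # sensitivity: (parameter name, lower, upper) — typically original ±x%
    sensitivity_parameters: list[tuple[str, float, float]] = field(default_factory=list)
    # optimization / estimation: free parameters and their box
    optimization_parameters: list[tuple[str, float, float]] = field(default_factory=list)
    repeat_count: int = 1
    # scan: names + explicit points, or a generator spec mapping
    scan_parameters: list[str] = field(default_factory=list)
    scan_grid: Any = None
    scan_subtask: dict = field(default_factory=lambda: {"type": "time_course"})
    # algorithm sweep
    algorithms: list[tuple[str, dict]] = field(default_factory=list)
    # raw mode
    raw_args: str = ""
    raw_executable: str = ""
    # estimation dataset, embedded as TSV text (Time + observed species columns)
    dataset_tsv: str = ""
    base_seed: int = 0
    balance: LoadBalanceConfig = field(default_factory=LoadBalanceConfig)

    def validate(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise TaskValidationError(f"unknown task type {self.task_type!r}")
        if self.task_type != "raw" and self.model is None:
            raise TaskValidationError(f"{self.task_type} task requires a model")
        if self.model is not None:
            self.model.validate()
        if self.task_type == "sensitivity":
            if not self.sensitivity_parameters:
                raise TaskValidationError("sensitivity task requires a non-empty parameter list")
            for name, lo, hi in self.sensitivity_parameters:
                if name not in self.model.parameters:
                    raise TaskValidationError(f"unknown sensitivity parameter {name!r}")
                if not lo < hi:
                    raise TaskValidationError(
                        f"sensitivity bounds for {name!r} require lower < upper")
            if not self.target_spec:
                raise TaskValidationError("sensitivity task requires target_spec")
        if self.task_type in REPEAT_TASK_TYPES and self.repeat_count < 1:
            raise TaskValidationError("repeat_count must be >= 1")
        if self.task_type in ("optimization_repeat", "parameter_estimation_repeat"):
            if not self.optimization_parameters:
                raise TaskValidationError(f"{self.task_type} requires optimization_parameters")
            for name, lo, hi in self.optimization_parameters:
                if not lo < hi:
                    raise TaskValidationError(f"bounds for {name!r} require lower < upper")
        if self.task_type == "optimization_repeat" and not self.target_spec:
            raise TaskValidationError("optimization_repeat requires target_spec")
        if self.task_type == "parameter_estimation_repeat" and not self.dataset_tsv:
            raise TaskValidationError("parameter_estimation_repeat requires dataset_tsv")
        if self.task_type == "scan" and self.scan_grid is None:
            raise TaskValidationError("scan task requires scan_grid")
        if self.task_type == "algorithm_sweep" and not self.algorithms:
            raise TaskValidationError("algorithm_sweep requires a non-empty algorithms list")
        if self.task_type == "raw":
            if self.repeat_count < 1:
                raise TaskValidationError("repeat_count must be >= 1")
            if "{out}" not in self.raw_args:
                raise TaskValidationError("raw_args template must contain the {out} token")


@dataclass
class Job:
    """One parallel work unit with its self-contained document."""

    job_index: int
    document: dict
    seed: int
    assigned_repeats: int | None = None
    assigned_subrange: tuple[int, int] | None = None  # half-open grid interval
    state: str = "created"
    exit_status: int | None = None
    cpu_time: float | None = None
    attempts: int = 0
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.assigned_repeats is None) == (self.assigned_subrange is None):
            raise ValueError("exactly one of assigned_repeats / assigned_subrange must be set")

    @property
    def output_filename(self) -> str:
        return self.document["output"]

    def document_filename(self) -> str:
        return f"job_{self.job_index}.yaml"

    def document_yaml(self) -> str:
        return yaml.safe_dump(self.document, sort_keys=True)


@dataclass
class JobBundle:
    task: TaskSpec
    jobs: list[Job]

    def __post_init__(self) -> None:
        for i, job in enumerate(self.jobs):
            if job.job_index != i:
                raise ValueError("job_index values must be 0..N-1 with no gaps")


def _base_document(task: TaskSpec, job_index: int, seed: int) -> dict:
    doc = {
        "task_type": task.task_type,
        "job_index": job_index,
        "seed": seed,
        "output": f"job_{job_index}.out",
    }
    if task.model is not None:
        doc["model"] = write_native_model(task.model)
    return doc


def _objective_fragment(task: TaskSpec) -> dict:
    return {
        "target": task.target_spec,
        "mode": task.target_mode,
        "t_end": task.t_end,
        "n_points": task.n_points,
        "direction": task.direction,
    }


def split_sensitivity(task: TaskSpec) -> JobBundle:
    """2·P jobs for P parameters: (param 0 max, param 0 min, param 1 max, ...).

    Each job optimizes the scaled sensitivity of the target with respect to
    its focus parameter over the full P-dimensional bounds box.
    """
    task.validate()
    if task.task_type != "sensitivity":
        raise TaskValidationError("split_sensitivity requires a sensitivity task")
    jobs = []
    for p_i, (pname, lo, hi) in enumerate(task.sensitivity_parameters):
        for direction in ("maximize", "minimize"):
            idx = len(jobs)
            doc = _base_document(task, idx, task.base_seed + idx)
            doc.update(
                focus_parameter=pname,
                direction=direction,
                bounds=[[n, float(l), float(h)] for n, l, h in task.sensitivity_parameters],
                objective=_objective_fragment(task),
                algorithm=task.algorithm,
                settings=dict(task.algorithm_settings),
            )
            jobs.append(Job(job_index=idx, document=doc, seed=task.base_seed + idx,
                            assigned_repeats=1))
    return JobBundle(task=task, jobs=jobs)


def split_repeats(task: TaskSpec, repeats_per_job: int) -> JobBundle:
    """ceil(repeat_count / repeats_per_job) jobs; all full except the last,
    which carries the remainder.  Each job records its global repeat offset
    so per-repeat seeds are independent of how the repeats were chunked."""
    task.validate()
    if task.task_type not in REPEAT_TASK_TYPES:
        raise TaskValidationError(f"split_repeats does not apply to {task.task_type!r}")
    if repeats_per_job < 1:
        raise TaskValidationError(f"repeats_per_job must be >= 1, got {repeats_per_job}")
    n_jobs = math.ceil(task.repeat_count / repeats_per_job)
    jobs = []
    offset = 0
    for idx in range(n_jobs):
        r = min(repeats_per_job, task.repeat_count - offset)
        doc = _base_document(task, idx, task.base_seed + idx)
        doc.update(repeats=r, repeat_offset=offset, base_seed=task.base_seed)
        if task.task_type == "stochastic_repeat":
            doc.update(t_end=task.t_end, n_points=task.n_points)
        else:
            doc.update(
                objective=_objective_fragment(task),
                parameters=[[n, float(l), float(h)] for n, l, h in task.optimization_parameters],
                algorithm=task.algorithm,
                settings=dict(task.algorithm_settings),
            )
            if task.task_type == "parameter_estimation_repeat":
                doc["dataset"] = task.dataset_tsv
        jobs.append(Job(job_index=idx, document=doc, seed=task.base_seed + idx,
                        assigned_repeats=r))
        offset += r
    assert offset == task.repeat_count
    return JobBundle(task=task, jobs=jobs)


def materialize_scan_grid(task: TaskSpec) -> list[tuple[float, ...]]:
    """Resolve the scan grid to a concrete list of parameter-value tuples.

    Accepts an explicit list, a ``{"type": "range", ...}`` spec (uniform grid
    over one parameter), or a ``{"type": "random", ...}`` spec (points sampled
    uniformly in a box, seeded once from base_seed so materialization is
    deterministic and happens before splitting).
    """
    grid = task.scan_grid
    if isinstance(grid, list):
        return [tuple(float(v) for v in np.atleast_1d(pt)) for pt in grid]
    if isinstance(grid, dict):
        if grid["type"] == "range":
            vals = np.linspace(float(grid["start"]), float(grid["stop"]), int(grid["n"]))
            return [(float(v),) for v in vals]
        if grid["type"] == "random":
            rng = np.random.default_rng(task.base_seed)
            bounds = [(float(lo), float(hi)) for lo, hi in grid["bounds"]]
            n = int(grid["n"])
            pts = [tuple(rng.uniform(lo, hi) for lo, hi in bounds) for _ in range(n)]
            return pts
        raise TaskValidationError(f"unknown scan grid spec type {grid['type']!r}")
    raise TaskValidationError(f"cannot materialize scan grid from {type(grid).__name__}")


def split_scan(task: TaskSpec, chunk_count: int) -> JobBundle:
    """Contiguous, non-overlapping half-open chunks covering the grid exactly;
    sizes differ by at most 1 with the larger chunks first."""
    task.validate()
    if task.task_type != "scan":
        raise TaskValidationError("split_scan requires a scan task")
    if chunk_count < 1:
        raise TaskValidationError(f"chunk_count must be >= 1, got {chunk_count}")
    points = materialize_scan_grid(task)
    n = len(points)
    if chunk_count > n:
        import logging
        logging.getLogger("simfarm").warning(
            "chunk_count %d exceeds grid size %d; clamping", chunk_count, n)
        chunk_count = n
    base, rem = divmod(n, chunk_count)
    jobs = []
    start = 0
    for idx in range(chunk_count):
        size = base + (1 if idx < rem else 0)
        stop = start + size
        doc = _base_document(task, idx, task.base_seed + idx)
        doc.update(
            parameter_names=list(task.scan_parameters),
            points=[list(p) for p in points[start:stop]],
            subrange=[start, stop],
            subtask=dict(task.scan_subtask),
            t_end=task.t_end,
            n_points=task.n_points,
        )
        jobs.append(Job(job_index=idx, document=doc, seed=task.base_seed + idx,
                        assigned_subrange=(start, stop)))
        start = stop
    assert start == n
    return JobBundle(task=task, jobs=jobs)


def split_algorithm_sweep(task: TaskSpec) -> JobBundle:
    """Exactly one job per (algorithm, settings) entry, in list order."""
    task.validate()
    if task.task_type != "algorithm_sweep":
        raise TaskValidationError("split_algorithm_sweep requires an algorithm_sweep task")
    seen = set()
    for algo, settings in task.algorithms:
        key = (algo, tuple(sorted(settings.items())))
        if key in seen:
            raise TaskValidationError(f"duplicate algorithm+settings entry: {algo} {settings}")
        seen.add(key)
    jobs = []
    for idx, (algo, settings) in enumerate(task.algorithms):
        doc = _base_document(task, idx, task.base_seed + idx)
        doc.update(
            algorithm=algo,
            settings=dict(settings),
            objective=_objective_fragment(task),
            parameters=[[n, float(l), float(h)] for n, l, h in task.optimization_parameters],
        )
        jobs.append(Job(job_index=idx, document=doc, seed=task.base_seed + idx,
                        assigned_repeats=1))
    return JobBundle(task=task, jobs=jobs)


def split_raw(task: TaskSpec) -> JobBundle:
    """repeat_count jobs, one repeat each, with {job}/{out} tokens substituted."""
    task.validate()
    if task.task_type != "raw":
        raise TaskValidationError("split_raw requires a raw task")
    jobs = []
    for idx in range(task.repeat_count):
        out = f"job_{idx}.out"
        doc = _base_document(task, idx, task.base_seed + idx)
        doc.update(
            arguments=task.raw_args.format(job=idx, out=out),
            executable=task.raw_executable,
        )
        jobs.append(Job(job_index=idx, document=doc, seed=task.base_seed + idx,
                        assigned_repeats=1))
    return JobBundle(task=task, jobs=jobs)


def split_task(task: TaskSpec, *, repeats_per_job: int = 1,
               chunk_count: int = 1) -> JobBundle:
    """Dispatch to the splitter for the task's type."""
    if task.task_type == "sensitivity":
        return split_sensitivity(task)
    if task.task_type in REPEAT_TASK_TYPES:
        return split_repeats(task, repeats_per_job)
    if task.task_type == "scan":
        return split_scan(task, chunk_count)
    if task.task_type == "algorithm_sweep":
        return split_algorithm_sweep(task)
    if task.task_type == "raw":
        return split_raw(task)
    raise TaskValidationError(f"unknown task type {task.task_type!r}")
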