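"""Execution backends: submit-description files and a local process pool.

Two backends are provided.  ``submit_files_only`` writes one standard
submit-description file per job (key = value lines ending in ``queue``),
directly usable with a real scheduler.  ``local_pool`` emulates the pool's
job lifecycle on a bounded thread pool: jobs move created → idle → running
and end completed, failed (non-zero exit), or held (malformed document,
never started).  Evicted jobs are re-queued and restart from scratch — there
is no checkpointing, so every attempt's CPU time is spent (and accounted)
again.  Eviction is injected probabilistically per attempt for testing; real
pools evict for environmental reasons.
"""

from __future__ import annotations

import threading
import time
from collections import Counter, deque
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import read_native_model
from .tasks import Job, JobBundle
from .worker import execute_job

__all__ = [
    "SubmitDescription",
    "BackendConfig",
    "StateSummary",
    "write_submit_description",
    "parse_submit_description",
    "run_bundle",
    "poll_states",
]

# legal lifecycle transitions
_TRANSITIONS = {
    "created": {"idle"},
    "idle": {"running", "held"},
    "running": {"completed", "evicted", "failed"},
    "evicted": {"idle"},
    "completed": {"failed"},  # completed-with-nonzero-exit is marked failed
}

# Condor-style event codes used in the per-job log files
_EV_SUBMIT, _EV_EXECUTE, _EV_EVICT, _EV_TERMINATE, _EV_HELD = "000", "001", "004", "005", "012"


@dataclass
class BackendConfig:
    backend: str = "local_pool"  # or "submit_files_only"
    max_parallel: int = 2
    eviction_rate: float | list[float] = 0.0  # list = per-attempt schedule
    poll_interval: float = 0.01
    seed: int = 0  # drives the eviction-injection RNG only

    def __post_init__(self) -> None:
        if self.backend not in ("local_pool", "submit_files_only"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.max_parallel < 1:
            raise ValueError("max_parallel must be >= 1")
        rates = self.eviction_rate if isinstance(self.eviction_rate, list) else [self.eviction_rate]
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"eviction rate must be in [0, 1], got {r}")
        if isinstance(self.eviction_rate, float) and self.eviction_rate >= 1.0:
            raise ValueError("a stationary eviction rate of 1 would never terminate; "
                             "use a per-attempt schedule like [1.0]")


@dataclass
class SubmitDescription:
    """The key = value job specification handed to the scheduler."""

    executable: str
    arguments: str
    input_files: list[str]
    output: str
    error: str
    log: str
    requirements: str = ""
    queue_count: int = 1

    def to_text(self) -> str:
        lines = [
            f"executable = {self.executable}",
            f"arguments = {self.arguments}",
            f"transfer_input_files = {','.join(self.input_files)}",
        ]
        if self.requirements:
            lines.append(f"requirements = {self.requirements}")
        lines += [
            f"output = {self.output}",
            f"error = {self.error}",
            f"log = {self.log}",
            "queue" if self.queue_count == 1 else f"queue {self.queue_count}",
        ]
        return "\n".join(lines) + "\n"


def parse_submit_description(text: str) -> SubmitDescription:
    fields: dict[str, str] = {}
    queue_count = 1
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line == "queue" or line.startswith("queue "):
            queue_count = int(line.split()[1]) if " " in line else 1
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"cannot parse submit-description line {line!r}")
        fields[key.strip()] = value.strip()
    return SubmitDescription(
        executable=fields["executable"],
        arguments=fields.get("arguments", ""),
        input_files=[f for f in fields.get("transfer_input_files", "").split(",") if f],
        output=fields["output"],
        error=fields["error"],
        log=fields["log"],
        requirements=fields.get("requirements", ""),
        queue_count=queue_count,
    )


def write_submit_description(job: Job, paths: dict, workdir) -> Path:
    """Write ``job_<index>.sub`` for one job.

    ``paths`` supplies ``executable`` (required), optional extra
    ``input_files`` and a ``requirements`` expression.  The job document must
    already be materialized on disk; the executable and every input file must
    exist at write time.
    """
    workdir = Path(workdir)
    doc_path = workdir / job.document_filename()
    if not doc_path.exists():
        raise FileNotFoundError(f"job document not found: {doc_path}")
    exe = str(paths["executable"])
    input_files = [str(doc_path)] + [str(p) for p in paths.get("input_files", [])]
    for f in [exe, *input_files]:
        if not Path(f).exists():
            raise FileNotFoundError(f"input file not found: {f}")
    desc = SubmitDescription(
        executable=exe,
        arguments=paths.get("arguments", f"run {doc_path.name}"),
        input_files=input_files,
        output=f"job_{job.job_index}.stdout",
        error=f"job_{job.job_index}.stderr",
        log=f"job_{job.job_index}.log",
        requirements=paths.get("requirements", ""),
    )
    sub_path = workdir / f"job_{job.job_index}.sub"
    sub_path.write_text(desc.to_text())
    return sub_path


# ---------------------------------------------------------------------------
# Local pool
# ---------------------------------------------------------------------------

class _JobLog:
    """Appends Condor-style event records to the per-job log file."""

    def __init__(self, workdir: Path, job_index: int):
        self.path = Path(workdir) / f"job_{job_index}.log"
        self.job_index = job_index
        self.path.write_text("")

    def record(self, code: str, event: str, detail: str = "") -> None:
        line = f"{code} (job_{self.job_index}) {event}"
        if detail:
            line += f" {detail}"
        with open(self.path, "a") as fh:
            fh.write(line + "\n")


def _transition(job: Job, new_state: str) -> None:
    allowed = _TRANSITIONS.get(job.state, set())
    if new_state not in allowed:
        raise RuntimeError(f"illegal transition {job.state} -> {new_state} "
                           f"for job {job.job_index}")
    job.state = new_state
    job.history.append(new_state)


def _eviction_probability(rate, attempt: int) -> float:
    if isinstance(rate, list):
        return rate[attempt - 1] if attempt - 1 < len(rate) else 0.0
    return float(rate)


def _validate_document(doc: dict) -> None:
    """Pre-start validation; failure here is a malformed submission, which
    holds the job without ever executing it."""
    if not isinstance(doc, dict) or "task_type" not in doc or "output" not in doc:
        raise ValueError("job document missing required keys")
    if doc["task_type"] != "raw":
        if "model" not in doc:
            raise ValueError("job document missing model")
        read_native_model(doc["model"])


def run_bundle(bundle: JobBundle, config: BackendConfig, workdir) -> JobBundle:
    """Run every job of the bundle on the local pool and return the bundle
    with final states, exit statuses and per-job CPU time filled in.

    At most ``config.max_parallel`` jobs run concurrently.  An evicted job is
    re-queued and restarts from scratch on its next attempt; CPU time from
    every attempt is summed.  The observed maximum concurrency is exposed as
    ``bundle.run_stats['max_concurrent']``.
    """
    if config.backend != "local_pool":
        raise ValueError("run_bundle requires the local_pool backend")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    logs = {j.job_index: _JobLog(workdir, j.job_index) for j in bundle.jobs}

    lock = threading.Lock()
    stats = {"running": 0, "max_concurrent": 0}

    queue: deque[Job] = deque()
    for job in bundle.jobs:
        if job.state == "created":
            _transition(job, "idle")
        logs[job.job_index].record(_EV_SUBMIT, "submitted")
        job.cpu_time = 0.0
        try:
            _validate_document(job.document)
        except Exception as exc:  # noqa: BLE001
            _transition(job, "held")
            logs[job.job_index].record(_EV_HELD, "held", f"reason={exc}")
            continue
        # write the job document so each work unit is self-contained on disk
        (workdir / job.document_filename()).write_text(job.document_yaml())
        queue.append(job)

    # eviction decisions drawn up-front, in job order, for determinism
    def decide_eviction(job: Job) -> bool:
        p = _eviction_probability(config.eviction_rate, job.attempts + 1)
        if p <= 0.0:
            return False
        return bool(rng.random() < p)

    def run_attempt(job: Job, evict: bool):
        with lock:
            stats["running"] += 1
            stats["max_concurrent"] = max(stats["max_concurrent"], stats["running"])
        t0 = time.thread_time()
        job.attempts += 1
        logs[job.job_index].record(_EV_EXECUTE, "executing", f"attempt={job.attempts}")
        try:
            execute_job(job.document, workdir)
            status: int | None = 0
            error = ""
        except Exception as exc:  # noqa: BLE001 - any failure becomes a nonzero exit
            status = 1
            error = str(exc)
        cpu = time.thread_time() - t0
        with lock:
            stats["running"] -= 1
        job.cpu_time += cpu
        if evict:
            # the node was reclaimed: discard the attempt's output, keep its cost
            out = workdir / job.output_filename
            if out.exists():
                out.unlink()
            logs[job.job_index].record(_EV_EVICT, "evicted", f"attempt={job.attempts}")
            return "evicted", cpu, ""
        logs[job.job_index].record(
            _EV_TERMINATE, "terminated",
            f"exit_status={status} cpu_time={cpu:.6f}")
        return ("completed" if status == 0 else "failed"), cpu, error

    with ThreadPoolExecutor(max_workers=config.max_parallel) as pool:
        futures = {}
        while queue or futures:
            while queue and len(futures) < config.max_parallel:
                job = queue.popleft()
                _transition(job, "running")
                futures[pool.submit(run_attempt, job, decide_eviction(job))] = job
            done, _ = wait(list(futures), return_when=FIRST_COMPLETED)
            for fut in done:
                job = futures.pop(fut)
                outcome, _cpu, error = fut.result()
                if outcome == "evicted":
                    _transition(job, "evicted")
                    _transition(job, "idle")
                    queue.append(job)
                elif outcome == "completed":
                    job.exit_status = 0
                    _transition(job, "completed")
                else:
                    job.exit_status = 1
                    _transition(job, "failed")
                    logs[job.job_index].record(_EV_TERMINATE, "error", f"detail={error[:300]}")
    bundle.run_stats = {"max_concurrent": stats["max_concurrent"]}
    return bundle


@dataclass
class StateSummary:
    counts: dict[str, int]
    task_state: str  # running | finished | error
    held_jobs: list[int] = field(default_factory=list)
    failed_jobs: list[int] = field(default_factory=list)


def poll_states(bundle: JobBundle) -> StateSummary:
    """Summarize job states, marking completed jobs with a non-zero exit
    status as failed (a non-zero exit indicates an error)."""
    for job in bundle.jobs:
        if job.state == "completed" and job.exit_status not in (0, None):
            _transition(job, "failed")
    counts = Counter(job.state for job in bundle.jobs)
    held = [j.job_index for j in bundle.jobs if j.state == "held"]
    failed = [j.job_index for j in bundle.jobs if j.state == "failed"]
    if held or failed:
        task_state = "error"
    elif counts.get("completed", 0) == len(bundle.jobs):
        task_state = "finished"
    else:
        task_state = "running"
    return StateSummary(counts=dict(counts), task_state=task_state,
                        held_jobs=held, failed_jobs=failed)
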