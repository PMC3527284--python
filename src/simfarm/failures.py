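"""Failure diagnosis and notification.

A failed task is classified by parsing the per-job log files: a job that was
held with no execute record failed *before* execution (a malformed
submission), while a job that executed and exited non-zero failed *after*
(a task-setup problem).  Probable-cause text comes from an editable rule
table shipped as package data.  All files a task produced can be packaged
into one deterministic compressed archive for offline inspection, and every
terminal task fires exactly one notification through a pluggable sink.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .backend import poll_states
from .tasks import JobBundle

__all__ = [
    "FailureReport",
    "classify_failure",
    "package_failure_bundle",
    "Notifier",
    "LogSink",
    "FileSink",
]

logger = logging.getLogger("simfarm")


@dataclass
class FailureReport:
    task_id: str
    phase: str  # pre_execution | post_execution | unknown
    probable_cause: str
    affected_jobs: list[int]
    bundle_path: str | None = None

    def summary(self) -> str:
        return (f"task {self.task_id}: {self.phase} failure affecting jobs "
                f"{self.affected_jobs} — {self.probable_cause}")


def _load_rules() -> dict:
    text = resources.files("simfarm.data").joinpath("failure_rules.yaml").read_text()
    return yaml.safe_load(text)


def read_job_log(workdir, job_index: int) -> str:
    path = Path(workdir) / f"job_{job_index}.log"
    return path.read_text()


def classify_failure(bundle: JobBundle, workdir, task_id: str | None = None) -> FailureReport:
    """Classify a failed bundle from its per-job logs.

    Phase is ``pre_execution`` iff every affected job was held before any
    execute record appears in its log; jobs that executed and then exited
    non-zero make the phase ``post_execution``.  Unreadable logs yield the
    ``unknown`` classification with the parse error attached.
    """
    summary = poll_states(bundle)
    if summary.task_state != "error":
        raise ValueError("classify_failure requires a task in the error state")
    affected = sorted(summary.held_jobs + summary.failed_jobs)
    task_id = task_id or bundle.task.name

    logs: dict[int, str] = {}
    for idx in affected:
        try:
            logs[idx] = read_job_log(workdir, idx)
        except OSError as exc:
            return FailureReport(task_id=task_id, phase="unknown",
                                 probable_cause=f"could not read job log: {exc}",
                                 affected_jobs=affected)

    executed = {idx for idx, text in logs.items() if "executing" in text}
    phase = "pre_execution" if not executed else "post_execution"

    rules = _load_rules()
    cause = rules["fallback"][phase]
    joined = "\n".join(logs.values())
    for rule in rules["rules"]:
        if rule["phase"] == phase and rule["pattern"] in joined:
            cause = rule["cause"]
            break
    return FailureReport(task_id=task_id, phase=phase, probable_cause=cause,
                         affected_jobs=affected)


def package_failure_bundle(task_dir, archive_path=None) -> Path:
    """Zip every file in the task directory (job documents, submit
    descriptions, logs, partial outputs) with a deterministic, sorted member
    listing and fixed timestamps, so packaging the same directory twice
    yields identical archives."""
    task_dir = Path(task_dir)
    files = sorted(p for p in task_dir.rglob("*") if p.is_file() and p.suffix != ".zip")
    if not files:
        raise ValueError(f"nothing to package: {task_dir} has no files")
    archive_path = Path(archive_path or task_dir / "failure_bundle.zip")
    with zipfile.ZipFile(archive_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for p in files:
            info = zipfile.ZipInfo(str(p.relative_to(task_dir)),
                                   date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, p.read_bytes())
    return archive_path


class LogSink:
    """Notification sink that records to the activity log."""

    def deliver(self, task_id: str, state: str, detail: str) -> None:
        logger.info("notification: task %s %s %s", task_id, state, detail)


class FileSink:
    """Notification sink that appends one line per event to a file."""

    def __init__(self, path):
        self.path = Path(path)

    def deliver(self, task_id: str, state: str, detail: str) -> None:
        with open(self.path, "a") as fh:
            fh.write(f"{task_id}\t{state}\t{detail}\n")


class CallbackSink:
    def __init__(self, fn):
        self.fn = fn

    def deliver(self, task_id: str, state: str, detail: str) -> None:
        self.fn(task_id, state, detail)


@dataclass
class Notifier:
    """Delivers exactly one notification per (task, terminal state).

    A repeat call for the same terminal event is suppressed; a sink failure
    is logged and never propagates to the task.
    """

    sink: object
    _delivered: set = field(default_factory=set)

    def notify(self, task_id: str, state: str, report: FailureReport | None = None) -> bool:
        if state not in ("finished", "failed"):
            raise ValueError(f"notify requires a terminal state, got {state!r}")
        key = (task_id, state)
        if key in self._delivered:
            return False
        detail = report.summary() if report is not None else ""
        try:
            self.sink.deliver(task_id, state, detail)
        except Exception as exc:  # noqa: BLE001 - sink failure must not kill the task
            logger.error("notification sink failed for task %s: %s", task_id, exc)
        self._delivered.add(key)
        return True
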