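"""Per-task usage records and the speed-up statistic.

CPU hours sum every job attempt's processor time (an evicted attempt's work
is real cost, so it counts); queueing time is excluded.  Wall-clock hours
run from task submission to task end and include any time spent waiting for
resources.  The speed-up factor is CPU time / wall-clock time: how much
faster the task finished than a serial run of the same work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .tasks import JobBundle

__all__ = ["UsageRecord", "record_usage", "speedup", "UsageStore"]

logger = logging.getLogger("simfarm")


@dataclass
class UsageRecord:
    task_id: str
    submission_time: float  # epoch seconds
    end_time: float
    n_jobs: int
    cpu_hours: float
    wall_clock: float  # hours

    @property
    def speedup(self) -> float:
        return speedup(self)


def record_usage(bundle: JobBundle, submission_time: float, end_time: float,
                 task_id: str | None = None) -> UsageRecord:
    """Build the usage record for a finished bundle.

    ``cpu_time`` on each job already sums all of its attempts (eviction
    reruns included).  A job with no recorded CPU time counts as 0 with a
    warning.
    """
    if end_time <= submission_time:
        raise ValueError("end time must be after submission time")
    cpu_seconds = 0.0
    for job in bundle.jobs:
        if job.cpu_time is None:
            logger.warning("job %d has no recorded CPU time; counting 0", job.job_index)
        else:
            cpu_seconds += job.cpu_time
    return UsageRecord(
        task_id=task_id or bundle.task.name,
        submission_time=submission_time,
        end_time=end_time,
        n_jobs=len(bundle.jobs),
        cpu_hours=cpu_seconds / 3600.0,
        wall_clock=(end_time - submission_time) / 3600.0,
    )


def speedup(record: UsageRecord) -> float:
    """Speed-up factor = CPU time / wall-clock time."""
    if record.wall_clock <= 0:
        raise ValueError("wall-clock time must be positive")
    return record.cpu_hours / record.wall_clock


_COLUMNS = ["task_id", "submission_time", "end_time", "n_jobs",
            "cpu_hours", "wall_clock", "speedup"]


class UsageStore:
    """Append-only TSV store of usage records."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.exists():
            self.path.write_text("\t".join(_COLUMNS) + "\n")

    def append(self, record: UsageRecord) -> None:
        row = [record.task_id, f"{record.submission_time:.3f}", f"{record.end_time:.3f}",
               str(record.n_jobs), f"{record.cpu_hours:.8g}",
               f"{record.wall_clock:.8g}", f"{record.speedup:.8g}"]
        with open(self.path, "a") as fh:
            fh.write("\t".join(row) + "\n")

    def load(self) -> list[UsageRecord]:
        records = []
        with open(self.path) as fh:
            next(fh)  # header
            for line in fh:
                if not line.strip():
                    continue
                tid, sub, end, n, cpu, wall, _sp = line.rstrip("\n").split("\t")
                records.append(UsageRecord(task_id=tid, submission_time=float(sub),
                                           end_time=float(end), n_jobs=int(n),
                                           cpu_hours=float(cpu), wall_clock=float(wall)))
        return records

    def aggregates(self) -> dict:
        """Summary statistics recomputed from the store."""
        records = self.load()
        if not records:
            return {"count": 0}
        speedups = [r.speedup for r in records]
        return {
            "count": len(records),
            "total_cpu_hours": sum(r.cpu_hours for r in records),
            "total_jobs": sum(r.n_jobs for r in records),
            "mean_speedup": sum(speedups) / len(speedups),
            "max_speedup": max(speedups),
        }
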