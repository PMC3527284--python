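"""Load balancing: pack repeats into jobs targeting a per-job runtime *t*.

The balancer first times a single repeat of the task, then assigns
floor(t_target / single_time) repeats to each job so no job is predicted to
run longer than the target.  A single repeat slower than the target (or one
that exceeds the benchmark budget and is abandoned) forces one repeat per
job, as does the user override.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

__all__ = [
    "LoadBalanceConfig",
    "BenchmarkResult",
    "benchmark_single_repeat",
    "repeats_per_job",
    "TaskSetupError",
]

DEFAULT_T_TARGET = 900.0  # seconds; 15 minutes


class TaskSetupError(RuntimeError):
    """The benchmark repeat itself failed — a pre-submission failure."""


@dataclass
class LoadBalanceConfig:
    """``t_target`` is the administrator-set target per-job runtime in
    seconds; ``benchmark_cap`` bounds the wall-clock spent measuring one
    repeat (defaults to ``t_target``)."""

    t_target: float = DEFAULT_T_TARGET
    override_one_per_job: bool = False
    benchmark_cap: float | None = None

    def __post_init__(self) -> None:
        if self.t_target <= 0:
            raise ValueError(f"t_target must be positive, got {self.t_target}")
        if self.benchmark_cap is None:
            self.benchmark_cap = self.t_target
        if self.benchmark_cap <= 0:
            raise ValueError(f"benchmark_cap must be positive, got {self.benchmark_cap}")


@dataclass
class BenchmarkResult:
    seconds: float
    timed_out: bool = False


def benchmark_single_repeat(run_one_repeat, config: LoadBalanceConfig,
                            clock=time.perf_counter) -> BenchmarkResult:
    """Time one repeat (wall clock).  ``run_one_repeat`` is a zero-argument
    callable executing exactly one repeat of the task; it may honour a
    ``deadline`` keyword to abandon work past the benchmark budget.

    If the measured time exceeds ``benchmark_cap`` the cap value is returned
    flagged as timed out.  The benchmark repeat is a pure measurement and is
    never counted towards the task's repeats.
    """
    start = clock()
    try:
        try:
            run_one_repeat(deadline=start + config.benchmark_cap)
        except TypeError:
            run_one_repeat()
    except Exception as exc:  # noqa: BLE001 - any repeat failure is a setup failure
        raise TaskSetupError(f"benchmark repeat failed: {exc}") from exc
    elapsed = clock() - start
    if elapsed > config.benchmark_cap:
        return BenchmarkResult(seconds=config.benchmark_cap, timed_out=True)
    return BenchmarkResult(seconds=elapsed, timed_out=False)


def repeats_per_job(single_time: float | BenchmarkResult,
                    config: LoadBalanceConfig) -> int:
    """Repeats per job for a measured single-repeat time.

    Rules, in order: the one-per-job override wins; a repeat at or above the
    target (including timed-out benchmarks) gets one repeat per job;
    otherwise floor(t_target / single_time), never below 1.  floor (not
    round) keeps each job's predicted runtime at or under the target, which
    is what bounds the work lost to an eviction.
    """
    if isinstance(single_time, BenchmarkResult):
        if single_time.timed_out:
            return 1
        single_time = single_time.seconds
    if single_time <= 0:
        raise ValueError(f"single_time must be positive, got {single_time}")
    if config.override_one_per_job:
        return 1
    if single_time >= config.t_target:
        return 1
    return max(1, int(config.t_target // single_time))
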