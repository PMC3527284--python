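"""Bounded-box optimizers: global-best particle swarm and a deterministic
local search (bounded Nelder–Mead).

Both routes share the same contract: every probed point lies inside the
bounds box, the progress trace is monotone in the optimization direction,
and identical (problem, algorithm, settings, seed) inputs give identical
results.  Maximization is implemented by negating the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "OptimizationProblem",
    "OptimizationResult",
    "run_optimization",
    "OptimizationConfigError",
    "OptimizationFailure",
    "ALGORITHMS",
]

# constriction-standard PSO coefficients
PSO_INERTIA = 0.729
PSO_COGNITIVE = 1.494
PSO_SOCIAL = 1.494

ALGORITHMS = ("particle_swarm", "local_search")


class OptimizationConfigError(ValueError):
    """Unknown algorithm or out-of-range settings."""


class OptimizationFailure(RuntimeError):
    """The objective was non-finite at every probed point."""


@dataclass
class OptimizationProblem:
    objective: object  # callable: ndarray -> float
    bounds: list[tuple[float, float]]
    direction: str = "minimize"

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"direction must be minimize/maximize, got {self.direction!r}")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bounds require lower < upper, got ({lo}, {hi})")


@dataclass
class OptimizationResult:
    best_value: float
    best_parameters: np.ndarray
    algorithm: str
    evaluations: int
    progress_trace: list[tuple[int, float]] = field(default_factory=list)

    def trace_tsv(self) -> str:
        """Two-column TSV (step, best value so far) for progress charts."""
        lines = ["step\tbest_value"]
        lines += [f"{s}\t{v:.10g}" for s, v in self.progress_trace]
        return "\n".join(lines) + "\n"


class _TrackedObjective:
    """Wraps the (possibly negated) objective: clamps to bounds, counts
    evaluations, and records the monotone best-so-far trace."""

    def __init__(self, fn, bounds, sign):
        self.fn = fn
        self.lo = np.array([b[0] for b in bounds])
        self.hi = np.array([b[1] for b in bounds])
        self.sign = sign
        self.evaluations = 0
        self.best = np.inf
        self.best_x = None
        self.trace: list[tuple[int, float]] = []
        self.any_finite = False

    def __call__(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        v = self.sign * float(self.fn(x))
        self.evaluations += 1
        if np.isfinite(v):
            self.any_finite = True
            if v < self.best:
                self.best = v
                self.best_x = x.copy()
            return v
        return np.inf


def run_optimization(problem: OptimizationProblem, algorithm: str,
                     settings: dict | None = None, seed: int = 0) -> OptimizationResult:
    """Run one bounded optimization and return the best point found.

    ``particle_swarm`` is a global-best PSO (inertia 0.729, cognitive and
    social weights 1.494, positions clamped to the box, fully determined by
    ``seed``).  ``local_search`` is a deterministic bounded Nelder–Mead
    started from the box center; ``seed`` is ignored for it.
    """
    settings = dict(settings or {})
    if algorithm not in ALGORITHMS:
        raise OptimizationConfigError(
            f"unknown algorithm {algorithm!r}; available: {ALGORITHMS}"
        )
    sign = 1.0 if problem.direction == "minimize" else -1.0
    tracked = _TrackedObjective(problem.objective, problem.bounds, sign)

    if algorithm == "particle_swarm":
        _pso(tracked, problem.bounds, settings, seed)
    else:
        _nelder_mead(tracked, problem.bounds, settings)

    if not tracked.any_finite:
        raise OptimizationFailure("objective non-finite at every probed point")
    return OptimizationResult(
        best_value=sign * tracked.best,
        best_parameters=tracked.best_x,
        algorithm=algorithm,
        evaluations=tracked.evaluations,
        progress_trace=[(s, sign * v) for s, v in tracked.trace],
    )


def _pso(tracked: _TrackedObjective, bounds, settings, seed) -> None:
    swarm_size = int(settings.pop("swarm_size", 20))
    iterations = int(settings.pop("iterations", 100))
    if settings:
        raise OptimizationConfigError(f"unknown PSO settings: {sorted(settings)}")
    if swarm_size < 2:
        raise OptimizationConfigError(f"swarm_size must be >= 2, got {swarm_size}")
    if iterations < 1:
        raise OptimizationConfigError(f"iterations must be >= 1, got {iterations}")

    rng = np.random.default_rng(seed)
    lo, hi = tracked.lo, tracked.hi
    dim = len(bounds)
    span = hi - lo
    pos = lo + rng.random((swarm_size, dim)) * span
    vel = (rng.random((swarm_size, dim)) - 0.5) * span

    pbest = pos.copy()
    pbest_val = np.array([tracked(p) for p in pos])
    g = int(np.argmin(pbest_val))
    tracked.trace.append((0, tracked.best))

    for it in range(1, iterations + 1):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        vel = (PSO_INERTIA * vel
               + PSO_COGNITIVE * r1 * (pbest - pos)
               + PSO_SOCIAL * r2 * (pbest[g] - pos))
        pos = np.clip(pos + vel, lo, hi)
        for i in range(swarm_size):
            v = tracked(pos[i])
            if v < pbest_val[i]:
                pbest_val[i] = v
                pbest[i] = pos[i]
        g = int(np.argmin(pbest_val))
        tracked.trace.append((it, tracked.best))


def _nelder_mead(tracked: _TrackedObjective, bounds, settings) -> None:
    maxiter = int(settings.pop("maxiter", 400))
    xatol = float(settings.pop("xatol", 1e-8))
    fatol = float(settings.pop("fatol", 1e-8))
    if settings:
        raise OptimizationConfigError(f"unknown local_search settings: {sorted(settings)}")
    x0 = (tracked.lo + tracked.hi) / 2.0

    step = [0]

    def record(_xk):
        step[0] += 1
        tracked.trace.append((step[0], tracked.best))

    tracked(x0)
    tracked.trace.append((0, tracked.best))
    minimize(tracked, x0, method="Nelder-Mead", callback=record,
             options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol})
    # ensure the trace ends at the overall best even if the last callback
    # predates the final accepted point
    tracked.trace.append((step[0] + 1, tracked.best))
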