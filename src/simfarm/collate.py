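"""Collation: merge per-job outputs into what a serial run would produce.

Stochastic repeats are merged exactly from per-job partial moments
(n, Σx, Σx² per time point per species), so any chunking of the same repeat
ensemble gives identical means and standard deviations.  Scan chunks are
concatenated in job order, reproducing the single-machine output byte for
byte.  Optimization-style tasks reduce to a best-of selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ReactionNetworkModel, write_native_model
from .optimize import OptimizationResult

__all__ = [
    "EnsembleSummary",
    "SensitivityReport",
    "CollationError",
    "summarize_ensemble",
    "concatenate_scan_outputs",
    "select_best",
    "best_algorithms",
    "sensitivity_report",
]


class CollationError(RuntimeError):
    pass


@dataclass
class EnsembleSummary:
    """Per-timepoint, per-species mean and standard deviation over repeats."""

    time_grid: np.ndarray
    species: list[str]
    mean: np.ndarray  # (time, species)
    sd: np.ndarray
    n_repeats: int

    def to_tsv(self, path) -> None:
        """Time, then <species>_mean and <species>_sd columns."""
        header = ["Time"]
        for sp in self.species:
            header += [f"{sp}_mean", f"{sp}_sd"]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, t in enumerate(self.time_grid):
                row = [format(t, ".10g")]
                for j in range(len(self.species)):
                    row += [format(self.mean[i, j], ".10g"), format(self.sd[i, j], ".10g")]
                fh.write("\t".join(row) + "\n")


def summarize_ensemble(chunk_summaries, *, sd_divisor: str = "sample") -> EnsembleSummary:
    """Pool per-job partial moments into one ensemble summary.

    Each chunk is ``(n, grid, species, sums, sums_of_squares)`` with arrays of
    shape (time, species).  The pooled mean is Σx/Σn and the standard
    deviation is the sample SD (divisor n−1; set ``sd_divisor='population'``
    for divisor n).  With a single repeat the SD is reported as 0.
    """
    if not chunk_summaries:
        raise CollationError("no chunk summaries to pool")
    if sd_divisor not in ("sample", "population"):
        raise ValueError(f"sd_divisor must be 'sample' or 'population', got {sd_divisor!r}")
    n_total = 0
    grid0 = species0 = None
    total = totalsq = None
    for idx, (n, grid, species, s, ss) in enumerate(chunk_summaries):
        if grid0 is None:
            grid0, species0 = np.asarray(grid, dtype=float), list(species)
            total = np.zeros_like(np.asarray(s, dtype=float))
            totalsq = np.zeros_like(total)
        else:
            if list(species) != species0 or not np.array_equal(np.asarray(grid), grid0):
                raise CollationError(f"chunk {idx} has a mismatched time grid or species order")
        n_total += int(n)
        total += np.asarray(s, dtype=float)
        totalsq += np.asarray(ss, dtype=float)
    mean = total / n_total
    if n_total == 1:
        sd = np.zeros_like(mean)
    else:
        div = n_total - 1 if sd_divisor == "sample" else n_total
        var = (totalsq - n_total * mean**2) / div
        sd = np.sqrt(np.maximum(var, 0.0))
    return EnsembleSummary(time_grid=grid0, species=species0, mean=mean,
                           sd=sd, n_repeats=n_total)


def concatenate_scan_outputs(chunk_paths, out_path) -> None:
    """Header + all chunks' data rows in job order, as one TSV file —
    identical to the output of running the whole grid serially."""
    chunk_paths = list(chunk_paths)
    missing = [str(p) for p in chunk_paths if not p.exists()]
    if missing:
        raise CollationError(f"missing scan chunk outputs: {missing}")
    header = None
    with open(out_path, "w") as out:
        for p in chunk_paths:
            with open(p) as fh:
                first = fh.readline()
                if header is None:
                    header = first
                    out.write(header)
                elif first != header:
                    raise CollationError(f"chunk {p} has a mismatched header")
                for line in fh:
                    out.write(line)


def select_best(results: list[OptimizationResult], direction: str,
                *, model: ReactionNetworkModel | None = None,
                parameter_names: list[str] | None = None):
    """Extremal best_value for the direction; ties go to the earliest entry
    (lowest job index).  If a model and parameter names are given, also
    return the model document with the winning parameter values substituted.
    """
    if not results:
        raise CollationError("no optimization results to select from")
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"direction must be minimize/maximize, got {direction!r}")
    sign = 1.0 if direction == "minimize" else -1.0
    best = min(range(len(results)), key=lambda i: (sign * results[i].best_value, i))
    winner = results[best]
    if model is not None and parameter_names is not None:
        updated = model.with_parameters(
            dict(zip(parameter_names, map(float, winner.best_parameters))))
        return winner, write_native_model(updated)
    return winner


def best_algorithms(results: dict[str, OptimizationResult], direction: str,
                    tolerance: float = 0.0) -> set[str]:
    """All algorithms whose best value is within ``tolerance`` of the
    extremal one (default 0: exact ties only)."""
    if not results:
        raise CollationError("no per-algorithm results")
    sign = 1.0 if direction == "minimize" else -1.0
    extremal = min(sign * r.best_value for r in results.values())
    return {name for name, r in results.items()
            if sign * r.best_value <= extremal + tolerance}


@dataclass
class SensitivityReport:
    """Per-parameter max/min sensitivity and importance = max − min."""

    parameters: list[str]
    max_value: dict[str, float]
    min_value: dict[str, float]
    importance: dict[str, float]
    traces: dict[str, dict[str, list[tuple[int, float]]]]  # param -> {max,min} -> trace

    def to_tsv(self) -> str:
        lines = ["parameter\tmax_value\tmin_value\timportance"]
        for p in self.parameters:
            lines.append(f"{p}\t{self.max_value[p]:.10g}\t{self.min_value[p]:.10g}"
                         f"\t{self.importance[p]:.10g}")
        return "\n".join(lines) + "\n"


def sensitivity_report(parameters: list[str],
                       results: list[OptimizationResult]) -> SensitivityReport:
    """Build the per-parameter report from 2·P optimization results ordered
    (param 0 max, param 0 min, param 1 max, ...)."""
    if len(results) != 2 * len(parameters):
        raise CollationError(
            f"expected {2 * len(parameters)} results for {len(parameters)} "
            f"parameters, got {len(results)}")
    max_v, min_v, imp, traces = {}, {}, {}, {}
    for i, p in enumerate(parameters):
        r_max, r_min = results[2 * i], results[2 * i + 1]
        max_v[p] = float(r_max.best_value)
        min_v[p] = float(r_min.best_value)
        if max_v[p] < min_v[p]:
            raise CollationError(f"parameter {p!r}: max sensitivity below min "
                                 "(results paired in the wrong order?)")
        imp[p] = max_v[p] - min_v[p]
        traces[p] = {"max": list(r_max.progress_trace), "min": list(r_min.progress_trace)}
    return SensitivityReport(parameters=list(parameters), max_value=max_v,
                             min_value=min_v, importance=imp, traces=traces)
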