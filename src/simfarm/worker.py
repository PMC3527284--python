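"""Execution of one self-contained job document.

This is the code the pool runs: it receives nothing but the job document
(model text + task fragment + seed) and a working directory, and writes the
job's output file there.  Per-repeat random seeds are derived from
``(base_seed, global repeat index)`` so results do not depend on how repeats
were chunked into jobs.
"""

from __future__ import annotations

import shlex
import subprocess
from pathlib import Path

import numpy as np
import yaml

from .model import read_native_model
from .objectives import (
    make_estimation_objective,
    make_sensitivity_objective,
    make_target_objective,
    parse_dataset,
)
from .optimize import OptimizationProblem, OptimizationResult, run_optimization
from .simulate import _steady_state, simulate_ode, simulate_ssa

__all__ = ["execute_job", "repeat_seed", "result_to_dict", "result_from_dict"]


def repeat_seed(base_seed: int, repeat_index: int) -> int:
    """Deterministic 31-bit seed for one global repeat index."""
    ss = np.random.SeedSequence((base_seed, repeat_index))
    return int(ss.generate_state(1)[0] % (2**31))


def result_to_dict(result: OptimizationResult) -> dict:
    return {
        "best_value": float(result.best_value),
        "best_parameters": [float(v) for v in result.best_parameters],
        "algorithm": result.algorithm,
        "evaluations": int(result.evaluations),
        "progress_trace": [[int(s), float(v)] for s, v in result.progress_trace],
    }


def result_from_dict(d: dict) -> OptimizationResult:
    return OptimizationResult(
        best_value=d["best_value"],
        best_parameters=np.array(d["best_parameters"], dtype=float),
        algorithm=d["algorithm"],
        evaluations=d["evaluations"],
        progress_trace=[(s, v) for s, v in d["progress_trace"]],
    )


def execute_job(document: dict, workdir: Path) -> None:
    """Run the work described by ``document`` and write its output file.

    Raises on any execution problem; the backend converts that into a
    non-zero exit status.
    """
    workdir = Path(workdir)
    task_type = document["task_type"]
    out_path = workdir / document["output"]
    if task_type == "stochastic_repeat":
        _run_stochastic(document, out_path)
    elif task_type == "scan":
        _run_scan(document, out_path)
    elif task_type in ("optimization_repeat", "parameter_estimation_repeat"):
        _run_optimization_repeats(document, out_path)
    elif task_type in ("sensitivity", "algorithm_sweep"):
        _run_single_optimization(document, out_path)
    elif task_type == "raw":
        _run_raw(document, workdir, out_path)
    else:
        raise ValueError(f"job document has unknown task type {task_type!r}")


def _run_stochastic(document: dict, out_path: Path) -> None:
    """Run the assigned stochastic repeats, emitting partial moments
    (n, per-timepoint sum, sum of squares) — an exact, bounded-size merge
    input for the ensemble summary."""
    model = read_native_model(document["model"])
    n_rep = int(document["repeats"])
    offset = int(document["repeat_offset"])
    base_seed = int(document["base_seed"])
    t_end, n_points = float(document["t_end"]), int(document["n_points"])

    total = None
    totalsq = None
    grid = None
    species = None
    for r in range(n_rep):
        traj = simulate_ssa(model, t_end=t_end, n_points=n_points,
                            seed=repeat_seed(base_seed, offset + r))
        if total is None:
            total = np.zeros_like(traj.values)
            totalsq = np.zeros_like(traj.values)
            grid, species = traj.time_grid, traj.species
        total += traj.values
        totalsq += traj.values ** 2
    _write_moments(out_path, n_rep, grid, species, total, totalsq)


def _write_moments(path: Path, n: int, grid, species, total, totalsq) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n={n}\n")
        header = ["Time"]
        for sp in species:
            header += [f"{sp}_sum", f"{sp}_sumsq"]
        fh.write("\t".join(header) + "\n")
        for i, t in enumerate(grid):
            row = [format(t, ".10g")]
            for j in range(len(species)):
                row += [repr(float(total[i, j])), repr(float(totalsq[i, j]))]
            fh.write("\t".join(row) + "\n")


def read_moments(path) -> tuple[int, np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Inverse of the moments writer: (n, grid, species, sums, sums of squares)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# n="):
            raise ValueError(f"{path}: missing '# n=' header line")
        n = int(first[4:])
        header = fh.readline().rstrip("\n").split("\t")
        rows = [list(map(float, line.split("\t"))) for line in fh if line.strip()]
    species = [c[:-4] for c in header[1:] if c.endswith("_sum")]
    data = np.array(rows, dtype=float)
    grid = data[:, 0]
    total = data[:, 1::2]
    totalsq = data[:, 2::2]
    return n, grid, species, total, totalsq


def _scan_result_columns(subtask: dict, model, point_params: dict,
                         t_end: float, n_points: int) -> tuple[list[str], list[float]]:
    m = model.with_parameters(point_params)
    kind = subtask.get("type", "time_course")
    if kind == "time_course":
        traj = simulate_ode(m, t_end=t_end, n_points=n_points)
        return list(m.species), [float(v) for v in traj.values[-1]]
    if kind == "steady_state":
        state = _steady_state(m)
        return list(m.species), [float(v) for v in state]
    if kind == "optimization":
        free = [(n, float(lo), float(hi)) for n, lo, hi in subtask["parameters"]]
        obj = make_target_objective(m, subtask["target"], [n for n, _, _ in free],
                                    mode=subtask.get("mode", "final_time"),
                                    t_end=t_end, n_points=n_points)
        problem = OptimizationProblem(objective=obj,
                                      bounds=[(lo, hi) for _, lo, hi in free],
                                      direction=subtask.get("direction", "minimize"))
        res = run_optimization(problem, subtask.get("algorithm", "local_search"),
                               subtask.get("settings", {}), seed=int(subtask.get("seed", 0)))
        return ["best_value"], [float(res.best_value)]
    raise ValueError(f"unknown scan subtask type {kind!r}")


def _run_scan(document: dict, out_path: Path) -> None:
    model = read_native_model(document["model"])
    names = document["parameter_names"]
    t_end, n_points = float(document["t_end"]), int(document["n_points"])
    subtask = document["subtask"]
    lines = []
    header = None
    for point in document["points"]:
        params = dict(zip(names, map(float, point)))
        cols, vals = _scan_result_columns(subtask, model, params, t_end, n_points)
        if header is None:
            header = "\t".join(list(names) + cols)
        lines.append("\t".join(format(v, ".10g") for v in list(point) + vals))
    with open(out_path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _optimization_problem(document: dict, model):
    frag = document["objective"]
    names = [p[0] for p in document["parameters"]]
    bounds = [(float(p[1]), float(p[2])) for p in document["parameters"]]
    if document["task_type"] == "parameter_estimation_repeat":
        objective = make_estimation_objective(model, parse_dataset(document["dataset"]), names)
        direction = "minimize"
    else:
        objective = make_target_objective(
            model, frag["target"], names, mode=frag["mode"],
            t_end=float(frag["t_end"]), n_points=int(frag["n_points"]))
        direction = frag.get("direction", "minimize")
    return OptimizationProblem(objective=objective, bounds=bounds,
                               direction=direction), names


def _run_optimization_repeats(document: dict, out_path: Path) -> None:
    model = read_native_model(document["model"])
    problem, names = _optimization_problem(document, model)
    offset = int(document["repeat_offset"])
    base_seed = int(document["base_seed"])
    results = []
    for r in range(int(document["repeats"])):
        res = run_optimization(problem, document["algorithm"],
                               dict(document["settings"]),
                               seed=repeat_seed(base_seed, offset + r))
        entry = result_to_dict(res)
        entry["repeat_index"] = offset + r
        entry["parameter_names"] = names
        results.append(entry)
    out_path.write_text(yaml.safe_dump(results, sort_keys=True))


def _run_single_optimization(document: dict, out_path: Path) -> None:
    model = read_native_model(document["model"])
    frag = document["objective"]
    if document["task_type"] == "sensitivity":
        names = [b[0] for b in document["bounds"]]
        bounds = [(float(b[1]), float(b[2])) for b in document["bounds"]]
        objective = make_sensitivity_objective(
            model, frag["target"], names, document["focus_parameter"],
            mode=frag["mode"], t_end=float(frag["t_end"]),
            n_points=int(frag["n_points"]))
        direction = document["direction"]
    else:  # algorithm_sweep
        names = [p[0] for p in document["parameters"]]
        bounds = [(float(p[1]), float(p[2])) for p in document["parameters"]]
        objective = make_target_objective(
            model, frag["target"], names, mode=frag["mode"],
            t_end=float(frag["t_end"]), n_points=int(frag["n_points"]))
        direction = frag.get("direction", "minimize")
    problem = OptimizationProblem(objective=objective, bounds=bounds, direction=direction)
    res = run_optimization(problem, document["algorithm"],
                           dict(document["settings"]), seed=int(document["seed"]))
    entry = result_to_dict(res)
    entry["parameter_names"] = names
    if document["task_type"] == "sensitivity":
        entry["focus_parameter"] = document["focus_parameter"]
        entry["direction"] = document["direction"]
    out_path.write_text(yaml.safe_dump(entry, sort_keys=True))


def _run_raw(document: dict, workdir: Path, out_path: Path) -> None:
    """Raw mode: run the user-supplied executable with the substituted
    argument string, or — with no executable configured — record the
    substituted arguments in the output file."""
    args = document["arguments"]
    exe = document.get("executable") or ""
    if exe:
        proc = subprocess.run([exe, *shlex.split(args)], cwd=workdir,
                              capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"raw executable exited {proc.returncode}: {proc.stderr[:500]}")
        if not out_path.exists():
            out_path.write_text(proc.stdout)
    else:
        out_path.write_text(args + "\n")


if __name__ == "__main__":  # pool entry point: run one job document
    import sys

    _doc = yaml.safe_load(Path(sys.argv[1]).read_text())
    execute_job(_doc, Path(sys.argv[2]) if len(sys.argv) > 2 else Path("."))
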