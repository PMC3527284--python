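"""Objective functions built from a model and a task fragment.

Three kinds of objective are used by the task types:

* a plain *target* objective — evaluate the task's target expression at the
  final time or steady state, as a function of a free-parameter vector;
* a *sensitivity* objective — the scaled sensitivity coefficient
  (p_i / T) * dT/dp_i of the target T with respect to one focus parameter,
  evaluated by central finite differences, as a function of the position in
  the full parameter box (this is what the global sensitivity task maximizes
  and minimizes per parameter);
* an *estimation* objective — the sum of squared residuals between a
  deterministic time course and an observed dataset.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .model import ReactionNetworkModel
from .simulate import evaluate_target, simulate_ode

__all__ = [
    "make_target_objective",
    "make_sensitivity_objective",
    "make_estimation_objective",
    "parse_dataset",
]

SENSITIVITY_REL_STEP = 1e-3  # central-difference relative perturbation


def make_target_objective(model: ReactionNetworkModel, target: str,
                          parameter_names: list[str], *, mode: str = "final_time",
                          t_end: float = 10.0, n_points: int = 101):
    """Objective mapping a vector over ``parameter_names`` to the target value."""

    def objective(x: np.ndarray) -> float:
        m = model.with_parameters(dict(zip(parameter_names, map(float, x))))
        return evaluate_target(m, target, mode=mode, t_end=t_end, n_points=n_points)

    return objective


def make_sensitivity_objective(model: ReactionNetworkModel, target: str,
                               parameter_names: list[str], focus_parameter: str, *,
                               mode: str = "final_time", t_end: float = 10.0,
                               n_points: int = 101,
                               rel_step: float = SENSITIVITY_REL_STEP):
    """Scaled sensitivity of the target w.r.t. ``focus_parameter``.

    At a point p in the box, returns (p_i / T(p)) * dT/dp_i estimated by a
    central difference with relative step ``rel_step``.  When T(p) is zero
    the unscaled derivative is returned (the scaling would divide by zero).
    """
    if focus_parameter not in parameter_names:
        raise ValueError(f"{focus_parameter!r} is not among the free parameters")
    i = parameter_names.index(focus_parameter)
    base = make_target_objective(model, target, parameter_names,
                                 mode=mode, t_end=t_end, n_points=n_points)

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        p = x[i]
        h = rel_step * (abs(p) if p != 0 else 1.0)
        up, dn = x.copy(), x.copy()
        up[i] += h
        dn[i] -= h
        t_val = base(x)
        deriv = (base(up) - base(dn)) / (2 * h)
        if t_val == 0.0:
            return deriv
        return (p / t_val) * deriv

    return objective


def parse_dataset(tsv_text: str) -> pd.DataFrame:
    """Parse an embedded dataset: a 'Time' column plus observed species."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t")
    if df.columns[0] != "Time":
        raise ValueError(f"dataset must start with a 'Time' column, got {df.columns[0]!r}")
    return df


def make_estimation_objective(model: ReactionNetworkModel, dataset: pd.DataFrame,
                              parameter_names: list[str]):
    """Sum of squared residuals between the deterministic time course and the
    dataset's observed species columns, on the dataset's own time grid."""
    times = dataset["Time"].to_numpy(dtype=float)
    observed_species = [c for c in dataset.columns if c != "Time"]
    unknown = set(observed_species) - set(model.species)
    if unknown:
        raise ValueError(f"dataset observes unknown species: {sorted(unknown)}")
    if times[0] != 0.0 or len(times) < 2:
        raise ValueError("dataset time grid must start at 0 with >= 2 points")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0]):
        raise ValueError("dataset time grid must be uniform")
    obs = dataset[observed_species].to_numpy(dtype=float)

    def objective(x: np.ndarray) -> float:
        m = model.with_parameters(dict(zip(parameter_names, map(float, x))))
        traj = simulate_ode(m, t_end=float(times[-1]), n_points=len(times))
        cols = [traj.species.index(s) for s in observed_species]
        return float(np.sum((traj.values[:, cols] - obs) ** 2))

    return objective
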