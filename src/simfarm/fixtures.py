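"""Built-in toy models, workload stubs and synthetic datasets.

Everything every other module needs for testing and examples is generated
here, with no downloads: small mass-action networks with known closed-form
or easily-oracled behaviour, sleep-based workload stubs for timing the load
balancer, and a seed-deterministic synthetic parameter-estimation dataset
generator (simulate a fixture, add i.i.d. Gaussian noise, emit TSV together
with the true parameters for recovery tests).

The catalog models are structurally analogous stand-ins for the published
signalling/oscillation models that large production runs use; the properties
under test here (splitting arithmetic, balancing, collation exactness) do
not depend on the biology.
"""

from __future__ import annotations

import io
import time

import numpy as np
import pandas as pd

from .model import Reaction, ReactionNetworkModel
from .simulate import simulate_ode

__all__ = ["get_model", "list_models", "sleep_workload", "make_estimation_dataset"]


def _birth_death() -> ReactionNetworkModel:
    """Immigration–death: ∅→A at rate k, A→∅ at rate d·A.  Stationary law is
    Poisson(k/d), so mean = variance = k/d (10 by default)."""
    return ReactionNetworkModel(
        name="birth_death",
        species={"A": 0.0},
        parameters={"k": 10.0, "d": 1.0},
        reactions=[
            Reaction(reactants={}, products={"A": 1}, rate_constant="k", name="birth"),
            Reaction(reactants={"A": 1}, products={}, rate_constant="d", name="death"),
        ],
    )


def _decay() -> ReactionNetworkModel:
    """First-order decay A→∅: A(t) = A(0)·exp(−k·t)."""
    return ReactionNetworkModel(
        name="decay",
        species={"A": 100.0},
        parameters={"k": 1.0},
        reactions=[Reaction(reactants={"A": 1}, products={}, rate_constant="k",
                            name="decay")],
    )


def _isomerization() -> ReactionNetworkModel:
    """A⇌B with total amount conserved (50)."""
    return ReactionNetworkModel(
        name="isomerization",
        species={"A": 50.0, "B": 0.0},
        parameters={"kf": 1.0, "kr": 0.5},
        reactions=[
            Reaction(reactants={"A": 1}, products={"B": 1}, rate_constant="kf", name="fwd"),
            Reaction(reactants={"B": 1}, products={"A": 1}, rate_constant="kr", name="rev"),
        ],
    )


def _dimerization() -> ReactionNetworkModel:
    """Irreversible dimerization 2A→B."""
    return ReactionNetworkModel(
        name="dimerization",
        species={"A": 100.0, "B": 0.0},
        parameters={"k": 0.01},
        reactions=[Reaction(reactants={"A": 2}, products={"B": 1}, rate_constant="k",
                            name="dimerize")],
    )


def _oscillator_3var() -> ReactionNetworkModel:
    """A 3-species mass-action predator–prey oscillator (Lotka-type):
    food S catalyses prey growth, prey X feeds predator Y, Y decays.
    Sustained oscillations in X and Y — a small stand-in for oscillating
    signalling models."""
    return ReactionNetworkModel(
        name="oscillator_3var",
        species={"S": 10.0, "X": 10.0, "Y": 10.0},
        parameters={"k1": 1.0, "k2": 0.1, "k3": 1.0},
        reactions=[
            Reaction(reactants={"S": 1, "X": 1}, products={"S": 1, "X": 2},
                     rate_constant="k1", name="prey_growth"),
            Reaction(reactants={"X": 1, "Y": 1}, products={"Y": 2},
                     rate_constant="k2", name="predation"),
            Reaction(reactants={"Y": 1}, products={}, rate_constant="k3",
                     name="predator_death"),
        ],
    )


_CATALOG = {
    "birth_death": _birth_death,
    "decay": _decay,
    "isomerization": _isomerization,
    "dimerization": _dimerization,
    "oscillator_3var": _oscillator_3var,
}

# default simulation horizons giving visible dynamics for each fixture
DEFAULT_T_END = {
    "birth_death": 10.0,
    "decay": 5.0,
    "isomerization": 5.0,
    "dimerization": 5.0,
    "oscillator_3var": 20.0,
}


def list_models() -> list[str]:
    return sorted(_CATALOG)


def get_model(name: str) -> ReactionNetworkModel:
    """A fresh, validated instance of a catalog model."""
    try:
        return _CATALOG[name]()
    except KeyError:
        raise KeyError(f"unknown fixture model {name!r}; available: {list_models()}") from None


def sleep_workload(duration: float):
    """A repeat stub that sleeps for ``duration`` seconds; honours the load
    balancer's ``deadline`` keyword by stopping early when the benchmark
    budget is exhausted."""

    def run_one_repeat(deadline: float | None = None) -> None:
        if deadline is None:
            time.sleep(duration)
            return
        remaining = deadline - time.perf_counter()
        time.sleep(min(duration, max(remaining, 0.0)) )

    return run_one_repeat


def make_estimation_dataset(model_name: str, noise_sd: float, n_points: int,
                            seed: int, t_end: float | None = None
                            ) -> tuple[str, dict[str, float]]:
    """Synthetic observations for parameter-recovery tests.

    Simulates the named fixture deterministically on a uniform grid, adds
    i.i.d. Gaussian noise of standard deviation ``noise_sd`` to every
    observation, and returns ``(tsv_text, true_parameters)``.  The same seed
    always yields the same dataset.
    """
    model = get_model(model_name)
    if t_end is None:
        t_end = DEFAULT_T_END[model_name]
    traj = simulate_ode(model, t_end=t_end, n_points=n_points)
    rng = np.random.default_rng(seed)
    observed = traj.values + rng.normal(0.0, noise_sd, size=traj.values.shape)
    df = pd.DataFrame({"Time": traj.time_grid})
    for j, sp in enumerate(traj.species):
        df[sp] = observed[:, j]
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    return buf.getvalue(), dict(model.parameters)
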