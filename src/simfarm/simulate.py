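"""Deterministic (ODE) and stochastic (SSA) simulation of mass-action networks.

The deterministic route assembles d[S]/dt from the stoichiometry and
integrates with an adaptive-step solver (LSODA, rtol 1e-8).  The stochastic
route is an exact Gillespie direct-method realization of the jump process,
reported on a uniform output grid by piecewise-constant left interpolation.

Rate conventions, with n_s the amount of species s in particle numbers and V
the compartment volume:

* ODE flux of a reaction with rate constant k and reactant stoichiometry
  {s: m_s}:  k * prod_s n_s**m_s / V**(order-1).
* SSA propensity: k * prod_s C(n_s, m_s) / V**(order-1), i.e. the number of
  distinct reactant combinations — n(n-1)/2 for an order-2 self-reaction.

For first-order (linear) networks the two conventions coincide, so SSA
ensemble means converge to the ODE solution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from .model import ReactionNetworkModel, Trajectory

__all__ = [
    "simulate_ode",
    "simulate_ssa",
    "evaluate_target",
    "IntegrationFailure",
    "NoSteadyStateError",
]


class IntegrationFailure(RuntimeError):
    """ODE integration produced a non-finite state or failed to converge."""


class NoSteadyStateError(RuntimeError):
    """Long-time integration did not reach the steady-state tolerance."""


def _build_rate_tables(model: ReactionNetworkModel):
    """Precompute per-reaction (rate constant, reactant index/stoich arrays,
    net stoichiometry change vector, volume scale)."""
    index = {sp: i for i, sp in enumerate(model.species)}
    n_sp = len(index)
    tables = []
    for rxn in model.reactions:
        k = model.parameters[rxn.rate_constant]
        r_idx = np.array([index[s] for s in rxn.reactants], dtype=int)
        r_sto = np.array(list(rxn.reactants.values()), dtype=int)
        change = np.zeros(n_sp)
        for s, c in rxn.reactants.items():
            change[index[s]] -= c
        for s, c in rxn.products.items():
            change[index[s]] += c
        vol_scale = model.volume ** (rxn.order - 1) if rxn.order > 1 else 1.0
        tables.append((k, r_idx, r_sto, change, vol_scale))
    return tables


def _time_grid(t_end: float, n_points: int) -> np.ndarray:
    if not (t_end > 0):
        raise ValueError(f"t_end must be positive, got {t_end}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    return np.linspace(0.0, t_end, n_points)


def simulate_ode(model: ReactionNetworkModel, t_end: float, n_points: int) -> Trajectory:
    """Integrate the mass-action ODEs on a uniform grid over [0, t_end]."""
    model.validate()
    tables = _build_rate_tables(model)
    grid = _time_grid(t_end, n_points)

    def rhs(_t, y):
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)  # guards tiny negative overshoot from the solver
        for k, r_idx, r_sto, change, vol in tables:
            flux = k / vol
            for i, m in zip(r_idx, r_sto):
                flux *= yc[i] ** m
            dy += flux * change
        return dy

    sol = solve_ivp(
        rhs, (0.0, t_end), model.initial_state(), method="LSODA",
        t_eval=grid, rtol=1e-8, atol=1e-10,
    )
    if not sol.success:
        raise IntegrationFailure(f"integration failed: {sol.message}")
    values = sol.y.T
    bad = ~np.isfinite(values)
    if bad.any():
        t_bad = grid[np.argwhere(bad)[0][0]]
        raise IntegrationFailure(f"non-finite state first seen at t={t_bad:g}")
    return Trajectory(time_grid=grid, values=values, species=model.species_names)


def _propensity(k: float, state: np.ndarray, r_idx, r_sto, vol: float) -> float:
    a = k / vol
    for i, m in zip(r_idx, r_sto):
        n = state[i]
        if m == 1:
            a *= n
        else:  # C(n, m): distinct reactant combinations
            if n < m:
                return 0.0
            comb = 1.0
            for j in range(m):
                comb *= (n - j)
            a *= comb / math.factorial(m)
    return max(a, 0.0)


def simulate_ssa(model: ReactionNetworkModel, t_end: float, n_points: int,
                 seed) -> Trajectory:
    """One exact Gillespie direct-method realization.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical seeds
    give bit-identical trajectories.  Initial amounts must be integers.
    """
    model.validate()
    state0 = model.initial_state()
    if np.any(state0 != np.round(state0)):
        raise ValueError("SSA requires integer initial amounts")
    tables = _build_rate_tables(model)
    grid = _time_grid(t_end, n_points)
    rng = np.random.default_rng(seed)

    state = state0.copy()
    out = np.empty((len(grid), len(state)))
    t = 0.0
    gi = 0  # next grid index to fill
    while True:
        props = np.array([_propensity(k, state, r_idx, r_sto, vol)
                          for k, r_idx, r_sto, _c, vol in tables])
        total = props.sum()
        if total <= 0.0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        # record state at every grid point strictly before the next event
        while gi < len(grid) and grid[gi] < t_next:
            out[gi] = state
            gi += 1
        if gi >= len(grid):
            break
        # fire the chosen reaction at t_next
        t = t_next
        choice = rng.random() * total
        acc = 0.0
        for j, p in enumerate(props):
            acc += p
            if choice < acc or j == len(props) - 1:
                state = state + tables[j][3]
                break
    return Trajectory(time_grid=grid, values=out, species=model.species_names)


# ---------------------------------------------------------------------------
# Target evaluation (objectives for sensitivity / optimization tasks)
# ---------------------------------------------------------------------------

_EVAL_GLOBALS = {"__builtins__": {}, "abs": abs, "min": min, "max": max,
                 "exp": math.exp, "log": math.log, "sqrt": math.sqrt}


def _steady_state(model: ReactionNetworkModel, tol: float = 1e-9,
                  t_block: float = 50.0, max_blocks: int = 200) -> np.ndarray:
    """Find a steady state by long-time integration, doubling the horizon
    until the derivative norm drops below ``tol``."""
    tables = _build_rate_tables(model)

    def rhs(_t, y):
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)
        for k, r_idx, r_sto, change, vol in tables:
            flux = k / vol
            for i, m in zip(r_idx, r_sto):
                flux *= yc[i] ** m
            dy += flux * change
        return dy

    state = model.initial_state()
    horizon = t_block
    for _ in range(max_blocks):
        sol = solve_ivp(rhs, (0.0, horizon), state, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise IntegrationFailure(f"integration failed: {sol.message}")
        state = sol.y[:, -1]
        if np.linalg.norm(rhs(0.0, state)) < tol:
            return state
        horizon *= 2.0
    raise NoSteadyStateError(
        f"derivative norm still >= {tol} after {max_blocks} doubling steps"
    )


def evaluate_target(model: ReactionNetworkModel, target_spec: str, *,
                    mode: str = "final_time", t_end: float = 10.0,
                    n_points: int = 101) -> float:
    """Evaluate an expression over species amounts and parameters.

    ``mode='final_time'`` uses the ODE state at ``t_end``;
    ``mode='steady_state'`` integrates until the derivative norm is < 1e-9.
    The expression may reference species names, parameter names and the
    functions abs/min/max/exp/log/sqrt.
    """
    if mode == "final_time":
        traj = simulate_ode(model, t_end=t_end, n_points=n_points)
        state = traj.values[-1]
    elif mode == "steady_state":
        state = _steady_state(model)
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    names: dict[str, float] = dict(model.parameters)
    names.update({sp: float(v) for sp, v in zip(model.species, state)})
    try:
        return float(eval(target_spec, _EVAL_GLOBALS, names))  # noqa: S307 - restricted namespace
    except NameError as exc:
        raise ValueError(f"target expression references an undefined name: {exc}") from exc
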