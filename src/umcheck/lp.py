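"""Linear and mixed-integer programming over the steady-state flux space.

Every optimisation in the package reduces to optimising a linear
functional over ``F = {v : N @ v = 0, lb <= v <= ub}`` (flux balance
analysis, per-reaction flux ranges) or to a small MILP built on the same
constraint block (minimal-medium prediction).  The backend is scipy's
HiGHS interface, driven with tight feasibility tolerances so that the
zero-flux test for blocked reactions is numerically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, sparse

from .config import DEFAULT_CONFIG, RunConfig
from .model import Model

__all__ = [
    "FluxDistribution",
    "FluxRange",
    "SolverError",
    "fba",
    "flux_minmax",
    "flux_variability",
    "solve_milp",
]


class SolverError(RuntimeError):
    """Backend failure that is not plain infeasibility."""


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state flux vector with the optimised objective value."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min: float
    max: float


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


def _highs_options(config: RunConfig) -> dict:
    return {
        "presolve": True,
        "primal_feasibility_tolerance": min(config.feasibility_tol, 1e-9),
        "dual_feasibility_tolerance": min(config.feasibility_tol, 1e-9),
    }


def _arrays(model: Model):
    n_mat = model.stoichiometric_matrix()
    lbs, ubs = model.bounds_arrays()
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    return n_mat, lbs, ubs, index


def _solve_lp(model: Model, c: np.ndarray, config: RunConfig):
    n_mat, lbs, ubs, _ = _arrays(model)
    res = optimize.linprog(
        c,
        A_eq=n_mat,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lbs, ubs]),
        method="highs",
        options=_highs_options(config),
    )
    status = _STATUS.get(res.status, "error")
    if status in ("iteration_limit", "numerical", "error"):
        raise SolverError(f"LP solver failed with status {res.status}: {res.message}")
    return res, status


def fba(
    model: Model,
    objective_id: str | None = None,
    direction: str = "max",
    config: RunConfig = DEFAULT_CONFIG,
) -> FluxDistribution:
    """Optimise a single reaction flux over the steady-state flux space.

    With ``objective_id=None`` the model's biomass reaction is optimised —
    classic flux balance analysis, where the biomass flux stands for the
    growth rate.
    """
    if objective_id is None:
        objective_id = model.biomass_id
        if objective_id is None:
            raise ValueError("model has no biomass reaction; pass objective_id")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    _, _, _, index = _arrays(model)
    if objective_id not in index:
        raise KeyError(f"unknown reaction id {objective_id!r}")
    c = np.zeros(model.n_reactions)
    c[index[objective_id]] = -1.0 if direction == "max" else 1.0
    res, status = _solve_lp(model, c, config)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    sign = -1.0 if direction == "max" else 1.0
    fluxes = dict(zip(model.reaction_ids, (float(x) for x in res.x)))
    return FluxDistribution(fluxes=fluxes, objective_value=float(sign * res.fun),
                            status=status)


def fba_objective(model: Model, weights: dict[str, float], direction: str = "max",
                  config: RunConfig = DEFAULT_CONFIG) -> FluxDistribution:
    """FBA with an arbitrary linear objective (weighted reaction fluxes)."""
    _, _, _, index = _arrays(model)
    c = np.zeros(model.n_reactions)
    sign = -1.0 if direction == "max" else 1.0
    for rid, w in weights.items():
        c[index[rid]] = sign * w
    res, status = _solve_lp(model, c, config)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    fluxes = dict(zip(model.reaction_ids, (float(x) for x in res.x)))
    return FluxDistribution(fluxes=fluxes, objective_value=float(sign * res.fun),
                            status=status)


def flux_minmax(
    model: Model, reaction_id: str, config: RunConfig = DEFAULT_CONFIG
) -> FluxRange:
    """Minimum and maximum steady-state flux through one reaction."""
    lo = fba(model, reaction_id, "min", config)
    hi = fba(model, reaction_id, "max", config)
    if not (lo.optimal and hi.optimal):
        raise SolverError(
            f"flux range for {reaction_id!r} unavailable: "
            f"min status {lo.status}, max status {hi.status}"
        )
    return FluxRange(reaction_id=reaction_id, min=lo.objective_value,
                     max=hi.objective_value)


def flux_variability(
    model: Model,
    reaction_ids: Iterable[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict[str, FluxRange]:
    """Flux ranges for many reactions (two LPs each)."""
    ids = list(reaction_ids) if reaction_ids is not None else model.reaction_ids
    out: dict[str, FluxRange] = {}
    for rid in ids:
        out[rid] = flux_minmax(model, rid, config)
    return out


@dataclass(frozen=True)
class MILPResult:
    x: np.ndarray | None
    objective_value: float | None
    status: str


def solve_milp(
    c: Sequence[float],
    a_matrix,
    con_lb: Sequence[float],
    con_ub: Sequence[float],
    var_lb: Sequence[float],
    var_ub: Sequence[float],
    integrality: Sequence[int],
    config: RunConfig = DEFAULT_CONFIG,
) -> MILPResult:
    """Solve ``min c @ x`` s.t. ``con_lb <= A @ x <= con_ub`` and variable
    bounds, with ``integrality[i] = 1`` marking integer variables."""
    a_matrix = sparse.csr_matrix(a_matrix)
    constraints = optimize.LinearConstraint(a_matrix, np.asarray(con_lb),
                                            np.asarray(con_ub))
    res = optimize.milp(
        c=np.asarray(c, dtype=float),
        constraints=constraints,
        integrality=np.asarray(integrality),
        bounds=optimize.Bounds(np.asarray(var_lb, dtype=float),
                               np.asarray(var_ub, dtype=float)),
        options={"time_limit": config.time_limit_s},
    )
    if res.status == 0:
        return MILPResult(x=res.x, objective_value=float(res.fun), status="optimal")
    if res.status == 2:
        return MILPResult(x=None, objective_value=None, status="infeasible")
    if res.status == 3:
        return MILPResult(x=None, objective_value=None, status="unbounded")
    raise SolverError(f"MILP solver failed: status {res.status}: {res.message}")
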