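"""Crowding-constrained flux balance solver.

Solves

    max  v_obj
    s.t. S·v = 0
         lb ≤ v ≤ ub        (uptake capacities folded into exchange ubs)
         Σ aᵢ·vᵢ ≤ budget   (enzyme-catalysed reactions; see crowding_lhs)

on a split (all-irreversible) network, with a lexicographic second stage
minimizing total flux Σ vᵢ among biomass optima so that reported uptake
hierarchies are single-valued.  Both stages are plain LPs solved with HiGHS
through :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = ["FluxProblem", "FluxState", "solve_fbawmc", "crowding_lhs"]

#: primal feasibility tolerance on S·v and the crowding constraint
FEASIBILITY_TOL = 1e-8
#: optimality / tie-breaking tolerance
OPTIMALITY_TOL = 1e-9


@dataclass(frozen=True)
class FluxProblem:
    """One FBAwMC instance: a split network plus uptake capacities U.

    ``uptake_capacity`` maps substrate names (keys of the network's
    ``substrate_exchange_ids``) to the maximum uptake flux U
    (mmol·gDW⁻¹·hr⁻¹); unnamed substrates keep their exchange upper bound.
    ``crowding_budget`` overrides the network's budget when given
    (``math.inf`` disables crowding = plain FBA).
    """

    network: MetabolicNetwork
    uptake_capacity: dict[str, float] = field(default_factory=dict)
    objective_id: str | None = None
    crowding_budget: float | None = None
    include_exchange_crowding: bool = False

    def __post_init__(self):
        unknown = set(self.uptake_capacity) - set(self.network.substrate_exchange_ids)
        if unknown:
            raise ValueError(f"uptake_capacity for unknown substrates {sorted(unknown)}")
        for s, u in self.uptake_capacity.items():
            if u < 0:
                raise ValueError(f"negative uptake capacity for {s}")
        if any(r.lower_bound < 0 for r in self.network.reactions):
            raise ValueError("network must be in split (irreversible) form")

    @property
    def budget(self) -> float:
        return (
            self.crowding_budget
            if self.crowding_budget is not None
            else self.network.crowding_budget
        )


@dataclass(frozen=True)
class FluxState:
    """One LP solution: fluxes, the growth rate μ and the crowding load."""

    fluxes: dict[str, float]
    growth_rate: float
    crowding_lhs: float
    status: str  # optimal | infeasible | unbounded
    objective_value: float = 0.0
    feasibility_tol: float = FEASIBILITY_TOL
    optimality_tol: float = OPTIMALITY_TOL

    def flux(self, rxn_id: str) -> float:
        return self.fluxes.get(rxn_id, 0.0)

    def net_flux(self, rxn_id: str) -> float:
        """Signed net flux of a possibly split reaction (forward − reverse)."""
        from .network import REVERSE_SUFFIX

        return self.fluxes.get(rxn_id, 0.0) - self.fluxes.get(
            rxn_id + REVERSE_SUFFIX, 0.0
        )


def crowding_lhs(
    fluxes: dict[str, float],
    coefficients: dict[str, float],
    include_exchanges: bool = False,
    exchange_ids: set[str] | None = None,
) -> float:
    """Σ aᵢ·vᵢ over enzyme-catalysed reactions of a split flux vector.

    Exchange pseudo-reactions carry no enzyme and are excluded unless
    ``include_exchanges`` (transporter-cost variant); the biomass reaction is
    included (ribosome demand).  ``coefficients`` must cover every flux id.
    """
    missing = set(fluxes) - set(coefficients)
    if missing:
        raise ValueError(f"no crowding coefficient for reactions {sorted(missing)}")
    exchange_ids = exchange_ids or set()
    total = 0.0
    for rid, v in fluxes.items():
        if not include_exchanges and rid in exchange_ids:
            continue
        total += coefficients[rid] * v
    return total


def _crowding_vector(problem: FluxProblem) -> np.ndarray:
    net = problem.network
    a = np.zeros(len(net.reactions))
    for j, r in enumerate(net.reactions):
        if r.kind == "exchange" and not problem.include_exchange_crowding:
            continue
        a[j] = r.crowding_coefficient
    return a


def solve_fbawmc(problem: FluxProblem) -> FluxState:
    """Solve one FBAwMC LP with parsimonious tie-breaking.

    Stage 1 maximizes the objective flux (biomass by default); stage 2 pins
    the objective at its optimum (within ``OPTIMALITY_TOL``) and minimizes
    Σ vᵢ, returning the unique parsimonious optimum.  Infeasibility and
    unboundedness are reported in ``status``, not raised.
    """
    net = problem.network
    n = len(net.reactions)
    obj_id = problem.objective_id or net.biomass_id
    try:
        j_obj = net.reaction_ids.index(obj_id)
    except ValueError:
        raise ValueError(f"objective reaction {obj_id!r} not in network") from None

    S = net.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in net.reactions])
    ub = np.array([r.upper_bound for r in net.reactions], dtype=float)
    # a specified capacity REPLACES the exchange bound: U is the capacity
    for s, u in problem.uptake_capacity.items():
        j = net.reaction_ids.index(net.substrate_exchange_ids[s])
        ub[j] = u
    ub = np.maximum(ub, lb)

    a = _crowding_vector(problem)
    budget = problem.budget
    A_ub, b_ub = None, None
    if math.isfinite(budget):
        A_ub, b_ub = a.reshape(1, -1), np.array([budget])

    c = np.zeros(n)
    c[j_obj] = -1.0
    bounds = list(zip(lb, ub))
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 2:
        return FluxState({}, math.nan, math.nan, "infeasible")
    if res.status == 3:
        return FluxState({}, math.inf, math.nan, "unbounded")
    if not res.success:  # numerical failure — surface as infeasible with context
        return FluxState({}, math.nan, math.nan, "infeasible")
    opt = -res.fun

    # stage 2: parsimonious flux with the objective pinned at its optimum
    bounds2 = list(bounds)
    bounds2[j_obj] = (opt, opt)
    res2 = linprog(np.ones(n), A_ub=A_ub, b_ub=b_ub, A_eq=S,
                   b_eq=np.zeros(S.shape[0]), bounds=bounds2, method="highs")
    if not res2.success:  # exact pin numerically infeasible: allow tiny slack
        bounds2[j_obj] = (max(lb[j_obj], opt - OPTIMALITY_TOL), ub[j_obj])
        res2 = linprog(np.ones(n), A_ub=A_ub, b_ub=b_ub, A_eq=S,
                       b_eq=np.zeros(S.shape[0]), bounds=bounds2, method="highs")
    x = res2.x if res2.success else res.x

    fluxes = {rid: float(v) for rid, v in zip(net.reaction_ids, x)}
    lhs = float(a @ x)
    j_bio = net.reaction_ids.index(net.biomass_id)
    return FluxState(
        fluxes=fluxes,
        growth_rate=float(x[j_bio]),
        crowding_lhs=lhs,
        status="optimal",
        objective_value=float(x[j_obj]),
    )
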