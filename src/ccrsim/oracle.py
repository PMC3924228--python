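"""Independent brute-force verification oracle for small FBAwMC instances.

The feasible set of an FBAwMC problem is a bounded polyhedron
{v : S·v = 0, lb ≤ v ≤ ub, a·v ≤ budget}; a linear objective attains its
maximum at a vertex, where the active constraints have full column rank.
The oracle enumerates every candidate vertex directly with dense linear
algebra — no LP solver involved — and returns the best feasible one.  It is
deliberately exponential and refuses instances beyond a small size, which is
exactly what makes it an independent check on :func:`ccrsim.fba.solve_fbawmc`.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .fba import FluxProblem, FluxState, _crowding_vector

__all__ = ["brute_force_oracle", "random_small_problem", "OracleSizeError"]

_FEAS_TOL = 1e-7


class OracleSizeError(ValueError):
    """Instance too large for exhaustive vertex enumeration."""


def brute_force_oracle(
    problem: FluxProblem,
    max_reactions: int = 12,
    max_free_exchanges: int = 4,
) -> FluxState:
    """Exhaustively enumerate polytope vertices of a small FBAwMC instance.

    Refuses problems with more than ``max_reactions`` reactions or more than
    ``max_free_exchanges`` substrate exchanges with nonzero capacity, since
    vertex enumeration is combinatorial.  All bounds must be finite (cap
    unbounded reactions before calling).
    """
    net = problem.network
    n = len(net.reactions)
    if n > max_reactions:
        raise OracleSizeError(f"{n} reactions > limit {max_reactions}")
    free_ex = sum(1 for u in problem.uptake_capacity.values() if u > 0)
    if free_ex > max_free_exchanges:
        raise OracleSizeError(
            f"{free_ex} free exchange dimensions > limit {max_free_exchanges}"
        )

    S = net.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in net.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in net.reactions], dtype=float)
    for s, u in problem.uptake_capacity.items():
        j = net.reaction_ids.index(net.substrate_exchange_ids[s])
        ub[j] = u
    ub = np.maximum(ub, lb)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise OracleSizeError("oracle requires finite bounds on every reaction")

    a = _crowding_vector(problem)
    budget = problem.budget

    # inequality rows: v_j >= lb_j, v_j <= ub_j, a.v <= budget (if finite)
    rows, rhs = [], []
    eye = np.eye(n)
    for j in range(n):
        rows.append(-eye[j]); rhs.append(-lb[j])
        rows.append(eye[j]); rhs.append(ub[j])
    if math.isfinite(budget):
        rows.append(a.copy()); rhs.append(budget)
    G = np.array(rows)
    h = np.array(rhs)

    rank_S = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank_S  # inequalities to activate at a vertex
    obj_id = problem.objective_id or net.biomass_id
    j_obj = net.reaction_ids.index(obj_id)

    best_val = -math.inf
    best_x = None
    feasible_found = False
    for active in combinations(range(len(G)), k):
        A = np.vstack([S, G[list(active)]]) if S.size else G[list(active)]
        b = np.concatenate([np.zeros(S.shape[0]), h[list(active)]])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.linalg.norm(A @ x - b) > _FEAS_TOL:
            continue
        if np.any(G @ x - h > _FEAS_TOL):
            continue
        feasible_found = True
        if x[j_obj] > best_val:
            best_val = x[j_obj]
            best_x = x

    if not feasible_found:
        return FluxState({}, math.nan, math.nan, "infeasible")
    assert best_x is not None
    fluxes = {rid: float(v) for rid, v in zip(net.reaction_ids, best_x)}
    j_bio = net.reaction_ids.index(net.biomass_id)
    return FluxState(
        fluxes=fluxes,
        growth_rate=float(best_x[j_bio]),
        crowding_lhs=float(a @ best_x),
        status="optimal",
        objective_value=float(best_val),
    )


def random_small_problem(seed: int, n_reactions: int = 6, n_metabolites: int = 3) -> FluxProblem:
    """A seeded random small FBAwMC instance for cross-checking solvers.

    Builds an irreversible network whose last reaction drains a designated
    biomass precursor; stoichiometric coefficients, bounds, crowding
    coefficients and the budget are all drawn from the seeded stream.  Every
    instance is feasible (v = 0) and bounded (finite upper bounds).
    """
    import numpy as np

    from .network import Metabolite, MetabolicNetwork, Reaction

    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"m{i}") for i in range(n_metabolites)]
    rxns = []
    for j in range(n_reactions - 1):
        stoich = {}
        for i in range(n_metabolites):
            c = rng.integers(-2, 3)
            if c != 0:
                stoich[f"m{i}"] = float(c)
        if not stoich:
            stoich[f"m{rng.integers(0, n_metabolites)}"] = 1.0
        rxns.append(
            Reaction(
                id=f"r{j}",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=float(rng.uniform(1.0, 10.0)),
                crowding_coefficient=float(rng.uniform(0.0, 0.3)),
            )
        )
    # biomass drains one metabolite so nonzero optima require production routes
    target = f"m{rng.integers(0, n_metabolites)}"
    rxns.append(
        Reaction(
            id="biomass",
            stoichiometry={target: -1.0},
            lower_bound=0.0,
            upper_bound=float(rng.uniform(5.0, 20.0)),
            crowding_coefficient=float(rng.uniform(0.0, 0.2)),
            kind="biomass",
        )
    )
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, biomass_id="biomass",
                           crowding_budget=float(rng.uniform(0.5, 2.0)))
    return FluxProblem(network=net)
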