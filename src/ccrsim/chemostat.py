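"""Steady-state FBAwMC across chemostat dilution rates.

At steady state the specific growth rate equals the dilution rate, μ = D.
The substrate-limited closure used here scales all maximum uptake capacities
by a common factor λ and bisects on λ until the crowding-constrained biomass
optimum satisfies μ(λ·U) = D.  Below the crowding onset the optimum
co-consumes every substrate in proportion to its capacity; once the crowding
constraint saturates, the LP reallocates enzyme space toward the most
crowding-efficient substrate (glucose) and toward low-cost fermentation,
which is exactly the carbon-catabolite-repression / acetate-overflow pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .fba import FluxProblem, FluxState, solve_fbawmc
from .network import MetabolicNetwork, split_reversible

__all__ = [
    "ChemostatPoint",
    "WashoutError",
    "simulate_chemostat_point",
    "consumption_ratio",
    "dilution_scan",
    "scan_frame",
    "ccr_onset",
]

#: bisection tolerance on |μ − D|
MU_TOL = 1e-8


class WashoutError(RuntimeError):
    """Requested dilution rate exceeds the maximal achievable growth rate."""

    def __init__(self, dilution_rate: float, mu_max: float):
        super().__init__(
            f"washout: D = {dilution_rate:g}/hr exceeds μ_max ≈ {mu_max:.6g}/hr"
        )
        self.dilution_rate = dilution_rate
        self.mu_max = mu_max


@dataclass(frozen=True)
class ChemostatPoint:
    """One steady state: uptake fluxes, carbon-weighted consumption ratios,
    acetate secretion and crowding saturation at dilution rate D."""

    dilution_rate: float
    uptake_fluxes: dict[str, float]
    consumption_ratios: dict[str, float]
    acetate_secretion: float
    crowding_lhs: float
    capacity_scale: float
    growth_rate: float
    washout: bool = False

    @property
    def total_carbon_uptake(self) -> float:
        return sum(self.uptake_fluxes.values())


def consumption_ratio(
    uptake_fluxes: dict[str, float], carbon_atoms: dict[str, int]
) -> dict[str, float]:
    """Carbon-weighted uptake fractions: rⱼ = vⱼ·cⱼ / Σₖ vₖ·cₖ.

    ``carbon_atoms`` gives atoms per molecule of each substrate.  All-zero
    uptake returns all-zero ratios rather than dividing by zero.
    """
    for s, v in uptake_fluxes.items():
        if v < -1e-9:
            raise ValueError(f"negative uptake flux for {s}")
    weighted = {s: max(v, 0.0) * carbon_atoms[s] for s, v in uptake_fluxes.items()}
    total = sum(weighted.values())
    if total <= 0:
        return {s: 0.0 for s in uptake_fluxes}
    return {s: w / total + 0.0 for s, w in weighted.items()}  # +0.0 kills -0.0


def _mu_at_scale(
    split: MetabolicNetwork, base: dict[str, float], lam: float, budget: float | None
) -> FluxState:
    caps = {s: lam * u for s, u in base.items()}
    return solve_fbawmc(
        FluxProblem(network=split, uptake_capacity=caps, crowding_budget=budget)
    )


def simulate_chemostat_point(
    net: MetabolicNetwork,
    dilution_rate: float,
    base_capacities: dict[str, float] | None = None,
    crowding_budget: float | None = None,
    lam_max: float = 1e6,
) -> ChemostatPoint:
    """Find the steady state at one dilution rate by bisecting the capacity scale.

    ``base_capacities`` fixes the relative substrate availability (defaults
    to the network's exchange upper bounds — the mixed-feed composition);
    the common scale λ is bisected until μ = D within ``MU_TOL``.  No acetate
    is present in the feed, so acetate reuptake is disabled at steady state.
    Raises :class:`WashoutError` when D exceeds the crowding-limited μ_max.
    """
    if dilution_rate < 0:
        raise ValueError("dilution rate must be >= 0")
    split = split_reversible(net)
    # no acetate in the chemostat feed: forbid reuptake
    from dataclasses import replace as _replace

    if net.acetate_exchange_id is not None:
        ac_rev = net.acetate_exchange_id + "__rev"
        split = MetabolicNetwork(
            metabolites=list(split.metabolites),
            reactions=[
                _replace(r, upper_bound=0.0) if r.id == ac_rev else r
                for r in split.reactions
            ],
            biomass_id=split.biomass_id,
            substrate_exchange_ids=dict(split.substrate_exchange_ids),
            acetate_exchange_id=split.acetate_exchange_id,
            crowding_budget=split.crowding_budget,
            name=split.name,
        )
    base = dict(
        base_capacities
        or {
            s: net.reaction(ex).upper_bound
            for s, ex in net.substrate_exchange_ids.items()
        }
    )
    carbons = net.substrate_carbon_atoms()
    names = list(net.substrate_exchange_ids)

    if dilution_rate == 0:
        return ChemostatPoint(
            dilution_rate=0.0,
            uptake_fluxes={s: 0.0 for s in names},
            consumption_ratios={s: 0.0 for s in names},
            acetate_secretion=0.0,
            crowding_lhs=0.0,
            capacity_scale=0.0,
            growth_rate=0.0,
        )

    sol_hi = _mu_at_scale(split, base, lam_max, crowding_budget)
    mu_max = sol_hi.growth_rate if sol_hi.status == "optimal" else math.inf
    if sol_hi.status == "unbounded" or mu_max >= dilution_rate + MU_TOL:
        pass
    else:
        raise WashoutError(dilution_rate, mu_max)

    lo, hi = 0.0, 1.0
    while True:
        sol = _mu_at_scale(split, base, hi, crowding_budget)
        if sol.status == "optimal" and sol.growth_rate >= dilution_rate:
            break
        lo, hi = hi, hi * 2.0
        if hi > lam_max:
            raise WashoutError(dilution_rate, mu_max)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        sol = _mu_at_scale(split, base, mid, crowding_budget)
        mu = sol.growth_rate if sol.status == "optimal" else 0.0
        if abs(mu - dilution_rate) <= MU_TOL:
            lo = hi = mid
            break
        if mu < dilution_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-14 * max(hi, 1.0):
            break
    lam = 0.5 * (lo + hi)
    sol = _mu_at_scale(split, base, lam, crowding_budget)

    uptakes = {s: sol.flux(net.substrate_exchange_ids[s]) for s in names}
    return ChemostatPoint(
        dilution_rate=dilution_rate,
        uptake_fluxes=uptakes,
        consumption_ratios=consumption_ratio(uptakes, carbons),
        acetate_secretion=(
            max(sol.net_flux(net.acetate_exchange_id), 0.0)
            if net.acetate_exchange_id is not None
            else 0.0
        ),
        crowding_lhs=sol.crowding_lhs,
        capacity_scale=lam,
        growth_rate=sol.growth_rate,
    )


def dilution_scan(
    net: MetabolicNetwork,
    dilution_rates,
    base_capacities: dict[str, float] | None = None,
    crowding_budget: float | None = None,
) -> list[ChemostatPoint]:
    """One steady state per dilution rate; washout becomes a flagged point."""
    points = []
    names = list(net.substrate_exchange_ids)
    for d in dilution_rates:
        try:
            points.append(
                simulate_chemostat_point(net, d, base_capacities, crowding_budget)
            )
        except WashoutError:
            points.append(
                ChemostatPoint(
                    dilution_rate=d,
                    uptake_fluxes={s: math.nan for s in names},
                    consumption_ratios={s: math.nan for s in names},
                    acetate_secretion=math.nan,
                    crowding_lhs=math.nan,
                    capacity_scale=math.nan,
                    growth_rate=math.nan,
                    washout=True,
                )
            )
    return points


def scan_frame(points: list[ChemostatPoint]) -> pd.DataFrame:
    """Tidy table (dilution_rate, substrate, uptake, ratio, acetate, crowding_lhs, washout)."""
    rows = []
    for p in points:
        for s in p.uptake_fluxes:
            rows.append(
                {
                    "dilution_rate": p.dilution_rate,
                    "substrate": s,
                    "uptake": p.uptake_fluxes[s],
                    "consumption_ratio": p.consumption_ratios[s],
                    "acetate_secretion": p.acetate_secretion,
                    "crowding_lhs": p.crowding_lhs,
                    "washout": p.washout,
                }
            )
    return pd.DataFrame(rows)


def ccr_onset(
    points: list[ChemostatPoint], budget: float = 1.0, tol: float = 1e-6
) -> float | None:
    """First dilution rate at which the crowding constraint saturates.

    Returns the smallest scanned D with crowding_lhs ≥ budget − tol, or
    ``None`` if the constraint never binds in the scan.
    """
    for p in sorted(points, key=lambda q: q.dilution_rate):
        if not p.washout and p.crowding_lhs >= budget - tol:
            return p.dilution_rate
    return None
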