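"""FBAwMC solver: toy optima, invariants, and brute-force oracle equivalence."""

import math

import numpy as np
import pytest

from ccrsim import (
    FluxProblem,
    brute_force_oracle,
    crowding_lhs,
    solve_fbawmc,
    split_reversible,
)
from ccrsim.network import Metabolite, MetabolicNetwork, Reaction
from ccrsim.oracle import OracleSizeError, random_small_problem


def test_two_substrate_toy_matches_vertex_enumeration(two_substrate_toy):
    """Crowding budget 1 splits between the cheap (a=0.1) and dear (a=0.2) routes:
    v = (5, 2.5), mu = 7.5, constraint saturated."""
    prob = FluxProblem(network=two_substrate_toy,
                       uptake_capacity={"s1": 5.0, "s2": 5.0})
    lp = solve_fbawmc(prob)
    bf = brute_force_oracle(prob)
    assert lp.status == bf.status == "optimal"
    assert lp.growth_rate == pytest.approx(7.5, abs=1e-6)
    assert bf.growth_rate == pytest.approx(7.5, abs=1e-9)
    assert lp.flux("r1") == pytest.approx(5.0, abs=1e-6)
    assert lp.flux("r2") == pytest.approx(2.5, abs=1e-6)
    assert lp.crowding_lhs == pytest.approx(1.0, abs=1e-6)


def test_starvation_gives_zero_growth_and_zero_flux(two_substrate_toy):
    sol = solve_fbawmc(
        FluxProblem(network=two_substrate_toy, uptake_capacity={"s1": 0.0, "s2": 0.0})
    )
    assert sol.status == "optimal"
    assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)
    assert all(abs(v) <= 1e-9 for v in sol.fluxes.values())


def test_single_chain_closed_form_without_crowding():
    """One glucose→biomass chain with yield y and U=8: mu = 8y when budget = ∞."""
    y = 0.3
    mets = [Metabolite("glc_e", is_external=True), Metabolite("glc"), Metabolite("b")]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1, "glc": 1}, 0, 100, 0, "exchange"),
        Reaction("cat", {"glc": -1, "b": y}, 0, 1000, 0.05),
        Reaction("biomass", {"b": -1}, 0, 1000, kind="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns, "biomass", {"glucose": "EX_glc"})
    sol = solve_fbawmc(
        FluxProblem(network=net, uptake_capacity={"glucose": 8.0},
                    crowding_budget=math.inf)
    )
    assert sol.growth_rate == pytest.approx(8 * y, abs=1e-8)


def test_infeasible_bounds_reported_not_raised():
    mets = [Metabolite("m")]
    rxns = [
        Reaction("make", {"m": 1.0}, 2.0, 5.0),  # forced production
        Reaction("biomass", {"m": -1.0}, 0.0, 1.0, kind="biomass"),  # cap 1 < 2
    ]
    net = MetabolicNetwork(mets, rxns, "biomass")
    sol = solve_fbawmc(FluxProblem(network=net))
    assert sol.status == "infeasible"


def test_unbounded_objective_reported():
    mets = [Metabolite("m")]
    rxns = [
        Reaction("make", {"m": 1.0}, 0.0, math.inf),
        Reaction("biomass", {"m": -1.0}, 0.0, math.inf, kind="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns, "biomass")
    sol = solve_fbawmc(FluxProblem(network=net, crowding_budget=math.inf))
    assert sol.status == "unbounded"


def test_solution_satisfies_mass_balance_and_crowding(split_net, fixture_caps):
    sol = solve_fbawmc(FluxProblem(network=split_net, uptake_capacity=fixture_caps))
    assert sol.status == "optimal"
    S = split_net.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in split_net.reaction_ids])
    assert np.max(np.abs(S @ v)) <= 1e-8
    assert np.min(v) >= -1e-9
    assert sol.crowding_lhs <= split_net.crowding_budget + 1e-8


def test_rejects_unsplit_network():
    mets = [Metabolite("m")]
    rxns = [
        Reaction("rev", {"m": 1.0}, -5, 5),
        Reaction("biomass", {"m": -1.0}, 0, 5, kind="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns, "biomass")
    with pytest.raises(ValueError, match="split"):
        FluxProblem(network=net)


# ---------------------------------------------------------------------------
# crowding_lhs


def test_crowding_lhs_arithmetic():
    assert crowding_lhs({}, {}) == 0.0
    assert crowding_lhs({"r": 5.0}, {"r": 0.2}) == pytest.approx(1.0)
    assert crowding_lhs({"r": 0.0, "q": 0.0}, {"r": 1.0, "q": 2.0}) == 0.0


def test_crowding_lhs_excludes_exchanges_unless_asked():
    fluxes = {"EX_a": 3.0, "r": 2.0}
    coeffs = {"EX_a": 0.5, "r": 0.1}
    assert crowding_lhs(fluxes, coeffs, exchange_ids={"EX_a"}) == pytest.approx(0.2)
    assert crowding_lhs(
        fluxes, coeffs, include_exchanges=True, exchange_ids={"EX_a"}
    ) == pytest.approx(1.7)


def test_crowding_lhs_rejects_mismatched_ids():
    with pytest.raises(ValueError, match="coefficient"):
        crowding_lhs({"r": 1.0}, {"q": 0.1})


def test_reported_lhs_equals_budget_at_toy_optimum(two_substrate_toy):
    sol = solve_fbawmc(
        FluxProblem(network=two_substrate_toy, uptake_capacity={"s1": 5, "s2": 5})
    )
    coeffs = {r.id: r.crowding_coefficient for r in two_substrate_toy.reactions}
    ex = {r.id for r in two_substrate_toy.reactions if r.kind == "exchange"}
    assert crowding_lhs(sol.fluxes, coeffs, exchange_ids=ex) == pytest.approx(
        sol.crowding_lhs, abs=1e-9
    )
    assert sol.crowding_lhs == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity


@pytest.mark.parametrize("seed", range(100))
def test_lp_matches_brute_force_on_random_small_networks(seed):
    prob = random_small_problem(seed)
    lp = solve_fbawmc(prob)
    bf = brute_force_oracle(prob)
    assert lp.status == bf.status == "optimal"
    assert abs(lp.growth_rate - bf.growth_rate) <= 1e-6


@pytest.mark.parametrize("seed", range(0, 100, 10))
def test_infinite_budget_reduces_to_plain_fba(seed):
    prob = random_small_problem(seed)
    relaxed = FluxProblem(network=prob.network, uptake_capacity=prob.uptake_capacity,
                          crowding_budget=math.inf)
    lp = solve_fbawmc(relaxed)
    bf = brute_force_oracle(relaxed)
    assert abs(lp.growth_rate - bf.growth_rate) <= 1e-6
    # relaxing the budget can only help
    assert lp.growth_rate >= solve_fbawmc(prob).growth_rate - 1e-9


def test_oracle_refuses_oversized_instances(split_net, fixture_caps):
    with pytest.raises(OracleSizeError):
        brute_force_oracle(
            FluxProblem(network=split_net, uptake_capacity=fixture_caps)
        )


def test_growth_is_monotone_in_budget_and_capacity(split_net, fixture_caps):
    """mu*(budget) and mu*(U) are non-decreasing on the fixture."""
    prev = -1.0
    for budget in (0.25, 0.5, 1.0, 2.0, math.inf):
        mu = solve_fbawmc(
            FluxProblem(network=split_net, uptake_capacity=fixture_caps,
                        crowding_budget=budget)
        ).growth_rate
        assert mu >= prev - 1e-9
        prev = mu
    prev = -1.0
    for scale in (0.0, 0.25, 0.5, 1.0, 2.0):
        caps = {s: scale * u for s, u in fixture_caps.items()}
        mu = solve_fbawmc(
            FluxProblem(network=split_net, uptake_capacity=caps)
        ).growth_rate
        assert mu >= prev - 1e-9
        prev = mu


def test_finite_budget_at_high_capacity_secretes_acetate(
    fixture_net, split_net, fixture_caps
):
    """The core overflow mechanism: crowding forces fermentation at high capacity,
    while the uncrowded optimum respires only."""
    crowded = solve_fbawmc(
        FluxProblem(network=split_net, uptake_capacity=fixture_caps)
    )
    uncrowded = solve_fbawmc(
        FluxProblem(network=split_net, uptake_capacity=fixture_caps,
                    crowding_budget=math.inf)
    )
    assert crowded.net_flux(fixture_net.acetate_exchange_id) > 1e-6
    assert uncrowded.net_flux(fixture_net.acetate_exchange_id) <= 1e-9
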