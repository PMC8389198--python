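"""LP core: FBA correctness against the vertex oracle and an independent
solver, duality, two-step parsimony, FVA and scenario application."""

import numpy as np
import pytest

from redgem import (
    InfeasibleModelError,
    Scenario,
    SamplerConfig,
    apply_scenario,
    chrr_sample,
    fba,
    fva,
    generate_toy_network,
    two_step_fba,
)
from redgem.datasets import fedbatch_comparison_table
from redgem.optimize import verify_solution
from redgem.synthetic import (
    ToyNetworkConfig,
    brute_force_fba_oracle,
    random_bounded_variant,
)


# ---- plain FBA -----------------------------------------------------------


def test_uptake_limited_chain_reaches_the_bound(chain_model):
    sol = fba(chain_model)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0)
    assert sol.fluxes["EX_A"] == pytest.approx(-10.0)


def test_internal_capacity_caps_the_chain(chain_model):
    m = chain_model.copy()
    m.reaction("AB").upper_bound = 4.0
    assert fba(m).objective_value == pytest.approx(4.0)


def test_infeasible_bounds_reported_without_fluxes(chain_model):
    m = chain_model.copy()
    m.reaction("EX_B").lower_bound = 20.0  # demands more than uptake allows
    sol = fba(m)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_toy_optimum_matches_vertex_enumeration(toy_model, toy_truth):
    oracle = brute_force_fba_oracle(toy_model)
    sol = fba(toy_model)
    assert oracle["status"] == "optimal"
    assert sol.objective_value == pytest.approx(
        oracle["objective_value"], abs=1e-6
    )
    assert sol.objective_value == pytest.approx(toy_truth.analytic_optimum)


def test_optimality_certificates_hold(toy_model):
    sol = fba(toy_model)
    checks = verify_solution(toy_model, sol)
    assert checks["max_balance_violation"] <= 1e-6
    assert checks["max_bound_violation"] <= 1e-6
    assert checks["duality_gap"] <= 1e-6


def test_agrees_with_independent_cobra_solver(toy_model, tmp_path):
    """Cross-check the in-house LP against cobrapy/GLPK on the same SBML."""
    cobra = pytest.importorskip("cobra")
    from redgem import save_model

    path = tmp_path / "toy.xml"
    save_model(toy_model, path)
    cm = cobra.io.read_sbml_model(str(path))
    ref = cm.optimize()
    assert ref.status == "optimal"
    assert fba(toy_model).objective_value == pytest.approx(
        ref.objective_value, abs=1e-6
    )


def test_oracle_agreement_on_seeded_variants(toy_model):
    rng = np.random.default_rng(20240317)
    for _ in range(12):
        variant = random_bounded_variant(toy_model, rng)
        oracle = brute_force_fba_oracle(variant)
        sol = fba(variant)
        if oracle["status"] == "optimal":
            assert sol.optimal
            assert sol.objective_value == pytest.approx(
                oracle["objective_value"], abs=1e-6
            )
            assert sol.duality_gap <= 1e-6
        else:
            assert sol.status == "infeasible"


# ---- shadow prices -------------------------------------------------------


def _finite_difference_price(model, met, eps=1e-4):
    base = fba(model).objective_value
    shifted = fba(model, balance_shift={met: -eps}).objective_value
    return -(shifted - base) / eps


def test_shadow_prices_match_finite_difference_sensitivity(
    pinned_growth_model,
):
    sol = fba(pinned_growth_model)
    for met in ("glyc_e", "succ_c", "ca_c", "arg_c"):
        fd = _finite_difference_price(pinned_growth_model, met)
        sp = sol.shadow_prices[met]
        assert sp == pytest.approx(fd, abs=1e-6), met
        if abs(fd) > 1e-6:
            assert np.sign(sp) == np.sign(fd)


def test_limiting_substrate_has_negative_price(toy_model):
    # uptake bound is the only bottleneck: the substrate limits CA output
    m = toy_model.copy()
    growth = m.reaction("BIOMASS")
    growth.lower_bound = growth.upper_bound = 2.5
    sol = fba(m)
    assert sol.shadow_prices["glyc_e"] == pytest.approx(-1.0 / 3.0, abs=1e-9)


# ---- two-step FBA --------------------------------------------------------


def test_two_step_on_unique_solution_equals_plain_fba(chain_model):
    one = fba(chain_model)
    two = two_step_fba(chain_model)
    assert two.objective_value == pytest.approx(one.objective_value, abs=1e-9)
    for rid, v in one.fluxes.items():
        assert two.fluxes[rid] == pytest.approx(v, abs=1e-6)


def test_parsimonious_step_picks_the_shorter_route():
    model, truth = generate_toy_network(ToyNetworkConfig(n_parallel_routes=1))
    sol = two_step_fba(model)
    assert sol.objective_value == pytest.approx(truth.analytic_optimum,
                                                abs=1e-9)
    # the 2-reaction detour is idle; all flux goes through the direct step
    assert sol.fluxes["ALT_0a"] == pytest.approx(0.0, abs=1e-6)
    assert sol.fluxes["PYK"] > 1.0
    # shifting any flux onto the detour strictly increases the L1 norm
    detour = {r: v for r, v in sol.fluxes.items()}
    shift = 1.0
    detour["PYK"] -= shift
    detour["ALT_0a"] += shift
    detour["ALT_0b"] += shift
    assert sol.sum_abs_flux < sum(abs(v) for v in detour.values()) - 1e-6


def test_step2_norm_never_exceeds_step1_norm(toy_model):
    step1 = fba(toy_model)
    both = two_step_fba(toy_model)
    assert both.sum_abs_flux <= sum(abs(v) for v in step1.fluxes.values()) + 1e-6
    assert both.objective_value == pytest.approx(step1.objective_value,
                                                 abs=1e-9)


# ---- FVA -----------------------------------------------------------------


def test_unique_chain_gives_degenerate_ranges(chain_model):
    for fr in fva(chain_model, fraction_of_optimum=1.0):
        assert fr.minimum == pytest.approx(fr.maximum, abs=1e-6)


def test_parallel_routes_share_the_total_at_full_optimum():
    model, _ = generate_toy_network(ToyNetworkConfig(n_parallel_routes=1))
    ranges = {fr.reaction_id: fr for fr in fva(model, 1.0)}
    total = ranges["PYK"].maximum
    assert ranges["ALT_0a"].minimum == pytest.approx(0.0, abs=1e-6)
    assert ranges["ALT_0a"].maximum == pytest.approx(total, abs=1e-6)
    assert ranges["PYK"].minimum == pytest.approx(0.0, abs=1e-6)


def test_blocked_reaction_has_zero_range():
    model, truth = generate_toy_network(
        ToyNetworkConfig(include_unreachable_branch=True)
    )
    ranges = {fr.reaction_id: fr for fr in fva(model, fraction_of_optimum=None)}
    for rid in truth.unreachable_reactions:
        assert ranges[rid].minimum == pytest.approx(0.0, abs=1e-9)
        assert ranges[rid].maximum == pytest.approx(0.0, abs=1e-9)


def test_sampled_optimal_solutions_lie_inside_fva_envelope(toy_model):
    """Near-uniform samples of the optimum-constrained polytope respect the
    FVA ranges computed at the same optimality fraction."""
    constrained = toy_model.copy()
    z = fba(toy_model).objective_value
    constrained.reaction("EX_ca").lower_bound = z  # pin the optimum
    ranges = {fr.reaction_id: fr for fr in fva(toy_model, 1.0)}
    sample = chrr_sample(
        constrained, SamplerConfig(n_points=100, steps_per_point=20, seed=4)
    )
    for j, rid in enumerate(sample.reaction_ids):
        col = sample.matrix[:, j]
        assert col.min() >= ranges[rid].minimum - 1e-6
        assert col.max() <= ranges[rid].maximum + 1e-6


# ---- scenarios -----------------------------------------------------------


def test_scenario_sets_growth_hard_and_exchange_soft(toy_model):
    scenario = Scenario(
        name="batch",
        growth_rate=0.042,
        growth_reaction_id="BIOMASS",
        lower_bounded={"EX_glyc": -0.182},
        upper_bounded={"EX_ca": 0.002},
    )
    constrained = apply_scenario(toy_model, scenario)
    growth = constrained.reaction("BIOMASS")
    assert (growth.lower_bound, growth.upper_bound) == (0.042, 0.042)
    glyc = constrained.reaction("EX_glyc")
    assert glyc.lower_bound == -0.182
    assert glyc.upper_bound == 0.0  # untouched
    assert constrained.reaction("EX_ca").upper_bound == 0.002
    # original untouched
    assert toy_model.reaction("BIOMASS").upper_bound == 1000


def test_published_fedbatch_roles_round_trip_onto_the_toy_analogues(toy_model):
    """The printed fed-batch constraint set maps onto the toy analogues:
    glycerol uptake as a lower bound, growth hard."""
    table = fedbatch_comparison_table()
    batch = table[table.condition == "batch"].set_index("quantity")
    scenario = Scenario(
        name="batch-36h",
        growth_rate=float(batch.loc["growth", "exp"]),
        growth_reaction_id="BIOMASS",
        lower_bounded={"EX_glyc": float(batch.loc["glycerol", "exp"])},
        upper_bounded={
            "EX_ca": float(batch.loc["clavulanate", "exp"]),
            "EX_succ": float(batch.loc["succinate", "exp"]),
        },
    )
    constrained = apply_scenario(toy_model, scenario)
    assert constrained.reaction("EX_glyc").lower_bound == pytest.approx(-0.182)
    growth = constrained.reaction("BIOMASS")
    assert growth.lower_bound == growth.upper_bound == pytest.approx(0.042)


def test_empty_scenario_changes_nothing(toy_model):
    constrained = apply_scenario(toy_model, Scenario(name="noop"))
    assert [
        (r.lower_bound, r.upper_bound) for r in constrained.reactions
    ] == [(r.lower_bound, r.upper_bound) for r in toy_model.reactions]


def test_contradictory_scenario_bounds_name_the_reaction(toy_model):
    scenario = Scenario(
        name="bad", upper_bounded={"EX_glyc": 0.0},
        lower_bounded={"EX_ca": -1.0},
    )
    # EX_ca has lb 0 in the model; a lower bound of -1 is fine, but an
    # upper bound below an already-positive lower bound must fail
    m = toy_model.copy()
    m.reaction("EX_succ").lower_bound = 0.5
    with pytest.raises(ValueError, match="EX_succ"):
        apply_scenario(m, Scenario(name="bad2",
                                   upper_bounded={"EX_succ": 0.1}))


def test_uptake_sign_convention_enforced():
    with pytest.raises(ValueError, match="<= 0"):
        Scenario(name="s", lower_bounded={"EX_glyc": 0.5}).validate()
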