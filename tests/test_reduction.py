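"""Reduction workflow: dead ends, blocked reactions, pruning, lumping,
biomass producibility, gap filling and loop handling."""

import pytest

from redgem import (
    DirectionalityEvidence,
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyNetworkConfig,
    add_lumped_reaction,
    check_biomass_precursors,
    correct_tics,
    detect_tics,
    drop_unproducible_precursors,
    fba,
    find_blocked_reactions,
    find_dead_end_metabolites,
    gap_fill,
    generate_toy_network,
    prune,
)


# ---- dead ends -----------------------------------------------------------


def test_chain_without_outlet_has_dead_end():
    m = MetabolicModel(id="m")
    m.add_metabolite(Metabolite(id="A_c"))
    m.add_metabolite(Metabolite(id="B_c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_c": -1},
                            lower_bound=-10, upper_bound=0))
    m.add_reaction(Reaction(id="AB", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=1000))
    assert find_dead_end_metabolites(m) == {"B_c"}


def test_connected_toy_network_has_no_dead_ends(toy_model):
    assert find_dead_end_metabolites(toy_model) == set()


def test_injected_orphans_are_the_only_dead_ends():
    model, truth = generate_toy_network(ToyNetworkConfig(include_dead_ends=2))
    assert find_dead_end_metabolites(model) == truth.dead_end_metabolites


# ---- blocked reactions ---------------------------------------------------


def test_unreachable_branch_is_exactly_the_blocked_set():
    model, truth = generate_toy_network(
        ToyNetworkConfig(include_unreachable_branch=True)
    )
    assert find_blocked_reactions(model) == truth.unreachable_reactions


def test_carbon_source_exchange_is_not_blocked(toy_model):
    assert "EX_glyc" not in find_blocked_reactions(toy_model)


# ---- pruning -------------------------------------------------------------


def test_keeping_all_subsystems_is_identity(toy_model, toy_truth):
    reduced, log = prune(toy_model, toy_truth.core_subsystems)
    assert reduced.reaction_ids == toy_model.reaction_ids
    assert log.passes == []


def test_minor_subsystem_is_pruned_with_its_metabolites(toy_truth):
    model, truth = generate_toy_network(
        ToyNetworkConfig(include_minor_subsystem=True)
    )
    reduced, log = prune(model, toy_truth.core_subsystems)
    assert truth.minor_subsystem_reactions.isdisjoint(reduced.reaction_ids)
    for met in ("m1_c", "m2_c", "m3_c"):
        assert not reduced.has_metabolite(met)
    # everything else survives and the model still reaches its optimum
    assert fba(reduced).objective_value == pytest.approx(
        truth.analytic_optimum
    )


def test_pruning_is_a_fixed_point(toy_truth):
    model, _ = generate_toy_network(
        ToyNetworkConfig(include_minor_subsystem=True, include_dead_ends=1)
    )
    once, log1 = prune(model, toy_truth.core_subsystems)
    twice, log2 = prune(once, toy_truth.core_subsystems)
    assert once.reaction_ids == twice.reaction_ids
    assert log2.passes == []


def test_replaying_the_log_reproduces_the_reduced_model(toy_truth):
    model, _ = generate_toy_network(
        ToyNetworkConfig(include_minor_subsystem=True,
                         include_unreachable_branch=True)
    )
    reduced, log = prune(model, toy_truth.core_subsystems)
    replayed = log.replay(model)
    assert replayed.reaction_ids == reduced.reaction_ids
    assert replayed.metabolite_ids == reduced.metabolite_ids


def test_objective_survives_even_when_its_subsystem_is_dropped(toy_model):
    # the CA exchange lives in "exchange", which is not kept, yet the
    # objective reaction is implicitly protected from removal
    reduced, _ = prune(toy_model, {"biomass"})
    assert reduced.has_reaction(toy_model.objective_id)


# ---- lumped reactions ----------------------------------------------------


def test_lump_enables_flux_through_broken_branch(toy_model, toy_truth):
    crippled = toy_model.copy()
    crippled.remove_reactions(["LMPD_arg"])
    assert fba(crippled).objective_value == pytest.approx(0.0, abs=1e-9)
    add_lumped_reaction(crippled, "LMPD_arg2", {"akg_c": -1, "arg_c": 1})
    assert fba(crippled).objective_value == pytest.approx(
        toy_truth.analytic_optimum
    )
    assert crippled.reaction("LMPD_arg2").is_lumped


def test_null_lump_rejected(toy_model):
    with pytest.raises(ValueError, match="null"):
        add_lumped_reaction(toy_model.copy(), "LMPD_null", {"g3p_c": 0.0})


def test_lump_with_unknown_metabolite_autocreates_it(toy_model, caplog):
    m = toy_model.copy()
    add_lumped_reaction(m, "LMPD_new", {"g3p_c": -1, "novel_c": 1})
    assert m.has_metabolite("novel_c")


# ---- biomass precursors --------------------------------------------------


def test_all_precursors_of_intact_network_are_producible(toy_model):
    flags = check_biomass_precursors(toy_model, "BIOMASS")
    assert set(flags) == {"g3p_c", "oaa_c", "akg_c"}
    assert all(flags.values())
    # probe sinks must not persist
    assert not any(r.id.startswith("SINK_PROBE") for r in toy_model.reactions)


def test_cut_pathway_makes_precursor_unproducible_and_droppable(toy_model):
    m = toy_model.copy()
    m.remove_reactions(["ICDH"])  # only route to akg
    flags = check_biomass_precursors(m, "BIOMASS")
    assert flags["akg_c"] is False
    assert flags["g3p_c"] is True
    drop_unproducible_precursors(m, "BIOMASS", flags)
    stoich = m.reaction("BIOMASS").stoichiometry
    assert "akg_c" not in stoich
    assert stoich["g3p_c"] == -0.5  # untouched, no renormalisation


def test_dropping_every_precursor_is_an_error(toy_model):
    m = toy_model.copy()
    flags = {"g3p_c": False, "oaa_c": False, "akg_c": False}
    with pytest.raises(ValueError, match="all biomass precursors"):
        drop_unproducible_precursors(m, "BIOMASS", flags)


# ---- gap filling ---------------------------------------------------------


def test_gap_fill_noop_when_target_producible(toy_model):
    m = toy_model.copy()
    added = gap_fill(m, pool=[], targets=["ca_c"])
    assert added == []


def test_gap_fill_restores_single_missing_link(toy_model, toy_truth):
    m = toy_model.copy()
    m.remove_reactions(["ICDH"])
    pool = [
        Reaction(id="FILL_other", stoichiometry={"mal_c": -1, "succ_c": 1},
                 lower_bound=0, upper_bound=1000),
        Reaction(id="FILL_icdh", stoichiometry={"icit_c": -1, "akg_c": 1},
                 lower_bound=0, upper_bound=1000),
    ]
    added = gap_fill(m, pool, targets=["akg_c", "arg_c"])
    assert added == ["FILL_icdh"]
    assert fba(m).objective_value == pytest.approx(toy_truth.analytic_optimum)


def test_gap_fill_greedy_prefers_one_reaction_fixing_two_gaps(toy_model):
    m = toy_model.copy()
    m.remove_reactions(["ICDH"])  # breaks akg and (downstream) arg
    pool = [
        Reaction(id="FILL_arg_only", stoichiometry={"oaa_c": -1, "arg_c": 1},
                 lower_bound=0, upper_bound=1000),
        Reaction(id="FILL_both", stoichiometry={"icit_c": -1, "akg_c": 1},
                 lower_bound=0, upper_bound=1000),
    ]
    added = gap_fill(m, pool, targets=["akg_c", "arg_c"])
    # brute force over subsets of size <= 2 confirms one addition suffices
    assert added == ["FILL_both"]


def test_gap_fill_warns_on_unfillable_target(toy_model, caplog):
    m = toy_model.copy()
    added = gap_fill(m, pool=[], targets=["nonexistent_c"])
    assert added == []
    assert any("unproducible" in rec.message for rec in caplog.records)


# ---- TICs ----------------------------------------------------------------


def test_loop_free_network_has_empty_tic_report(toy_model):
    assert detect_tics(toy_model).loops == []


def test_injected_loop_detected_exactly():
    model, truth = generate_toy_network(ToyNetworkConfig(include_tic=True))
    report = detect_tics(model)
    assert report.loops == truth.tic_loops


def test_three_reaction_reversible_cycle_forms_one_loop():
    m = MetabolicModel(id="cycle")
    for mid in ("A_c", "B_c", "C_c"):
        m.add_metabolite(Metabolite(id=mid))
    m.add_reaction(Reaction(id="R_AB", stoichiometry={"A_c": -1, "B_c": 1}))
    m.add_reaction(Reaction(id="R_BC", stoichiometry={"B_c": -1, "C_c": 1}))
    m.add_reaction(Reaction(id="R_CA", stoichiometry={"C_c": -1, "A_c": 1}))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_c": -1},
                            lower_bound=-10, upper_bound=10,
                            is_exchange=True))
    report = detect_tics(m)
    assert report.loops == [{"R_AB", "R_BC", "R_CA"}]


def test_decisive_gibbs_evidence_dissolves_loop():
    model, truth = generate_toy_network(ToyNetworkConfig(include_tic=True))
    report = detect_tics(model)
    evidence = DirectionalityEvidence(dg={"TIC_A": -30.0})
    corrected_model, after = correct_tics(model, report, evidence)
    assert after.corrected == [("TIC_A", (-1000, 1000), (0.0, 1000))]
    assert after.loops == []
    # objective untouched by the directionality restriction
    assert fba(corrected_model).objective_value == pytest.approx(
        truth.analytic_optimum
    )


def test_loop_without_evidence_left_unresolved():
    model, _ = generate_toy_network(ToyNetworkConfig(include_tic=True))
    report = detect_tics(model)
    _, after = correct_tics(model, report, DirectionalityEvidence())
    assert after.corrected == []
    assert set(after.unresolved) == {"TIC_A", "TIC_B"}
    assert after.loops == report.loops


def test_gibbs_value_inside_dead_band_is_inconclusive():
    model, _ = generate_toy_network(ToyNetworkConfig(include_tic=True))
    report = detect_tics(model)
    _, after = correct_tics(model, report,
                            DirectionalityEvidence(dg={"TIC_A": 0.0}))
    assert after.corrected == []
    assert "TIC_A" in after.unresolved
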