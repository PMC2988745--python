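import numpy as np
import pytest

from gsmaudit import (
    Compartment,
    GeneratorSpec,
    Medium,
    Metabolite,
    Model,
    Reaction,
    blocked_reactions,
    build_flux_problem,
    flux_variability,
    generate_model,
    solve_fba,
)
from gsmaudit.medium import MediumError
from tests._oracles import cobra_blocked, cobra_fba, fba_by_vertex_enumeration
from tests.conftest import TINY_SPEC


def test_problem_dimensions_and_objective_column(toy1_problem):
    assert toy1_problem.S.shape == (6, 7)
    j = toy1_problem.column("GROWTH")
    col = toy1_problem.S.toarray()[:, j]
    assert list(np.nonzero(col)[0]) == [toy1_problem.row_ids.index("bp")]
    assert col[toy1_problem.row_ids.index("bp")] == -1.0


def test_medium_uptake_sets_exchange_lower_bound(toy1, toy1_med):
    problem = build_flux_problem(toy1, toy1_med, "GROWTH")
    assert problem.lb[problem.column("EX_glc")] == -10.0


def test_unknown_objective_rejected(toy1, toy1_med):
    with pytest.raises(KeyError, match="NOPE"):
        build_flux_problem(toy1, toy1_med, "NOPE")


def test_medium_species_without_exchange_named(toy1):
    with pytest.raises(MediumError, match="pyr"):
        build_flux_problem(toy1, Medium({"glc_ext": 10.0, "pyr": 1.0}), "GROWTH")


def test_toy1_fba_limited_by_uptake(toy1_problem):
    res = solve_fba(toy1_problem)
    assert res.status == "optimal"
    assert res.objective == pytest.approx(10.0, abs=1e-9)
    # steady state holds at the optimum
    assert np.abs(toy1_problem.S @ res.v).max() <= 1e-6


def test_zero_uptake_zero_growth(toy1):
    problem = build_flux_problem(toy1, Medium({"glc_ext": 0.0}), "GROWTH")
    assert solve_fba(problem).objective == pytest.approx(0.0, abs=1e-9)


def test_inverted_bounds_reported_infeasible(toy1_problem):
    toy1_problem.lb[0], toy1_problem.ub[0] = 1.0, -1.0
    assert solve_fba(toy1_problem).status == "infeasible"


def test_toy1_fva_structural_zeros(toy1_problem):
    fva = flux_variability(toy1_problem)
    assert fva.ranges["DEAD1"] == pytest.approx((0.0, 0.0), abs=1e-9)
    assert fva.ranges["ORPH"] == pytest.approx((0.0, 0.0), abs=1e-9)


def test_toy1_fva_at_full_optimum_pins_the_pathway(toy1_problem):
    fva = flux_variability(toy1_problem, fraction_of_optimum=1.0)
    assert fva.ranges["R1"] == pytest.approx((10.0, 10.0), abs=1e-7)
    lo, hi = fva.ranges["EX_glc"]
    assert (lo, hi) == pytest.approx((-10.0, -10.0), abs=1e-7)


def test_isolated_reversible_pair_is_blocked():
    m = Model(id="loop")
    m.compartments["c"] = Compartment("c", "extracellular")
    m.metabolites["A"] = Metabolite("A", "A", "c")
    m.metabolites["B"] = Metabolite("B", "B", "c")
    m.reactions["R"] = Reaction("R", stoich={"A": -1.0, "B": 1.0},
                                reversible=True, lb=-1000.0, ub=1000.0)
    problem = build_flux_problem(m, Medium({}), None)
    assert flux_variability(problem).ranges["R"] == pytest.approx((0.0, 0.0))
    assert blocked_reactions(problem) == {"R"}


def test_toy1_blocked_set(toy1_problem):
    assert blocked_reactions(toy1_problem) == {"DEAD1", "ORPH"}


def test_open_linear_chain_nothing_blocked(small_model):
    model, truth = small_model
    problem = build_flux_problem(model, truth.medium(), "BIOMASS")
    blocked = blocked_reactions(problem)
    backbone = {r for r in model.reactions if r.startswith(("R", "P", "EX", "TRANS", "BIOMASS"))}
    assert blocked & backbone == set()
    assert blocked == truth.blocked_reactions


def test_fva_sandwich(toy1_problem):
    res = solve_fba(toy1_problem)
    fva = flux_variability(toy1_problem, fraction_of_optimum=1.0)
    for rid, (lo, hi) in fva.ranges.items():
        j = toy1_problem.column(rid)
        assert lo - 1e-6 <= res.v[j] <= hi + 1e-6


@pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
def test_bound_scaling_invariance(toy1, toy1_med, lam):
    """Scaling all bounds by λ scales the optimum by λ, blocked set unchanged."""
    scaled = toy1.copy()
    for rxn in scaled.reactions.values():
        rxn.lb *= lam
        rxn.ub *= lam
    med = Medium({m: r * lam for m, r in toy1_med.uptake.items()})
    base = build_flux_problem(toy1, toy1_med, "GROWTH")
    scaled_p = build_flux_problem(scaled, med, "GROWTH")
    assert solve_fba(scaled_p).objective == pytest.approx(
        lam * solve_fba(base).objective, rel=1e-7)
    assert blocked_reactions(scaled_p) == blocked_reactions(base)


def test_knockout_monotonicity(toy1_problem):
    """Pinning any reaction to zero never increases the optimum."""
    base = solve_fba(toy1_problem).objective
    for rid in toy1_problem.col_ids:
        ko = toy1_problem.copy()
        j = ko.column(rid)
        ko.lb[j] = ko.ub[j] = 0.0
        res = solve_fba(ko)
        assert res.status != "optimal" or res.objective <= base + 1e-9


def test_fba_matches_vertex_enumeration_toy(toy1_problem):
    expected = fba_by_vertex_enumeration(
        toy1_problem.S.toarray(), toy1_problem.lb, toy1_problem.ub, toy1_problem.c)
    assert solve_fba(toy1_problem).objective == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("seed", range(10))
def test_fba_matches_vertex_enumeration_generated(seed):
    """On every <=8-reaction generated model the LP equals brute-force enumeration."""
    model, truth = generate_model(GeneratorSpec(seed=seed, **TINY_SPEC))
    assert len(model.reactions) <= 8
    problem = build_flux_problem(model, truth.medium(), "BIOMASS")
    expected = fba_by_vertex_enumeration(
        problem.S.toarray(), problem.lb, problem.ub, problem.c)
    assert solve_fba(problem).objective == pytest.approx(expected, abs=1e-6)


def test_fba_cross_checked_against_cobra(toy1, toy1_med, small_model):
    status, obj = cobra_fba(toy1, toy1_med, "GROWTH")
    ours = solve_fba(build_flux_problem(toy1, toy1_med, "GROWTH"))
    assert (status, obj) == ("optimal", pytest.approx(ours.objective, abs=1e-6))
    model, truth = small_model
    status, obj = cobra_fba(model, truth.medium(), "BIOMASS")
    ours = solve_fba(build_flux_problem(model, truth.medium(), "BIOMASS"))
    assert (status, obj) == ("optimal", pytest.approx(ours.objective, abs=1e-6))


def test_blocked_cross_checked_against_cobra(toy1, toy1_med, small_model):
    problem = build_flux_problem(toy1, toy1_med, objective=None)
    assert blocked_reactions(problem) == cobra_blocked(toy1, toy1_med)
    model, truth = small_model
    problem = build_flux_problem(model, truth.medium(), objective=None)
    assert blocked_reactions(problem) == cobra_blocked(model, truth.medium())
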