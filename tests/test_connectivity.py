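import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmaudit import (
    Compartment,
    GeneratorSpec,
    Medium,
    MediumError,
    Metabolite,
    Model,
    Reaction,
    blocked_reactions,
    build_flux_problem,
    build_graph,
    connectivity_report,
    dead_end_metabolites,
    generate_model,
    reachable_set,
    reconnection_impact,
    unreachable_clusters,
)
from tests.conftest import SMALL_SPEC

# frozen by hand-walking the 15-node TOY1 bipartite graph from glc_ext
TOY1_REACHABLE = {"glc_ext", "glc", "pyr", "bp", "waste_x"}


def _chain_model(reversible=False):
    """A -> B (single reaction), two internal metabolites."""
    m = Model(id="chain")
    m.compartments["c"] = Compartment("c", "cytosol")
    m.metabolites["A"] = Metabolite("A", "A", "c")
    m.metabolites["B"] = Metabolite("B", "B", "c")
    lb = -1000.0 if reversible else 0.0
    m.reactions["R"] = Reaction("R", stoich={"A": -1.0, "B": 1.0},
                                reversible=reversible, lb=lb, ub=1000.0)
    return m


def test_graph_arcs_irreversible():
    g = build_graph(_chain_model(reversible=False))
    assert set(g.edges) == {(("m", "A"), ("r", "R")), (("r", "R"), ("m", "B"))}


def test_graph_arcs_reversible():
    g = build_graph(_chain_model(reversible=True))
    assert g.number_of_edges() == 4


def test_graph_node_counts(toy1):
    g = build_graph(toy1)
    assert sum(1 for n in g if n[0] == "r") == 7
    assert sum(1 for n in g if n[0] == "m") == 6  # boundary species excluded


def test_toy1_reachability_matches_hand_bfs(toy1, toy1_med):
    assert reachable_set(toy1, toy1_med) == TOY1_REACHABLE


def test_empty_medium_reaches_nothing(toy1):
    assert reachable_set(toy1, Medium({})) == set()


def test_unknown_medium_species_named_in_error(toy1):
    with pytest.raises(MediumError, match="unobtainium"):
        reachable_set(toy1, Medium({"unobtainium": 1.0}))


def test_toy1_unreachable_cluster(toy1, toy1_med):
    assert unreachable_clusters(toy1, toy1_med) == [frozenset({"orphan_m"})]


def test_connected_chain_has_no_clusters():
    m = _chain_model()
    m.metabolites["A"].compartment = "c"
    med = Medium({"A": 5.0})
    # A is internal; make it medium-eligible by marking the compartment external
    m.compartments["c"] = Compartment("c", "extracellular")
    assert unreachable_clusters(m, med) == []


def test_toy1_dead_ends(toy1):
    assert dead_end_metabolites(toy1) == {"waste_x", "orphan_m"}


def test_reversible_pair_has_no_dead_ends():
    assert dead_end_metabolites(_chain_model(reversible=True)) == set()


def test_toy1_reconnection_impact(toy1, toy1_med):
    # granting orphan_m a source reaches 1 new metabolite and unblocks ORPH
    assert reconnection_impact(toy1, toy1_med) == [(frozenset({"orphan_m"}), 2)]


def test_no_clusters_no_ranking(small_model):
    model, truth = small_model
    fixed = model.copy()
    # give every orphan head a real producer: nothing is unreachable any more
    for k, cluster in enumerate(truth.orphan_clusters):
        head = min(cluster)
        fixed.reactions[f"FIX{k}"] = Reaction(
            f"FIX{k}", stoich={"m0001": -1.0, head: 1.0}
        )
    assert reconnection_impact(fixed, truth.medium()) == []


def test_bigger_cluster_ranks_first():
    """A cluster feeding 5 downstream reactions outranks one feeding 1."""
    spec = GeneratorSpec(n_backbone=6, n_isozyme_pairs=0, n_complexes=0,
                         n_parallel_routes=0, n_orphan_clusters=0,
                         orphan_cluster_size=0, n_deadend_branches=0,
                         n_unused_genes=0, seed=0)
    model, truth = generate_model(spec)
    # plant two chains by hand: 5-reaction chain vs a single connector
    for i in range(5):
        model.metabolites[f"big{i}"] = Metabolite(f"big{i}", f"big{i}", "c")
    for i in range(4):
        model.reactions[f"BIGR{i}"] = Reaction(
            f"BIGR{i}", stoich={f"big{i}": -1.0, f"big{i+1}": 1.0})
    model.reactions["BIGC"] = Reaction("BIGC", stoich={"big4": -1.0, "m0003": 1.0})
    model.metabolites["lone"] = Metabolite("lone", "lone", "c")
    model.reactions["LONEC"] = Reaction("LONEC", stoich={"lone": -1.0, "m0003": 1.0})
    ranked = reconnection_impact(model, truth.medium())
    assert [sorted(c) for c, _ in ranked][0] == [f"big{i}" for i in range(5)]
    assert ranked[0][1] > ranked[1][1]


def test_planted_clusters_recovered(small_model):
    model, truth = small_model
    found = unreachable_clusters(model, truth.medium())
    assert sorted(map(sorted, found)) == sorted(map(sorted, truth.orphan_clusters))


def test_planted_dead_ends_recovered(small_model):
    model, truth = small_model
    found = dead_end_metabolites(model)
    assert truth.deadend_metabolites <= found
    assert found == truth.expected_dead_ends()


def test_partition_property(small_model):
    model, truth = small_model
    rep = connectivity_report(model, truth.medium())
    unreachable = set().union(*rep.unreachable_clusters) if rep.unreachable_clusters else set()
    assert rep.reachable & unreachable == set()
    assert rep.reachable | unreachable == set(model.internal_metabolites())
    assert rep.fraction_reachable == pytest.approx(len(rep.reachable) / rep.n_internal)


def test_reachability_invariant_under_reaction_order(toy1, toy1_med):
    shuffled = toy1.copy()
    shuffled.reactions = dict(reversed(list(shuffled.reactions.items())))
    assert reachable_set(shuffled, toy1_med) == reachable_set(toy1, toy1_med)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(drop=st.sets(st.sampled_from(["glc_ext"]), max_size=1))
def test_medium_monotonicity_toy(drop):
    """Enlarging the medium never shrinks the reachable set."""
    from gsmaudit import toy1_medium, toy1_model

    model = toy1_model()
    full = toy1_medium()
    sub = Medium({k: v for k, v in full.uptake.items() if k not in drop})
    assert reachable_set(model, sub) <= reachable_set(model, full)


@pytest.mark.parametrize("seed", [0, 3, 9])
def test_medium_monotonicity_generated(seed):
    model, truth = generate_model(GeneratorSpec(seed=seed, **SMALL_SPEC))
    base = truth.medium()
    # enlarge: also feed a mid-backbone metabolite through its own exchange
    enlarged_model = model.copy()
    enlarged_model.metabolites["extra_b"] = Metabolite(
        "extra_b", "extra boundary", "e", is_boundary=True)
    enlarged_model.reactions["EX_extra"] = Reaction(
        "EX_extra", stoich={"m0004": -1.0, "extra_b": 1.0},
        reversible=True, lb=-5.0, ub=1000.0)
    enlarged = Medium(dict(base.uptake))
    enlarged.uptake["m0004"] = 5.0
    small = reachable_set(model, base)
    # the enlarged medium needs m0004 to qualify as seedable
    enlarged_model.metabolites["m0004"].compartment = "e"
    big = reachable_set(enlarged_model, enlarged)
    assert small <= big


def test_unreachable_implies_blocked_cross_module(small_model):
    """Mass balance forces zero flux through any unreachable metabolite."""
    model, truth = small_model
    clusters = unreachable_clusters(model, truth.medium())
    unreachable = set().union(*clusters)
    problem = build_flux_problem(model, truth.medium(), objective=None)
    blocked = blocked_reactions(problem)
    incident = {
        r.id for r in model.reactions.values() if set(r.stoich) & unreachable
    }
    assert incident <= blocked
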