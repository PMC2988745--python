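"""Graph-theoretic network audit.

Gap finding works on the bipartite metabolite-reaction digraph: a
metabolite is *unreachable* when no traversal from the growth-medium
constituents can produce it, and a *dead-end* metabolite is one that is
only ever produced or only ever consumed.  Unreachable metabolites are
grouped into clusters (weakly connected components of the subgraph they
induce), and clusters are ranked by how much of the network a curated
reconnection would recover — the quantity that tells a curator where
literature effort pays off most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .constraints import BLOCKED_TOL, blocked_reactions, build_flux_problem
from .core import DEFAULT_BOUND, Model, Reaction
from .medium import Medium, MediumError

__all__ = [
    "ConnectivityReport",
    "build_graph",
    "reachable_set",
    "unreachable_clusters",
    "dead_end_metabolites",
    "reconnection_impact",
    "connectivity_report",
]


@dataclass
class ConnectivityReport:
    """Partition of internal metabolites into reachable and unreachable."""

    reachable: set[str]
    unreachable_clusters: list[frozenset[str]]
    dead_ends: set[str]
    fraction_reachable: float
    n_internal: int = 0

    def n_unreachable(self) -> int:
        return sum(len(c) for c in self.unreachable_clusters)


def build_graph(model: Model) -> nx.DiGraph:
    """Bipartite digraph: substrate → reaction → product arcs.

    Nodes are ``("m", metabolite_id)`` and ``("r", reaction_id)``.
    Reversible reactions contribute the reverse arcs as well.  Boundary
    species are outside mass balance and are not added.
    """
    g = nx.DiGraph()
    internal = set(model.internal_metabolites())
    for mid in internal:
        g.add_node(("m", mid))
    for rxn in model.reactions.values():
        g.add_node(("r", rxn.id))
        for mid, coef in rxn.stoich.items():
            if mid not in internal:
                continue
            if coef < 0:
                g.add_edge(("m", mid), ("r", rxn.id))
                if rxn.reversible:
                    g.add_edge(("r", rxn.id), ("m", mid))
            else:
                g.add_edge(("r", rxn.id), ("m", mid))
                if rxn.reversible:
                    g.add_edge(("m", mid), ("r", rxn.id))
    return g


def _substrates(rxn: Reaction, forward: bool) -> list[str]:
    sign = -1 if forward else 1
    return [m for m, c in rxn.stoich.items() if sign * c > 0]


def _products(rxn: Reaction, forward: bool) -> list[str]:
    sign = 1 if forward else -1
    return [m for m, c in rxn.stoich.items() if sign * c > 0]


def reachable_set(
    model: Model, medium: Medium, semantics: str = "any"
) -> set[str]:
    """Metabolites producible from the medium, by graph traversal.

    ``semantics="any"`` fires a reaction once any substrate is reached
    (pure graph connectivity, the default); ``"all"`` requires every
    substrate (scope semantics).  Boundary species are treated as always
    available.  Returns all reached internal metabolites, medium seeds
    included.
    """
    if semantics not in ("any", "all"):
        raise ValueError(f"semantics must be 'any' or 'all', got {semantics!r}")
    medium.validate(model)
    if not medium.uptake:
        return set()
    return _reachable_unvalidated(model, set(medium.uptake), semantics)


def unreachable_clusters(
    model: Model, medium: Medium, semantics: str = "any"
) -> list[frozenset[str]]:
    """Group unreachable internal metabolites into weakly connected clusters.

    Two unreachable metabolites belong to the same cluster when a shared
    reaction links them (direction ignored — a cluster is a visual blob,
    not a pathway).  Sorted by size descending, then lexicographically.
    """
    internal = set(model.internal_metabolites())
    unreachable = internal - reachable_set(model, medium, semantics=semantics)
    g = nx.Graph()
    g.add_nodes_from(unreachable)
    for rxn in model.reactions.values():
        members = [m for m in rxn.stoich if m in unreachable]
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def dead_end_metabolites(model: Model) -> set[str]:
    """Internal metabolites only ever produced, or only ever consumed.

    A reversible reaction both produces and consumes each participant, so
    a metabolite touched by one is never a dead end on its account.
    Metabolites incident to no reaction at all are not counted.
    """
    internal = set(model.internal_metabolites())
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        for mid, coef in rxn.stoich.items():
            if mid not in internal:
                continue
            if coef > 0 or rxn.reversible:
                produced.add(mid)
            if coef < 0 or rxn.reversible:
                consumed.add(mid)
    return (produced ^ consumed) & (produced | consumed)


def reconnection_impact(
    model: Model,
    medium: Medium,
    semantics: str = "any",
    tol: float = BLOCKED_TOL,
) -> list[tuple[frozenset[str], int]]:
    """Rank unreachable clusters by what their reconnection would recover.

    For each cluster, one member is granted a hypothetical source (the
    member whose seeding reaches the most new metabolites by traversal),
    and the impact is the number of newly reachable metabolites plus the
    number of previously blocked reactions that become unblocked.  Only
    previously blocked reactions need re-testing: adding a source relaxes
    the flux cone, so unblocked reactions stay unblocked.  Sorted by
    impact descending; ties broken lexicographically on the smallest
    cluster member id.
    """
    clusters = unreachable_clusters(model, medium, semantics=semantics)
    if not clusters:
        return []
    base_reach = reachable_set(model, medium, semantics=semantics)
    base_problem = build_flux_problem(model, medium, objective=None)
    base_blocked = blocked_reactions(base_problem, tol=tol)

    scored: list[tuple[frozenset[str], int]] = []
    for cluster in clusters:
        # pick the member whose seeding recovers the most metabolites
        best_member, best_reach = None, base_reach
        for member in sorted(cluster):
            reach = _reachable_unvalidated(
                model, set(medium.uptake) | {member}, semantics
            )
            if best_member is None or len(reach) > len(best_reach):
                best_member, best_reach = member, reach
        patched = model.copy()
        src_id = "__SOURCE__"
        patched.reactions[src_id] = Reaction(
            id=src_id,
            name="hypothetical source",
            stoich={best_member: 1.0},
            reversible=False,
            lb=0.0,
            ub=DEFAULT_BOUND,
        )
        problem = build_flux_problem(patched, medium, objective=None)
        still = blocked_reactions(problem, tol=tol, reactions=sorted(base_blocked))
        unblocked = len(base_blocked - still)
        impact = len(best_reach - base_reach) + unblocked
        scored.append((cluster, impact))
    return sorted(scored, key=lambda t: (-t[1], min(t[0])))


def _reachable_unvalidated(model: Model, seeds: set[str], semantics: str) -> set[str]:
    """Fixpoint traversal from arbitrary seed metabolites (no medium checks)."""
    internal = set(model.internal_metabolites())
    reached = seeds & internal
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions.values():
            for fwd in (True, False) if rxn.reversible else (True,):
                subs = [m for m in _substrates(rxn, fwd) if m in internal]
                if not subs:
                    continue
                hit = (any if semantics == "any" else all)(m in reached for m in subs)
                if not hit:
                    continue
                for m in _products(rxn, fwd):
                    if m in internal and m not in reached:
                        reached.add(m)
                        changed = True
    return reached


def connectivity_report(
    model: Model, medium: Medium, semantics: str = "any"
) -> ConnectivityReport:
    """Assemble the full reachability picture for a model under a medium."""
    internal = model.internal_metabolites()
    reached = reachable_set(model, medium, semantics=semantics)
    clusters = unreachable_clusters(model, medium, semantics=semantics)
    frac = len(reached) / len(internal) if internal else 1.0
    return ConnectivityReport(
        reachable=reached,
        unreachable_clusters=clusters,
        dead_ends=dead_end_metabolites(model),
        fraction_reachable=frac,
        n_internal=len(internal),
    )
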