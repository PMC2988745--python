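"""Synthetic annotated metabolic models with known ground truth.

Two sources of test input:

* :func:`toy1_model` — a fixed 8-metabolite, 7-reaction model small enough
  that every pipeline answer (reachability, blocked set, FBA optimum,
  knockout fates) can be enumerated by hand;
* :func:`generate_model` — a seeded random generator that plants the
  structural defect classes a curation audit must find (orphan metabolite
  clusters with no path from the medium, dead-end branches) and the gene
  association patterns a knockout screen must resolve (single essential
  genes, isozyme OR-pairs, AND-complexes, redundant parallel routes,
  genes with no reaction), recording every planted feature in a
  :class:`GroundTruth`.

All database accessions emitted by the generator (ChEBI/UniProt/SGD/
PubMed-shaped) are synthetic placeholders, present only so annotation
I/O paths are exercised.  Stoichiometric coefficients are all unit, so
expected fluxes are analytically known: wild-type growth equals the
nutrient uptake bound.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

from .core import (
    Compartment,
    GeneProduct,
    Metabolite,
    MiriamRef,
    Model,
    Reaction,
    find_pseudo_reactions,
)
from .gpr import GprAnd, GprLeaf, GprOr
from .medium import Medium

__all__ = [
    "BIOMASS_SBO",
    "GeneratorSpec",
    "GroundTruth",
    "toy1_model",
    "toy1_medium",
    "generate_model",
    "with_biomass_component",
]

#: SBO term stamped on generated biomass pseudo-reactions (biomass production).
BIOMASS_SBO = "SBO:0000629"


# ------------------------------------------------------------------ TOY1

def toy1_model() -> Model:
    """The fixed hand-checkable fixture.

    Pathway: glucose exchange (uptake bound 10) → transport → glycolysis
    stand-in → precursor synthesis (two-gene complex) → biomass drain.
    Two planted defects: DEAD1 produces a waste metabolite nothing
    consumes, and ORPH consumes an orphan metabolite nothing produces.

    Known answers: scope (7 reactions, 8 metabolites, 5 proteins, 2
    compartments); FBA optimum 10; blocked = {DEAD1, ORPH}; unreachable =
    {orphan_m}; dead ends = {waste_x, orphan_m}; lethal single deletions =
    {G3, G4, G5}.
    """
    m = Model(id="TOY1", name="toy audit fixture")
    m.compartments["e"] = Compartment("e", "external")
    m.compartments["c"] = Compartment("c", "cytosol")

    def met(mid, name, comp, chebi=None, boundary=False):
        refs = {MiriamRef("chebi", chebi)} if chebi else set()
        m.metabolites[mid] = Metabolite(mid, name, comp, refs, boundary)

    met("glc_b", "D-glucose boundary pool", "e", boundary=True)
    met("glc_ext", "D-glucose", "e", chebi="CHEBI:17634")
    met("glc", "D-glucose", "c", chebi="CHEBI:17634")
    met("pyr", "pyruvate", "c", chebi="CHEBI:15361")
    met("bp", "biomass precursor", "c")
    met("waste_x", "waste product X", "c")
    met("orphan_m", "orphan metabolite", "c")
    met("biomass", "biomass", "c", boundary=True)

    for i in range(1, 6):
        m.genes[f"G{i}"] = GeneProduct(
            f"G{i}",
            refs={
                MiriamRef("uniprot", f"P0000{i}"),
                MiriamRef("sgd", f"S00000000{i}"),
                MiriamRef("pubmed", f"1000000{i}", "isDescribedBy"),
            },
        )

    def rxn(rid, name, stoich, gpr=None, lb=0.0, ub=1000.0, sbo=None, pubmed=None):
        ev = {MiriamRef("pubmed", pubmed, "isDescribedBy")} if pubmed else set()
        m.reactions[rid] = Reaction(
            rid, name, stoich, reversible=lb < 0, lb=lb, ub=ub,
            gpr=gpr, sbo=sbo, evidence=ev,
        )

    rxn("EX_glc", "glucose exchange", {"glc_ext": -1.0, "glc_b": 1.0}, lb=-10.0)
    rxn("T1", "glucose transport", {"glc_ext": -1.0, "glc": 1.0},
        gpr=GprOr((GprLeaf("G1"), GprLeaf("G2"))))
    rxn("R1", "glucose to pyruvate", {"glc": -1.0, "pyr": 1.0},
        gpr=GprLeaf("G3"), pubmed="12345678")
    rxn("R2", "precursor synthesis", {"pyr": -1.0, "bp": 1.0},
        gpr=GprAnd((GprLeaf("G4"), GprLeaf("G5"))))
    rxn("GROWTH", "biomass drain", {"bp": -1.0, "biomass": 1.0}, sbo=BIOMASS_SBO)
    rxn("DEAD1", "waste branch", {"pyr": -1.0, "waste_x": 1.0})
    rxn("ORPH", "orphan consumer", {"orphan_m": -1.0, "pyr": 1.0})
    return m


def toy1_medium() -> Medium:
    """Glucose-limited minimal medium for the fixture (uptake 10)."""
    return Medium({"glc_ext": 10.0})


# -------------------------------------------------------------- generator

@dataclass(frozen=True)
class GeneratorSpec:
    """Sizes and seed for a planted-defect model.

    Defaults produce a reconstruction-sized network: 1102 reactions over
    758 internal metabolites, with 75 metabolites in 25 orphan clusters
    (9.9% unreachable) and 140 structurally blocked reactions (12.7%),
    mirroring the connectivity profile of a curated genome-scale yeast
    network.  ``n_parallel_routes`` chain steps get a redundant duplicate
    reaction under a different gene, emulating isozyme re-routing at the
    reaction level.
    """

    n_backbone: int = 618            # backbone metabolites m1..mB
    n_isozyme_pairs: int = 30        # chain steps catalysed by (gA or gB)
    n_complexes: int = 30            # chain steps catalysed by (gA and gB)
    n_parallel_routes: int = 342     # chain steps with a duplicate reaction
    n_orphan_clusters: int = 25
    orphan_cluster_size: int = 3
    n_deadend_branches: int = 65
    n_unused_genes: int = 50
    seed: int = 0
    uptake: float = 10.0             # mmol·gDW⁻¹·h⁻¹
    bound_scale: float = 1000.0

    def validate(self) -> None:
        counts = (
            self.n_backbone, self.n_isozyme_pairs, self.n_complexes,
            self.n_parallel_routes, self.n_orphan_clusters,
            self.orphan_cluster_size, self.n_deadend_branches,
            self.n_unused_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all generator counts must be >= 0")
        if self.n_backbone < 1:
            raise ValueError("a biomass pathway needs n_backbone >= 1")
        n_edges = self.n_backbone - 1
        n_featured = self.n_isozyme_pairs + self.n_complexes + self.n_parallel_routes
        if n_featured > n_edges:
            raise ValueError(
                f"{n_featured} featured chain steps requested but only "
                f"{n_edges} backbone steps exist"
            )
        if self.n_orphan_clusters > 0 and self.orphan_cluster_size < 1:
            raise ValueError("orphan clusters need size >= 1")
        if self.uptake < 0 or self.bound_scale <= 0:
            raise ValueError("uptake must be >= 0 and bound_scale > 0")


@dataclass
class GroundTruth:
    """Record of every planted feature, for recovery tests."""

    medium_metabolite: str
    uptake: float
    wildtype_growth: float
    orphan_metabolites: set[str] = field(default_factory=set)
    orphan_clusters: list[frozenset[str]] = field(default_factory=list)
    blocked_reactions: set[str] = field(default_factory=set)
    deadend_metabolites: set[str] = field(default_factory=set)
    essential_genes: set[str] = field(default_factory=set)
    isozyme_pairs: set[tuple[str, str]] = field(default_factory=set)
    unused_genes: set[str] = field(default_factory=set)

    def medium(self) -> Medium:
        return Medium({self.medium_metabolite: self.uptake})

    def expected_dead_ends(self) -> set[str]:
        """Dead ends the audit should report: branch tips plus orphan heads."""
        heads = {min(c, key=_orphan_sort_key) for c in self.orphan_clusters}
        return self.deadend_metabolites | heads

    def to_json(self) -> str:
        d = asdict(self)
        d["orphan_clusters"] = [sorted(c) for c in self.orphan_clusters]
        for k in ("orphan_metabolites", "blocked_reactions", "deadend_metabolites",
                  "essential_genes", "unused_genes"):
            d[k] = sorted(d[k])
        d["isozyme_pairs"] = sorted(map(list, self.isozyme_pairs))
        return json.dumps(d, indent=2)


def _orphan_sort_key(mid: str):
    return mid


def generate_model(spec: GeneratorSpec) -> tuple[Model, GroundTruth]:
    """Build a feasible annotated model with planted defects.

    Topology: nutrient exchange → transport → linear backbone of
    unit-coefficient conversions → biomass drain.  Defects and gene
    patterns are attached at seeded-random backbone positions; planted
    classes never overlap (a chain step carries at most one feature, and
    orphan clusters never touch dead-end branches).  Identical seeds give
    byte-identical SBML.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    B, scale = spec.n_backbone, spec.bound_scale

    model = Model(id=f"synth_seed{spec.seed}", name="synthetic audit model")
    model.compartments["e"] = Compartment("e", "external")
    model.compartments["c"] = Compartment("c", "cytosol")

    met_counter = 0

    def add_met(mid, name, comp, boundary=False):
        nonlocal met_counter
        met_counter += 1
        refs = set() if boundary else {MiriamRef("chebi", f"CHEBI:9{met_counter:06d}")}
        model.metabolites[mid] = Metabolite(mid, name, comp, refs, boundary)

    gene_counter = 0

    def add_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"G{gene_counter:05d}"
        model.genes[gid] = GeneProduct(
            gid,
            refs={
                MiriamRef("uniprot", f"P{gene_counter:05d}"),
                MiriamRef("sgd", f"S{gene_counter:09d}"),
            },
        )
        return gid

    rxn_counter = 0

    def add_rxn(rid, stoich, gpr=None, lb=0.0, ub=scale, sbo=None):
        nonlocal rxn_counter
        rxn_counter += 1
        model.reactions[rid] = Reaction(
            rid, rid.lower().replace("_", " "), stoich,
            reversible=lb < 0, lb=lb, ub=ub, gpr=gpr, sbo=sbo,
            evidence={MiriamRef("pubmed", f"{90000000 + rxn_counter}", "isDescribedBy")},
        )

    add_met("nut_b", "nutrient boundary pool", "e", boundary=True)
    add_met("nut_e", "nutrient", "e")
    backbone = [f"m{i:04d}" for i in range(1, B + 1)]
    for mid in backbone:
        add_met(mid, f"intermediate {mid}", "c")
    add_met("bio_b", "biomass", "c", boundary=True)

    add_rxn("EX_nut", {"nut_e": -1.0, "nut_b": 1.0}, lb=-spec.uptake)
    add_rxn("TRANS", {"nut_e": -1.0, backbone[0]: 1.0})

    # one feature per chain step, drawn without overlap
    n_edges = B - 1
    featured = rng.sample(range(n_edges), spec.n_isozyme_pairs
                          + spec.n_complexes + spec.n_parallel_routes)
    iso_edges = set(featured[: spec.n_isozyme_pairs])
    cpx_edges = set(featured[spec.n_isozyme_pairs:
                             spec.n_isozyme_pairs + spec.n_complexes])
    par_edges = set(featured[spec.n_isozyme_pairs + spec.n_complexes:])

    truth = GroundTruth(
        medium_metabolite="nut_e", uptake=spec.uptake, wildtype_growth=spec.uptake
    )
    parallels: list[tuple[str, dict, str]] = []
    for i in range(n_edges):
        stoich = {backbone[i]: -1.0, backbone[i + 1]: 1.0}
        rid = f"R{i + 1:04d}"
        if i in iso_edges:
            a, b = add_gene(), add_gene()
            add_rxn(rid, stoich, gpr=GprOr((GprLeaf(a), GprLeaf(b))))
            truth.isozyme_pairs.add((a, b))
        elif i in cpx_edges:
            a, b = add_gene(), add_gene()
            add_rxn(rid, stoich, gpr=GprAnd((GprLeaf(a), GprLeaf(b))))
            truth.essential_genes |= {a, b}
        elif i in par_edges:
            a = add_gene()
            add_rxn(rid, stoich, gpr=GprLeaf(a))
            parallels.append((f"P{i + 1:04d}", dict(stoich), rid))
        else:
            a = add_gene()
            add_rxn(rid, stoich, gpr=GprLeaf(a))
            truth.essential_genes.add(a)
    for pid, stoich, _ in parallels:  # duplicate routes under their own gene
        add_rxn(pid, stoich, gpr=GprLeaf(add_gene()))

    add_rxn("BIOMASS", {backbone[-1]: -1.0, "bio_b": 1.0}, sbo=BIOMASS_SBO)

    # orphan clusters: a chain with no producer for its head, feeding the
    # backbone through a connector; every reaction in the chain is blocked
    for k in range(1, spec.n_orphan_clusters + 1):
        members = []
        for j in range(1, spec.orphan_cluster_size + 1):
            mid = f"o{k:03d}_{j:02d}"
            add_met(mid, f"orphan {mid}", "c")
            members.append(mid)
        for j in range(len(members) - 1):
            rid = f"ORX{k:03d}_{j + 1:02d}"
            add_rxn(rid, {members[j]: -1.0, members[j + 1]: 1.0}, gpr=GprLeaf(add_gene()))
            truth.blocked_reactions.add(rid)
        attach = backbone[rng.randrange(B)]
        rid = f"ORC{k:03d}"
        add_rxn(rid, {members[-1]: -1.0, attach: 1.0}, gpr=GprLeaf(add_gene()))
        truth.blocked_reactions.add(rid)
        truth.orphan_metabolites |= set(members)
        truth.orphan_clusters.append(frozenset(members))

    # dead-end branches: a product nothing consumes
    for j in range(1, spec.n_deadend_branches + 1):
        tip = f"w{j:03d}"
        add_met(tip, f"dead-end product {tip}", "c")
        attach = backbone[rng.randrange(B)]
        rid = f"DE{j:03d}"
        add_rxn(rid, {attach: -1.0, tip: 1.0}, gpr=GprLeaf(add_gene()))
        truth.blocked_reactions.add(rid)
        truth.deadend_metabolites.add(tip)

    for _ in range(spec.n_unused_genes):
        truth.unused_genes.add(add_gene())

    return model, truth


def with_biomass_component(model: Model, metabolite_id: str, coefficient: float) -> Model:
    """Return a copy whose biomass reaction also drains the given component.

    ``coefficient`` is the demand per unit of biomass flux (positive =
    consumed).  This reproduces the empirical biomass-refinement move: a
    component producible only through one gene's reaction makes that gene
    essential once the component joins the biomass definition.
    """
    if metabolite_id not in model.metabolites:
        raise KeyError(f"metabolite {metabolite_id!r} not in model")
    pseudo = sorted(find_pseudo_reactions(model))
    if not pseudo:
        raise ValueError("no biomass pseudo-reaction found (missing SBO annotation?)")
    if len(pseudo) > 1:
        raise ValueError(f"ambiguous biomass pseudo-reaction: {pseudo}")
    out = model.copy()
    rxn = out.reactions[pseudo[0]]
    new = rxn.stoich.get(metabolite_id, 0.0) - coefficient
    if new == 0.0:
        rxn.stoich.pop(metabolite_id, None)
    else:
        rxn.stoich[metabolite_id] = new
    return out
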