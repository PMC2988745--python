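"""Domain types for annotated metabolic models.

The unit every pipeline stage consumes is a :class:`Model`: compartments,
annotated metabolites and gene products, and an ordered collection of
reactions carrying stoichiometry, flux bounds (mmol·gDW⁻¹·h⁻¹), a boolean
gene association and optional ontology (SBO) terms that distinguish
pseudo-reactions (biomass, demands) from real chemistry.

Annotations follow the MIRIAM convention: each entity may reference one or
more external database records (ChEBI for metabolites, UniProt/SGD for gene
products, PubMed for evidence) through :class:`MiriamRef` triples.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .gpr import Gpr, gpr_genes, gpr_to_string

logger = logging.getLogger(__name__)

__all__ = [
    "MiriamRef",
    "Compartment",
    "Metabolite",
    "GeneProduct",
    "Reaction",
    "Model",
    "ScopeStats",
    "ModelIntegrityError",
    "DEFAULT_BOUND",
    "BIOMASS_SBO_TERMS",
    "validate_model",
    "model_stats",
    "find_pseudo_reactions",
    "decompartmentalise",
    "exchange_reactions",
    "external_compartments",
]

#: Default flux bound magnitude when a document states only a reversible flag.
DEFAULT_BOUND = 1000.0

#: SBO terms marking non-metabolic pseudo-reactions (biomass production,
#: biomass, demand).  Configurable per call in :func:`find_pseudo_reactions`.
BIOMASS_SBO_TERMS = frozenset({"SBO:0000629", "SBO:0000395", "SBO:0000628"})


class ModelIntegrityError(ValueError):
    """A model invariant is violated; the message names the element."""


@dataclass(frozen=True)
class MiriamRef:
    """A MIRIAM-style reference: (database, accession, relation qualifier)."""

    database: str
    identifier: str
    qualifier: str = "is"

    def __post_init__(self):
        if not self.database or not self.identifier:
            raise ValueError("MiriamRef requires non-empty database and identifier")


@dataclass
class Compartment:
    id: str
    name: str = ""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    refs: set[MiriamRef] = field(default_factory=set)
    is_boundary: bool = False

    def chebi_ids(self) -> frozenset[str]:
        return frozenset(r.identifier for r in self.refs if r.database == "chebi")


@dataclass
class GeneProduct:
    id: str
    refs: set[MiriamRef] = field(default_factory=set)


@dataclass
class Reaction:
    """One reaction: signed stoichiometry (negative = substrate), bounds, GPR.

    ``sbo`` carries the ontology term ("SBO:0000629"-style token) when the
    document declares one; ``evidence`` holds literature references.
    """

    id: str
    name: str = ""
    stoich: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    gpr: Optional[Gpr] = None
    sbo: Optional[str] = None
    evidence: set[MiriamRef] = field(default_factory=set)

    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)


@dataclass
class Model:
    id: str = "model"
    name: str = ""
    compartments: dict[str, Compartment] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, GeneProduct] = field(default_factory=dict)
    notes: str = ""

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def internal_metabolites(self) -> list[str]:
        """Metabolite ids subject to mass balance (non-boundary)."""
        return [m.id for m in self.metabolites.values() if not m.is_boundary]


@dataclass(frozen=True)
class ScopeStats:
    """Reconstruction scope: unique reactions, metabolites, proteins, compartments."""

    n_reactions: int
    n_metabolites: int
    n_proteins: int
    n_compartments: int

    def __post_init__(self):
        for f in (self.n_reactions, self.n_metabolites, self.n_proteins, self.n_compartments):
            if f < 0:
                raise ValueError("scope counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return {
            "reactions": self.n_reactions,
            "metabolites": self.n_metabolites,
            "proteins": self.n_proteins,
            "compartments": self.n_compartments,
        }


def validate_model(model: Model, strict: bool = True) -> list[str]:
    """Check referential integrity and bound sanity.

    Returns the list of problems found.  With ``strict=True`` the first
    problem raises :class:`ModelIntegrityError`; with ``strict=False`` all
    problems are logged and returned so a caller may repair them.
    """
    problems: list[str] = []

    def flag(msg: str):
        if strict:
            raise ModelIntegrityError(msg)
        logger.warning("model %s: %s", model.id, msg)
        problems.append(msg)

    for met in model.metabolites.values():
        if met.compartment and met.compartment not in model.compartments:
            flag(f"metabolite {met.id} references undeclared compartment {met.compartment}")
    for rxn in model.reactions.values():
        if rxn.lb > rxn.ub:
            flag(f"reaction {rxn.id} has lb > ub ({rxn.lb} > {rxn.ub})")
        for mid in rxn.stoich:
            if mid not in model.metabolites:
                flag(f"reaction {rxn.id} references undeclared metabolite {mid}")
        for g in rxn.genes():
            if g not in model.genes:
                flag(f"reaction {rxn.id} GPR references undeclared gene {g}")
    return problems


def find_pseudo_reactions(
    model: Model, sbo_terms: Iterable[str] = BIOMASS_SBO_TERMS
) -> set[str]:
    """Reactions semantically annotated as non-metabolic (biomass/demand).

    The biomass reaction does not represent real chemistry; its SBO
    annotation is what lets tooling single it out (as objective, or for
    removal before scope counting).  The accepted term set is configurable
    because different model generations used different terms.
    """
    terms = set(sbo_terms)
    return {r.id for r in model.reactions.values() if r.sbo in terms}


def model_stats(model: Model) -> ScopeStats:
    """Scope statistics: distinct reactions, metabolites, proteins, compartments.

    A gene product counts toward ``n_proteins`` iff it appears in at least
    one GPR of a non-pseudo reaction.
    """
    pseudo = find_pseudo_reactions(model)
    proteins: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.id not in pseudo:
            proteins |= rxn.genes()
    return ScopeStats(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_proteins=len(proteins),
        n_compartments=len(model.compartments),
    )


def exchange_reactions(model: Model) -> set[str]:
    """Reactions transporting a species across the system boundary.

    Identified structurally: at most one non-boundary participant (the
    classic ``EX_`` column shape), excluding annotated pseudo-reactions
    such as biomass.
    """
    pseudo = find_pseudo_reactions(model)
    out = set()
    for rxn in model.reactions.values():
        if rxn.id in pseudo or not rxn.stoich:
            continue
        internal = [m for m in rxn.stoich if not model.metabolites[m].is_boundary]
        if len(internal) <= 1:
            out.add(rxn.id)
    return out


def external_compartments(model: Model) -> set[str]:
    """Compartments on the medium side of the boundary.

    A compartment is external if it hosts a non-boundary participant of an
    exchange reaction, or if its id/name is a conventional extracellular
    token.  (Boundary species alone do not qualify a compartment: biomass
    drains place boundary sinks inside the cell.)
    """
    tokens = {"e", "ext", "external", "extracellular", "out", "env", "environment"}
    out = {
        c.id
        for c in model.compartments.values()
        if c.id.lower() in tokens or c.name.lower() in tokens
    }
    for rid in exchange_reactions(model):
        for mid in model.reactions[rid].stoich:
            met = model.metabolites[mid]
            if not met.is_boundary and met.compartment:
                out.add(met.compartment)
    return out


# -- decompartmentalisation --------------------------------------------------

_MERGED_COMPARTMENT = "u"


def _strip_compartment_suffix(name: str, model: Model) -> str:
    """Normalise a metabolite name for cross-compartment matching."""
    n = name.strip().lower()
    # bracketed or underscore/space-suffixed compartment tags
    for comp in model.compartments.values():
        for tag in filter(None, {comp.id.lower(), comp.name.lower()}):
            for pattern in (f"[{tag}]", f"_{tag}", f" {tag}"):
                if n.endswith(pattern):
                    n = n[: -len(pattern)].strip()
    return n


def decompartmentalise(model: Model) -> Model:
    """Merge species across compartments and drop the transport thereby emptied.

    Metabolites sharing a ChEBI reference (or, lacking one, a
    compartment-stripped case-insensitive name) are merged into a single
    species; boundary species only ever merge with other boundary species.
    Reactions whose merged stoichiometry cancels to nothing (pure
    transport) are removed, and reactions that become identical in
    stoichiometry, directionality and GPR are collapsed to one.  The result
    has a single compartment and is what "unique reaction/metabolite"
    scope counts are computed on.

    Idempotent: applying it to an already merged model is a no-op on all
    scope statistics.
    """
    validate_model(model)

    # choose a merge key per metabolite
    def merge_key(met: Metabolite):
        chebi = met.chebi_ids()
        if chebi:
            body = ("chebi", tuple(sorted(chebi)))
        else:
            body = ("name", _strip_compartment_suffix(met.name or met.id, model))
        return (met.is_boundary,) + body

    groups: dict[tuple, list[Metabolite]] = {}
    for met in model.metabolites.values():
        groups.setdefault(merge_key(met), []).append(met)

    old_to_new: dict[str, str] = {}
    merged = Model(id=model.id, name=model.name, notes=model.notes)
    merged.compartments[_MERGED_COMPARTMENT] = Compartment(_MERGED_COMPARTMENT, "unified")
    for key, members in groups.items():
        rep = min(members, key=lambda m: m.id)  # deterministic representative
        refs: set[MiriamRef] = set()
        for m in members:
            refs |= m.refs
        merged.metabolites[rep.id] = Metabolite(
            id=rep.id,
            name=rep.name,
            compartment=_MERGED_COMPARTMENT,
            refs=refs,
            is_boundary=rep.is_boundary,
        )
        for m in members:
            old_to_new[m.id] = rep.id

    merged.genes = copy.deepcopy(model.genes)

    seen: dict[tuple, str] = {}
    for rxn in model.reactions.values():
        stoich: dict[str, float] = {}
        for mid, coef in rxn.stoich.items():
            nid = old_to_new[mid]
            stoich[nid] = stoich.get(nid, 0.0) + coef
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich and rxn.stoich:
            continue  # pure transport annihilated by the merge
        dedup_key = (
            tuple(sorted(stoich.items())),
            rxn.reversible,
            rxn.gpr.canonical() if rxn.gpr is not None else "",
        )
        if dedup_key in seen:
            # same reaction in another compartment: keep one, pool evidence
            merged.reactions[seen[dedup_key]].evidence |= rxn.evidence
            continue
        seen[dedup_key] = rxn.id
        merged.reactions[rxn.id] = Reaction(
            id=rxn.id,
            name=rxn.name,
            stoich=stoich,
            reversible=rxn.reversible,
            lb=rxn.lb,
            ub=rxn.ub,
            gpr=rxn.gpr,
            sbo=rxn.sbo,
            evidence=set(rxn.evidence),
        )
    return merged
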