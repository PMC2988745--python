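"""SBML Level 2 reading and writing with MIRIAM annotation preservation.

Supported dialects are Level 2 Version 4 (the default) and Level 2
Version 1 (kept for backward compatibility with older tooling).  Both
round-trip the same model content:

* entity identity annotations travel as RDF ``bqbiol`` CV terms with
  ``identifiers.org`` resource URIs (``urn:miriam:`` URNs are also read);
* flux bounds use the legacy constraint-based convention of
  ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters;
* gene associations are written both as a ``GENE_ASSOCIATION:`` boolean
  string in the reaction notes and as modifier species references; on
  read the notes string wins (it carries the and/or structure) and bare
  modifiers fall back to an OR over all modifiers;
* gene products are species tagged with the polypeptide SBO term (and a
  notes marker for the v1 dialect, which predates the ``sboTerm``
  attribute) so they are never confused with metabolites;
* the reaction SBO term itself rides the ``sboTerm`` attribute in v4 and
  an ``SBO:`` notes line in v1.
"""

from __future__ import annotations

import re
import urllib.parse
from typing import Optional

import libsbml

from .core import (
    DEFAULT_BOUND,
    Compartment,
    GeneProduct,
    Metabolite,
    MiriamRef,
    Model,
    ModelIntegrityError,
    Reaction,
    validate_model,
)
from .gpr import GprOr, GprLeaf, gpr_to_string, parse_gpr

__all__ = ["read_sbml", "write_sbml", "read_sbml_file", "write_sbml_file",
           "SbmlReadError", "UnsupportedDialectError"]

GENE_SBO = "SBO:0000252"  # polypeptide chain

_QUALIFIERS = {
    "is": libsbml.BQB_IS,
    "hasPart": libsbml.BQB_HAS_PART,
    "isPartOf": libsbml.BQB_IS_PART_OF,
    "isVersionOf": libsbml.BQB_IS_VERSION_OF,
    "hasVersion": libsbml.BQB_HAS_VERSION,
    "isHomologTo": libsbml.BQB_IS_HOMOLOG_TO,
    "isDescribedBy": libsbml.BQB_IS_DESCRIBED_BY,
    "isEncodedBy": libsbml.BQB_IS_ENCODED_BY,
    "encodes": libsbml.BQB_ENCODES,
    "occursIn": libsbml.BQB_OCCURS_IN,
    "hasProperty": libsbml.BQB_HAS_PROPERTY,
    "isPropertyOf": libsbml.BQB_IS_PROPERTY_OF,
}
_QUALIFIER_NAMES = {v: k for k, v in _QUALIFIERS.items()}


class SbmlReadError(ValueError):
    """The document could not be parsed as SBML; message carries line info."""


class UnsupportedDialectError(SbmlReadError):
    """The document is valid XML but not an SBML Level 2 dialect we handle."""


# ---------------------------------------------------------------- writing

def _sbo_int(term: str) -> int:
    return int(term.rsplit(":", 1)[-1])


def _set_cvterms(element, refs: set[MiriamRef]) -> None:
    if not refs:
        return
    element.setMetaId("meta_" + element.getId())
    by_qual: dict[str, list[MiriamRef]] = {}
    for ref in sorted(refs, key=lambda r: (r.qualifier, r.database, r.identifier)):
        by_qual.setdefault(ref.qualifier, []).append(ref)
    for qual, group in sorted(by_qual.items()):
        cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(_QUALIFIERS.get(qual, libsbml.BQB_IS))
        for ref in group:
            cv.addResource(f"http://identifiers.org/{ref.database}/{ref.identifier}")
        element.addCVTerm(cv)


def _set_notes(element, lines: list[str]) -> None:
    if not lines:
        return
    body = "".join(f"<p>{line}</p>" for line in lines)
    element.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def write_sbml(model: Model, dialect: str = "l2v4") -> str:
    """Serialise a model to SBML text in the requested Level 2 dialect.

    Refuses (``ModelIntegrityError``) if the model violates its invariants;
    the emitted document re-reads to an equivalent model (same scope
    statistics, annotation sets, bounds and GPR truth tables).
    """
    if dialect not in ("l2v1", "l2v4"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'l2v1' or 'l2v4'")
    validate_model(model)
    version = 1 if dialect == "l2v1" else 4
    doc = libsbml.SBMLDocument(2, version)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    if model.name:
        sm.setName(model.name)
    if model.notes:
        _set_notes(sm, [model.notes])

    for comp in model.compartments.values():
        sc = sm.createCompartment()
        sc.setId(comp.id)
        if comp.name:
            sc.setName(comp.name)
        sc.setSize(1.0)

    if (model.metabolites or model.genes) and not model.compartments:
        raise ModelIntegrityError("species present but no compartment declared")
    default_comp = next(iter(model.compartments), None)

    for met in model.metabolites.values():
        ss = sm.createSpecies()
        ss.setId(met.id)
        if met.name:
            ss.setName(met.name)
        ss.setCompartment(met.compartment or default_comp)
        ss.setBoundaryCondition(met.is_boundary)
        ss.setInitialConcentration(0.0)
        _set_cvterms(ss, met.refs)

    for gene in model.genes.values():
        ss = sm.createSpecies()
        ss.setId(gene.id)
        ss.setCompartment(default_comp)
        ss.setBoundaryCondition(True)
        ss.setInitialConcentration(0.0)
        if dialect == "l2v4":
            ss.setSBOTerm(_sbo_int(GENE_SBO))
        if dialect == "l2v1":  # v1 predates sboTerm; marker rides the notes
            _set_notes(ss, [f"SBO: {GENE_SBO}"])
        _set_cvterms(ss, gene.refs)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        notes = []
        if rxn.gpr is not None:
            notes.append(f"GENE_ASSOCIATION: {gpr_to_string(rxn.gpr)}")
        if rxn.sbo is not None:
            if dialect == "l2v4":
                sr.setSBOTerm(_sbo_int(rxn.sbo))
            else:
                notes.append(f"SBO: {rxn.sbo}")
        _set_notes(sr, notes)
        for mid, coef in sorted(rxn.stoich.items()):
            if coef < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
        for gid in sorted(rxn.genes()):
            mod = sr.createModifier()
            mod.setSpecies(gid)
        law = sr.createKineticLaw()
        law.setFormula("FLUX_VALUE")
        for pid, value in (
            ("LOWER_BOUND", rxn.lb),
            ("UPPER_BOUND", rxn.ub),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 0.0),
        ):
            par = law.createParameter()
            par.setId(pid)
            par.setValue(value)
        _set_cvterms(sr, rxn.evidence)

    return libsbml.writeSBMLToString(doc)


def write_sbml_file(model: Model, path, dialect: str = "l2v4") -> None:
    with open(path, "w") as fh:
        fh.write(write_sbml(model, dialect=dialect))


# ---------------------------------------------------------------- reading

def _parse_resource(uri: str) -> Optional[tuple[str, str]]:
    """Extract (database, identifier) from identifiers.org / miriam URIs."""
    uri = uri.strip()
    if uri.startswith("urn:miriam:"):
        rest = uri[len("urn:miriam:"):]
        db, _, ident = rest.partition(":")
        if db and ident:
            return db, urllib.parse.unquote(ident)
        return None
    m = re.match(r"https?://identifiers\.org/(.+)$", uri)
    if m:
        rest = m.group(1)
        if "/" in rest:
            db, ident = rest.split("/", 1)
        elif ":" in rest:  # compact identifiers.org form db:id
            db, ident = rest.split(":", 1)
        else:
            return None
        if db and ident:
            return db, urllib.parse.unquote(ident)
    return None


def _get_refs(element) -> set[MiriamRef]:
    refs: set[MiriamRef] = set()
    for i in range(element.getNumCVTerms()):
        cv = element.getCVTerm(i)
        if cv.getQualifierType() == libsbml.BIOLOGICAL_QUALIFIER:
            qual = _QUALIFIER_NAMES.get(cv.getBiologicalQualifierType(), "is")
        else:
            qual = "is"
        for j in range(cv.getNumResources()):
            parsed = _parse_resource(cv.getResourceURI(j))
            if parsed:
                refs.add(MiriamRef(parsed[0], parsed[1], qual))
    return refs


_P_LINE = re.compile(r"<p[^>]*>(.*?)</p>", re.DOTALL)


def _get_note_fields(element) -> tuple[dict[str, str], list[str]]:
    """Split notes into KEY: value fields and free-text lines."""
    fields: dict[str, str] = {}
    free: list[str] = []
    if not element.isSetNotes():
        return fields, free
    html = element.getNotesString()
    for raw in _P_LINE.findall(html):
        line = re.sub(r"<[^>]+>", "", raw).strip()
        if not line:
            continue
        m = re.match(r"([A-Z_]+):\s*(.*)$", line)
        if m:
            fields[m.group(1)] = m.group(2).strip()
        else:
            free.append(line)
    return fields, free


def _sbo_token(element, note_fields: dict[str, str]) -> Optional[str]:
    if element.isSetSBOTerm():
        return element.getSBOTermID()
    if "SBO" in note_fields:
        return note_fields["SBO"]
    return None


def read_sbml(document: str, strict: bool = True) -> Model:
    """Parse SBML Level 2 text into a :class:`Model`.

    Species that carry the polypeptide SBO term, or that only ever appear
    as reaction modifiers, are classified as gene products rather than
    metabolites.  With ``strict=True`` a dangling cross-reference raises
    :class:`~gsmaudit.core.ModelIntegrityError`; with ``strict=False`` the
    problem is logged and repaired by declaring the missing element.
    """
    doc = libsbml.readSBMLFromString(document)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SbmlReadError(
                f"SBML parse error at line {err.getLine()}, column "
                f"{err.getColumn()}: {err.getMessage()}"
            )
    if doc.getLevel() != 2:
        raise UnsupportedDialectError(
            f"unsupported SBML dialect: level {doc.getLevel()} version "
            f"{doc.getVersion()}; only Level 2 is handled"
        )
    sm = doc.getModel()
    if sm is None:
        raise SbmlReadError("document contains no <model> element")

    model = Model(id=sm.getId() or "model", name=sm.getName() or "")
    _, free = _get_note_fields(sm)
    model.notes = "\n".join(free)

    for i in range(sm.getNumCompartments()):
        sc = sm.getCompartment(i)
        model.compartments[sc.getId()] = Compartment(sc.getId(), sc.getName() or "")

    # first pass over reactions: which species are stoichiometric vs modifiers
    stoich_species: set[str] = set()
    modifier_species: set[str] = set()
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        for j in range(sr.getNumReactants()):
            stoich_species.add(sr.getReactant(j).getSpecies())
        for j in range(sr.getNumProducts()):
            stoich_species.add(sr.getProduct(j).getSpecies())
        for j in range(sr.getNumModifiers()):
            modifier_species.add(sr.getModifier(j).getSpecies())

    for i in range(sm.getNumSpecies()):
        ss = sm.getSpecies(i)
        sid = ss.getId()
        note_fields, _ = _get_note_fields(ss)
        sbo = _sbo_token(ss, note_fields)
        is_gene = sbo == GENE_SBO or (
            sid in modifier_species and sid not in stoich_species
        )
        if is_gene:
            model.genes[sid] = GeneProduct(id=sid, refs=_get_refs(ss))
        else:
            model.metabolites[sid] = Metabolite(
                id=sid,
                name=ss.getName() or "",
                compartment=ss.getCompartment() or "",
                refs=_get_refs(ss),
                is_boundary=ss.getBoundaryCondition(),
            )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        note_fields, _ = _get_note_fields(sr)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        reversible = sr.getReversible()
        lb, ub = None, None
        if sr.isSetKineticLaw():
            law = sr.getKineticLaw()
            for j in range(law.getNumParameters()):
                par = law.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        if "GENE_ASSOCIATION" in note_fields:
            gpr = parse_gpr(note_fields["GENE_ASSOCIATION"])
        else:
            mods = sorted(
                sr.getModifier(j).getSpecies() for j in range(sr.getNumModifiers())
            )
            mods = [m for m in mods if m in model.genes]
            if not mods:
                gpr = None
            elif len(mods) == 1:
                gpr = GprLeaf(mods[0])
            else:
                gpr = GprOr(tuple(GprLeaf(m) for m in mods))

        model.reactions[sr.getId()] = Reaction(
            id=sr.getId(),
            name=sr.getName() or "",
            stoich=stoich,
            reversible=lb < 0,  # reversibility follows the bounds on load
            lb=lb,
            ub=ub,
            gpr=gpr,
            sbo=_sbo_token(sr, note_fields),
            evidence=_get_refs(sr),
        )

    problems = validate_model(model, strict=strict)
    for msg in problems:  # strict=False: repair by declaring the missing element
        m = re.search(r"undeclared compartment (\S+)", msg)
        if m:
            model.compartments[m.group(1)] = Compartment(m.group(1), "auto-repaired")
        m = re.search(r"undeclared metabolite (\S+)", msg)
        if m:
            model.metabolites[m.group(1)] = Metabolite(id=m.group(1), name="auto-repaired")
        m = re.search(r"undeclared gene (\S+)", msg)
        if m:
            model.genes[m.group(1)] = GeneProduct(id=m.group(1))
    return model


def read_sbml_file(path, strict: bool = True) -> Model:
    with open(path) as fh:
        return read_sbml(fh.read(), strict=strict)
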