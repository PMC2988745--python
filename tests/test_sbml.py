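import itertools

import pytest

from gsmaudit import (
    GeneratorSpec,
    Model,
    ModelIntegrityError,
    find_pseudo_reactions,
    generate_model,
    model_stats,
    read_sbml,
    write_sbml,
)
from gsmaudit.gpr import evaluate_gpr, gpr_genes
from gsmaudit.sbml_io import SbmlReadError, UnsupportedDialectError


def _assert_equivalent(a: Model, b: Model):
    """Scope, annotations, bounds and GPR truth tables all preserved."""
    assert model_stats(a) == model_stats(b)
    assert set(a.metabolites) == set(b.metabolites)
    for mid, met in a.metabolites.items():
        assert b.metabolites[mid].refs == met.refs
        assert b.metabolites[mid].is_boundary == met.is_boundary
    assert set(a.genes) == set(b.genes)
    for gid, gene in a.genes.items():
        assert b.genes[gid].refs == gene.refs
    assert set(a.reactions) == set(b.reactions)
    for rid, rxn in a.reactions.items():
        other = b.reactions[rid]
        assert other.stoich == rxn.stoich
        assert (other.lb, other.ub, other.reversible) == (rxn.lb, rxn.ub, rxn.reversible)
        assert other.sbo == rxn.sbo
        assert other.evidence == rxn.evidence
        genes = sorted(gpr_genes(rxn.gpr))
        for r in range(len(genes) + 1):  # full truth table
            for deleted in itertools.combinations(genes, r):
                assert evaluate_gpr(other.gpr, set(deleted)) == evaluate_gpr(
                    rxn.gpr, set(deleted)
                ), (rid, deleted)


@pytest.mark.parametrize("dialect", ["l2v1", "l2v4"])
def test_roundtrip_toy1(toy1, dialect):
    back = read_sbml(write_sbml(toy1, dialect=dialect))
    _assert_equivalent(toy1, back)
    assert find_pseudo_reactions(back) == {"GROWTH"}


@pytest.mark.parametrize("dialect", ["l2v1", "l2v4"])
def test_roundtrip_generated_model(dialect):
    model, _ = generate_model(
        GeneratorSpec(n_backbone=6, n_isozyme_pairs=1, n_complexes=1,
                      n_parallel_routes=1, n_orphan_clusters=1, orphan_cluster_size=2,
                      n_deadend_branches=1, n_unused_genes=2, seed=11)
    )
    back = read_sbml(write_sbml(model, dialect=dialect))
    _assert_equivalent(model, back)


def test_dialects_agree_on_scope(toy1):
    stats = {
        d: model_stats(read_sbml(write_sbml(toy1, dialect=d)))
        for d in ("l2v1", "l2v4")
    }
    assert stats["l2v1"] == stats["l2v4"]


def test_enzyme_annotation_block_roundtrip(toy1):
    """A gene product annotated against UniProt, SGD and PubMed keeps all 3 refs."""
    back = read_sbml(write_sbml(toy1))
    refs = back.genes["G1"].refs
    assert {r.database for r in refs} == {"uniprot", "sgd", "pubmed"}
    assert len(refs) == 3
    quals = {r.database: r.qualifier for r in refs}
    assert quals["pubmed"] == "isDescribedBy"


def test_degenerate_single_species_document():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
      <model id="tiny">
        <listOfCompartments><compartment id="c"/></listOfCompartments>
        <listOfSpecies><species id="s1" compartment="c"/></listOfSpecies>
      </model>
    </sbml>"""
    m = read_sbml(doc)
    assert model_stats(m).as_dict() == {
        "reactions": 0, "metabolites": 1, "proteins": 0, "compartments": 1,
    }


def test_empty_model_roundtrip():
    back = read_sbml(write_sbml(Model(id="void")))
    assert model_stats(back) == model_stats(Model())


def test_urn_miriam_resources_are_read():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
      <model id="urn_style">
        <listOfCompartments><compartment id="c"/></listOfCompartments>
        <listOfSpecies>
          <species id="atp" compartment="c" metaid="meta_atp">
            <annotation><rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
              xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
              <rdf:Description rdf:about="#meta_atp"><bqbiol:is><rdf:Bag>
                <rdf:li rdf:resource="urn:miriam:chebi:CHEBI%3A15422"/>
              </rdf:Bag></bqbiol:is></rdf:Description>
            </rdf:RDF></annotation>
          </species>
        </listOfSpecies>
      </model>
    </sbml>"""
    m = read_sbml(doc)
    (ref,) = m.metabolites["atp"].refs
    assert (ref.database, ref.identifier) == ("chebi", "CHEBI:15422")


def test_malformed_xml_reports_line():
    with pytest.raises(SbmlReadError, match="line"):
        read_sbml("<sbml><model></sbml>")


def test_unsupported_level_rejected():
    doc = """<?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
      <model id="l3"/>
    </sbml>"""
    with pytest.raises(UnsupportedDialectError):
        read_sbml(doc)


_DANGLING = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="broken">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies><species id="a" compartment="c"/></listOfSpecies>
    <listOfReactions>
      <reaction id="R" reversible="false">
        <listOfReactants><speciesReference species="a"/></listOfReactants>
        <listOfProducts><speciesReference species="ghost"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""


def test_dangling_reference_strict_vs_repair():
    with pytest.raises(ModelIntegrityError, match="ghost"):
        read_sbml(_DANGLING, strict=True)
    repaired = read_sbml(_DANGLING, strict=False)
    assert "ghost" in repaired.metabolites


def test_write_refuses_invalid_model(toy1):
    toy1.reactions["R1"].stoich["phantom"] = 1.0
    with pytest.raises(ModelIntegrityError, match="phantom"):
        write_sbml(toy1)
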