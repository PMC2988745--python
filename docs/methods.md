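# Methods

This note records the scientific conventions, defaults and design choices
behind `gsmaudit`, and what the synthetic test bed does and does not show
about real reconstructions.

## Model representation and SBML conventions

A model is a set of compartments, annotated metabolites, gene products and an
ordered collection of reactions. Annotations are MIRIAM triples
`(database, identifier, qualifier)`; on disk they travel as RDF CV terms with
`identifiers.org` resource URIs (legacy `urn:miriam:` URNs are also read).
Qualifiers outside the standard biology-qualifier vocabulary are coerced to
`is` on write; this is the one place round-tripping is lossy, accepted because
the qualifier vocabulary in practice is closed.

Flux bounds ride the legacy constraint-based convention of
`LOWER_BOUND`/`UPPER_BOUND` kinetic-law parameters, which keeps the emitted
files readable by the wider constraint-based tool family. When a document
gives only a reversible flag, defaults are lb = −1000, ub = 1000
(reversible) and lb = 0, ub = 1000 (irreversible), in mmol·gDW⁻¹·h⁻¹; on
load, reversibility is re-derived from lb < 0 so the two encodings can never
disagree. Gene associations are written both as a `GENE_ASSOCIATION:` boolean
string in reaction notes and as modifier species references; on read the
notes string wins (it carries AND/OR structure) and bare modifiers are
interpreted as an OR. Gene-product species carry the polypeptide SBO term
(`SBO:0000252`); because SBML Level 2 Version 1 predates the `sboTerm`
attribute, the l2v1 dialect carries all SBO terms in notes (`SBO: ...`)
instead, and the reader accepts either location. Biomass-type
pseudo-reactions are recognised by a configurable SBO term set (default
`SBO:0000629`, `SBO:0000395`, `SBO:0000628`), since the exact term varies
between model generations.

## Decompartmentalisation

Metabolites merge when they share a ChEBI reference, else when their
case-insensitive, compartment-suffix-stripped names match; boundary species
only merge with other boundary species (a biomass sink must never collapse
into its precursor pool). Reactions whose merged stoichiometry cancels
(pure transport) are dropped; reactions identical in merged stoichiometry,
reversibility and canonical GPR collapse to one, pooling their evidence.
The operation is idempotent and can only decrease entity counts. Protein
counts include a gene iff it appears in the GPR of at least one non-pseudo
reaction, so enzymes whose only reaction disappears in the merge (e.g. pure
transporters) stop counting — the count reflects enzymes with at least one
surviving reaction.

## Connectivity audit

Traversal fires a reaction when *any* substrate is reachable (pure graph
connectivity); reversible reactions are traversed in both directions, and
boundary species are treated as always available. The alternative *all*
substrates rule is exposed (`--semantics all`) because published connectivity
tables do not always state their convention. Medium constituents are the
only seeds; currency metabolites are not excluded, as no principled exclusion
list exists. Unreachable metabolites are clustered by weak connectivity
(shared reaction), matching the visual notion of a disconnected blob.
Internal means non-boundary throughout; the report's "intracellular" row
additionally excludes the extracellular compartment, which is detected from
exchange-reaction participants and conventional compartment names.

Reconnection impact grants one cluster member a hypothetical source reaction
and counts newly reachable metabolites plus newly unblocked reactions. Which
member is granted the source is a genuine free choice; the implementation
evaluates the cheap graph part for every member and takes the best, then runs
the LP part only for that member and only over the previously blocked
reactions — sound because adding a source relaxes the flux cone, so an
unblocked reaction can never become blocked.

## Flux analysis

LPs are solved with HiGHS (`scipy.optimize.linprog`), primal feasibility
tolerance 10⁻⁹. Blocked-reaction classification uses |min| and |max| ≤ 10⁻⁶
(configurable) so it is robust to solver noise, and runs *without* a growth
constraint: blockage is a structural property of stoichiometry and bounds,
not of any objective. For reactions that cannot go negative a single
maximisation suffices, which roughly halves the FVA cost of a blocked scan.
Exchange reactions are identified structurally (at most one non-boundary
participant, pseudo-reactions excluded); under a medium, the exchange of each
medium species gets lb = −uptake and every other exchange lb = 0, leaving
secretion open. Optimal flux vectors are never compared between
implementations — LP degeneracy makes them non-unique; only objective
values, ranges and zero/nonzero classifications are treated as canonical.

## Knockout screening

Deletions act through the GPR rules only; an empty rule means the reaction
can never be knocked out. A gene appearing in no rule is screened (growth
equals wild type bitwise, no LP solved) and flagged as unassigned, surfacing
the enzymes a reconstruction has not yet placed. The lethality threshold is
relative (default 1% of wild-type growth): a relative cutoff is invariant
under uniform rescaling of all bounds, which an absolute cutoff is not.
Double deletions are supported for isozyme-redundancy analysis. In the
confusion matrix, positive = predicted viable; experimental genes absent
from the screen are excluded and counted, never silently dropped.

## Synthetic generator

The generator emulates the structural classes an audit must detect, not the
biochemistry of any organism: a unit-stoichiometry backbone from one nutrient
exchange to a biomass drain, with planted orphan clusters (chains with an
unproducible head, feeding the backbone), dead-end branches, and chain steps
catalysed by single genes, OR-pairs, AND-complexes or duplicated parallel
reactions. Unit coefficients make every expected flux analytic: wild-type
growth equals the uptake bound (default 10 mmol·gDW⁻¹·h⁻¹). Planted classes
never overlap, keeping the ground truth unambiguous, and all randomness
(feature placement, attachment points) comes from one seeded stream in a
fixed documented order, so a seed maps to byte-identical SBML.

Default sizes produce a reconstruction-scale network — 1102 reactions over
758 intracellular metabolites with 75 unreachable metabolites (9.9%) in 25
clusters and 140 blocked reactions (12.7%) — the connectivity profile of a
well-curated genome-scale yeast network, so scale behaviour is exercised at
realistic proportions. What passing on such models does *not* show: real
reconstructions have non-unit stoichiometry, currency-metabolite hubs, broad
degree distributions and compartmental transport; the generator probes the
audit logic, not robustness to those features. Scope counts of real curated
networks can only be checked against their actual SBML distributions
(see `tests/test_acceptance.py`, which documents a drop-in path for them).

Tests cross-check FBA against exhaustive vertex enumeration of the flux
polytope (models ≤ 8 reactions) and both FBA and the blocked classification
against the cobra toolbox (GLPK), an implementation disjoint from the
scipy/HiGHS path used here.

## Numerical and degenerate-input choices

- lb > ub is reported as `infeasible` without invoking the solver.
- Knockouts that render the LP infeasible score growth 0 (with all-zero
  feasible wild type this does not occur, but tightened user bounds can).
- Ties in reconnection ranking break lexicographically on the smallest
  cluster member id; cluster lists sort by size then id, so all reports are
  deterministic.
- Metabolites incident to no reaction count as unreachable (no producer) but
  not as dead ends (they are neither produced nor consumed).
- An empty medium reaches nothing and a model with no internal metabolites
  has fraction-reachable 1 by convention.

## Known limitations

- SBML Level 3 (and its fbc package) is out of scope; Level 2 versions 1–4
  are read, versions 1 and 4 written.
- No gap-filling: the tool ranks reconnection targets, a curator fixes them.
- No regulation: transcriptional repression (the classic reason an isozyme
  fails to rescue a deletion in vivo) cannot be represented, so isozyme-rich
  networks over-predict viability by construction.
- No thermodynamic/loopless constraints and no parsimonious or quadratic
  knockout objectives.
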