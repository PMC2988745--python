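# gsmaudit

Auditing and validation of annotated genome-scale metabolic network
reconstructions.

Curated reconstructions — such as the community consensus networks of
*Saccharomyces cerevisiae* — are distributed as SBML Level 2 documents whose
species, reactions and enzymes carry MIRIAM-compliant RDF annotations
(ChEBI for metabolites, UniProt/SGD for gene products, PubMed for evidence).
Before such a network can support constraint-based modelling, a curator needs
to know: how large is it really (unique reactions/metabolites/proteins after
merging compartment duplicates), which parts are disconnected from the growth
medium, which reactions can never carry flux, where would gap-filling effort
pay off most, and does gene-deletion simulation agree with experimental
viability? `gsmaudit` answers each of these questions, for model curators and
constraint-based modellers.

## What it computes

**Scope.** Unique entity counts, optionally after *decompartmentalisation*:
metabolites that differ only by compartment (matched by shared ChEBI
reference, else by compartment-stripped name) are merged, transport reactions
thereby emptied are removed, and duplicated reactions are collapsed.

**Connectivity.** On the bipartite metabolite–reaction digraph, a metabolite
is *unreachable* if no traversal from the growth-medium constituents produces
it; unreachable metabolites are grouped into weakly connected clusters and
ranked by reconnection impact (how many metabolites and blocked reactions a
hypothetical source for the cluster would recover). *Dead-end* metabolites
are those only ever produced or only ever consumed.

**Flux analysis.** Flux balance analysis (FBA) solves

```
max  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub
```

where S is the stoichiometric matrix over internal metabolites, v the flux
vector (mmol·gDW⁻¹·h⁻¹) and c the indicator of the biomass pseudo-reaction,
which is located by its SBO annotation. Flux variability analysis (FVA)
minimises and maximises each vᵢ under the same constraints; a reaction whose
range is {0} is *blocked* — mass balancing alone forces it to zero flux.
Exchange fluxes are negative for uptake, positive for secretion.

**Knockout screening.** Each gene deletion is propagated through the boolean
gene–protein–reaction rules (AND = enzyme complex, OR = isozymes); reactions
whose rule evaluates false lose their flux bounds and growth is re-predicted
by FBA. Deletions are called lethal below 1% of wild-type growth (relative
threshold, configurable) and scored against an experimental lethal-gene list
in the convention where positive = predicted viable.

**Synthetic ground truth.** A seeded generator builds annotated models with
planted orphan clusters, dead-end branches, essential genes, isozyme pairs
and redundant routes, recording every planted feature, so the entire pipeline
is testable without any external model files.

## Worked example

Generate a small synthetic model with planted defects, then audit it:

```
$ gsmaudit synth --seed 42 --n-backbone 8 --n-isozyme-pairs 1 --n-complexes 1 \
    --n-parallel-routes 2 --n-orphan-clusters 2 --orphan-cluster-size 2 \
    --n-deadend-branches 2 --n-unused-genes 2 --out demo
$ gsmaudit audit --model demo/model.xml --medium demo/medium.tsv
intracellular_metabolites  unreachable  unreachable_pct  metabolic_reactions  zero_flux  zero_flux_pct
14                         4            28.6             18                   6          33.3
```

Of 14 intracellular metabolites, 4 (the two planted two-member orphan
clusters) cannot be reached from the medium, and 6 of 18 reactions (the two
orphan chains with their connectors, plus the two dead-end branches) can
never carry steady-state flux.

```
$ gsmaudit fba --model demo/model.xml --medium demo/medium.tsv
status      optimal
objective   10
```

Wild-type growth equals the nutrient uptake bound (10 mmol·gDW⁻¹·h⁻¹), as
expected for a unit-stoichiometry backbone. Screening all knockouts against
the generator's planted essential genes:

```
$ gsmaudit knockout --model demo/model.xml --medium demo/medium.tsv \
    --lethal demo/lethal.txt --json
...
"confusion_matrix": {
  "number_of_genes": 19,
  "true_positive_pct": 73.7,
  "true_negative_pct": 26.3,
  "false_positive_pct": 0.0,
  "false_negative_pct": 0.0,
  ...
}
```

All 5 planted essential genes are recovered as true negatives (predicted
lethal and lethal "in vivo"); isozyme-pair members and genes on redundant
parallel routes are correctly predicted viable.

To audit a real reconstruction, pass its SBML file and a medium TSV
(metabolite id, maximum uptake rate) to the same commands; `--objective auto`
finds the biomass reaction through its SBO annotation.

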