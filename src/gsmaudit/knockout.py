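"""Gene-deletion screening and scoring against experimental lethality.

For each deleted gene, every reaction whose GPR evaluates false loses its
flux capability (bounds pinned to zero) and growth is re-predicted by
FBA.  A deletion is called lethal when growth drops below a configurable
fraction of wild type.  Predictions are scored against an experimental
lethal-gene list in the 2x2 convention where POSITIVE means predicted
viable: a false positive is an in-silico knockout rescued by alternative
routing (e.g. an isozyme) that is lethal in vivo, and a false negative a
computational lethal that grows in vivo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .constraints import FluxProblem, build_flux_problem, solve_fba
from .core import Model
from .gpr import evaluate_gpr
from .medium import Medium

logger = logging.getLogger(__name__)

__all__ = [
    "KnockoutScreenResult",
    "ConfusionMatrix",
    "KnockoutError",
    "single_gene_deletion",
    "double_gene_deletion",
    "classify_viability",
    "confusion_matrix",
    "read_lethal_list",
]

VIABILITY_THRESHOLD = 0.01


class KnockoutError(RuntimeError):
    """The screen cannot run (wild type infeasible or not growing)."""


@dataclass
class KnockoutScreenResult:
    wildtype_growth: float
    growth: dict[str, float] = field(default_factory=dict)
    #: genes present in the model but appearing in no GPR (screened, trivially viable)
    unassigned_genes: set[str] = field(default_factory=set)


@dataclass
class ConfusionMatrix:
    """Counts with positive = predicted viable; percentages over screened genes."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def _pct(self, k: int) -> float:
        return 100.0 * k / self.n if self.n else 0.0

    @property
    def tp_pct(self) -> float:
        return self._pct(self.tp)

    @property
    def tn_pct(self) -> float:
        return self._pct(self.tn)

    @property
    def fp_pct(self) -> float:
        return self._pct(self.fp)

    @property
    def fn_pct(self) -> float:
        return self._pct(self.fn)

    def as_dict(self) -> dict:
        return {
            "number_of_genes": self.n,
            "true_positive_pct": round(self.tp_pct, 1),
            "true_negative_pct": round(self.tn_pct, 1),
            "false_positive_pct": round(self.fp_pct, 1),
            "false_negative_pct": round(self.fn_pct, 1),
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "excluded_experimental_genes": self.n_excluded,
        }


def _deletion_growth(
    model: Model, problem: FluxProblem, deleted: set[str], wildtype: float
) -> float:
    """Growth after pinning to zero every reaction disabled by ``deleted``."""
    affected = [
        rxn.id
        for rxn in model.reactions.values()
        if rxn.gpr is not None
        and (rxn.genes() & deleted)
        and not evaluate_gpr(rxn.gpr, deleted)
    ]
    if not affected:
        return wildtype  # nothing disabled: growth unchanged, exactly
    ko = problem.copy()
    for rid in affected:
        j = ko.column(rid)
        ko.lb[j] = 0.0
        ko.ub[j] = 0.0
    res = solve_fba(ko)
    if res.status != "optimal":
        return 0.0  # a fully pinned cone that lost feasibility cannot grow
    return max(res.objective, 0.0)


def single_gene_deletion(
    model: Model,
    medium: Medium,
    objective: str,
    genes: Optional[Iterable[str]] = None,
) -> KnockoutScreenResult:
    """FBA growth prediction for every single-gene deletion.

    Reactions with an empty GPR are never disabled.  Genes in no GPR are
    screened too (growth equals wild type exactly) and surfaced in
    ``unassigned_genes``.  Refuses to run when the wild type does not
    grow — the screen would be meaningless.
    """
    problem = build_flux_problem(model, medium, objective)
    wt = solve_fba(problem)
    if wt.status != "optimal":
        raise KnockoutError(f"wild-type FBA is {wt.status}; cannot screen knockouts")
    if wt.objective <= 0:
        raise KnockoutError(
            f"wild-type growth is {wt.objective:g}; check medium and objective"
        )

    assigned: set[str] = set()
    for rxn in model.reactions.values():
        assigned |= rxn.genes()
    targets = sorted(genes) if genes is not None else sorted(model.genes)

    result = KnockoutScreenResult(wildtype_growth=wt.objective)
    result.unassigned_genes = {g for g in targets if g not in assigned}
    for gene in targets:
        result.growth[gene] = _deletion_growth(model, problem, {gene}, wt.objective)
    return result


def double_gene_deletion(
    model: Model,
    medium: Medium,
    objective: str,
    pairs: Iterable[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Growth after deleting gene pairs (for isozyme redundancy analysis)."""
    problem = build_flux_problem(model, medium, objective)
    wt = solve_fba(problem)
    if wt.status != "optimal" or wt.objective <= 0:
        raise KnockoutError("wild type does not grow; cannot screen double knockouts")
    return {
        (a, b): _deletion_growth(model, problem, {a, b}, wt.objective)
        for a, b in pairs
    }


def classify_viability(
    result: KnockoutScreenResult, threshold: float = VIABILITY_THRESHOLD
) -> dict[str, str]:
    """Call each deletion viable or lethal.

    Lethal iff growth < threshold × wild-type growth.  The threshold is
    relative so the call is invariant under uniform rescaling of all flux
    bounds.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"viability threshold must be in (0, 1), got {threshold}")
    if result.wildtype_growth <= 0:
        raise KnockoutError("wild-type growth must be positive to classify viability")
    cut = threshold * result.wildtype_growth
    return {
        g: ("lethal" if growth < cut else "viable")
        for g, growth in result.growth.items()
    }


def confusion_matrix(
    predictions: dict[str, str],
    experimental_lethal: set[str],
    screened: Optional[set[str]] = None,
) -> ConfusionMatrix:
    """Score predicted viability against an experimental lethal set.

    Experimental genes absent from the screen are logged, excluded and
    counted in ``n_excluded``.
    """
    if screened is None:
        screened = set(predictions)
    missing = screened - set(predictions)
    if missing:
        raise ValueError(f"screened genes without predictions: {sorted(missing)[:5]}")
    excluded = experimental_lethal - set(predictions)
    if excluded:
        logger.warning(
            "%d experimental lethal genes absent from the screen: %s",
            len(excluded), ", ".join(sorted(excluded)[:10]),
        )
    tp = tn = fp = fn = 0
    for gene in screened:
        viable = predictions[gene] == "viable"
        lethal_in_vivo = gene in experimental_lethal
        if viable and not lethal_in_vivo:
            tp += 1
        elif not viable and lethal_in_vivo:
            tn += 1
        elif viable and lethal_in_vivo:
            fp += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, n_excluded=len(excluded))


def read_lethal_list(path) -> set[str]:
    """One gene id per line; '#' starts a comment."""
    genes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return genes
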