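"""Report assembly: TSV and JSON renderings of every audit stage.

Sign convention note carried in every flux report header: exchange flux
negative = uptake, positive = secretion.
"""

from __future__ import annotations

import json

from .connectivity import ConnectivityReport
from .constraints import FvaResult
from .core import Model, ScopeStats, external_compartments
from .knockout import ConfusionMatrix, KnockoutScreenResult

__all__ = [
    "stats_tsv",
    "stats_json",
    "audit_summary",
    "audit_tsv",
    "audit_json",
    "fva_tsv",
    "fva_json",
    "knockout_tsv",
    "knockout_json",
]


def stats_tsv(stats: dict[str, ScopeStats]) -> str:
    """Scope table, one row per model variant (as-is, decompartmentalised)."""
    lines = ["variant\treactions\tmetabolites\tproteins\tcompartments"]
    for variant, s in stats.items():
        lines.append(
            f"{variant}\t{s.n_reactions}\t{s.n_metabolites}\t{s.n_proteins}\t{s.n_compartments}"
        )
    return "\n".join(lines) + "\n"


def stats_json(stats: dict[str, ScopeStats]) -> str:
    return json.dumps({k: v.as_dict() for k, v in stats.items()}, indent=2)


def n_intracellular(model: Model) -> int:
    """Internal metabolites excluding the extracellular compartment."""
    ext = external_compartments(model)
    return sum(
        1
        for m in model.metabolites.values()
        if not m.is_boundary and m.compartment not in ext
    )


def audit_summary(
    model: Model, report: ConnectivityReport, blocked: set[str]
) -> dict:
    """Connectivity summary in the canonical audit-table layout."""
    n_intra = n_intracellular(model)
    ext = external_compartments(model)
    unreachable_intra = [
        m
        for c in report.unreachable_clusters
        for m in c
        if model.metabolites[m].compartment not in ext
    ]
    n_rxn = len(model.reactions)
    return {
        "intracellular_metabolites": n_intra,
        "unreachable": len(unreachable_intra),
        "unreachable_pct": round(100.0 * len(unreachable_intra) / n_intra, 1)
        if n_intra else 0.0,
        "metabolic_reactions": n_rxn,
        "zero_flux": len(blocked),
        "zero_flux_pct": round(100.0 * len(blocked) / n_rxn, 1) if n_rxn else 0.0,
        "fraction_reachable": round(report.fraction_reachable, 4),
    }


def audit_tsv(summary: dict) -> str:
    keys = [
        "intracellular_metabolites", "unreachable", "unreachable_pct",
        "metabolic_reactions", "zero_flux", "zero_flux_pct",
    ]
    header = "\t".join(keys)
    row = "\t".join(str(summary[k]) for k in keys)
    return header + "\n" + row + "\n"


def audit_json(
    model: Model,
    report: ConnectivityReport,
    blocked: set[str],
    ranking: list[tuple[frozenset[str], int]] | None = None,
) -> str:
    payload = {
        "summary": audit_summary(model, report, blocked),
        "reachable": sorted(report.reachable),
        "unreachable_clusters": [sorted(c) for c in report.unreachable_clusters],
        "dead_end_metabolites": sorted(report.dead_ends),
        "zero_flux_reactions": sorted(blocked),
    }
    if ranking is not None:
        payload["reconnection_ranking"] = [
            {"cluster": sorted(c), "impact": impact} for c, impact in ranking
        ]
    return json.dumps(payload, indent=2)


_FLUX_HEADER = "# flux sign convention: negative = uptake, positive = secretion\n"


def fva_tsv(fva: FvaResult, blocked: set[str]) -> str:
    lines = [_FLUX_HEADER + "reaction\tmin_flux\tmax_flux\tblocked"]
    for rid, (lo, hi) in sorted(fva.ranges.items()):
        lines.append(f"{rid}\t{lo:.6g}\t{hi:.6g}\t{'yes' if rid in blocked else 'no'}")
    return "\n".join(lines) + "\n"


def fva_json(fva: FvaResult, blocked: set[str]) -> str:
    return json.dumps(
        {
            "sign_convention": "negative = uptake, positive = secretion",
            "status": fva.status,
            "ranges": {r: list(v) for r, v in sorted(fva.ranges.items())},
            "zero_flux_reactions": sorted(blocked),
            "zero_flux_count": len(blocked),
        },
        indent=2,
    )


def knockout_tsv(
    screen: KnockoutScreenResult,
    predictions: dict[str, str],
    experimental_lethal: set[str] | None = None,
) -> str:
    lines = [_FLUX_HEADER + "gene\tgrowth\tpredicted\texperimental\tclass\tunassigned"]
    for gene in sorted(screen.growth):
        pred = predictions[gene]
        if experimental_lethal is None:
            exp = cls = "NA"
        else:
            exp = "lethal" if gene in experimental_lethal else "viable"
            viable = pred == "viable"
            lethal_in_vivo = gene in experimental_lethal
            cls = ("TP" if viable and not lethal_in_vivo
                   else "TN" if not viable and lethal_in_vivo
                   else "FP" if viable else "FN")
        una = "yes" if gene in screen.unassigned_genes else "no"
        lines.append(f"{gene}\t{screen.growth[gene]:.6g}\t{pred}\t{exp}\t{cls}\t{una}")
    return "\n".join(lines) + "\n"


def knockout_json(
    screen: KnockoutScreenResult,
    predictions: dict[str, str],
    matrix: ConfusionMatrix | None = None,
) -> str:
    payload = {
        "wildtype_growth": screen.wildtype_growth,
        "growth": {g: screen.growth[g] for g in sorted(screen.growth)},
        "predicted": {g: predictions[g] for g in sorted(predictions)},
        "unassigned_genes": sorted(screen.unassigned_genes),
    }
    if matrix is not None:
        payload["confusion_matrix"] = matrix.as_dict()
    return json.dumps(payload, indent=2)
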