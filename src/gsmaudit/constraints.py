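"""Constraint-based analysis: FBA, FVA and blocked-reaction detection.

The steady-state flux cone is ``{v : S·v = 0, lb <= v <= ub}`` with S the
stoichiometric matrix over internal (non-boundary) metabolites.  Flux
balance analysis maximises an objective ``c·v`` (typically the biomass
pseudo-reaction) over that cone; flux variability analysis minimises and
maximises each individual flux, optionally while holding the objective at
a fraction of its optimum.  A reaction whose attainable range is {0} is
blocked: mass balancing alone — most often a dead-end metabolite — forces
it to zero flux regardless of objective.

Exchange fluxes follow the dominant sign convention: negative = uptake,
positive = secretion.  Linear programs are solved with HiGHS through
scipy.  Flux vectors at the optimum are not unique (LP degeneracy); only
objective values, ranges and zero/nonzero classifications are canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .core import Model, exchange_reactions
from .medium import Medium, MediumError

__all__ = [
    "FluxProblem",
    "FluxResult",
    "FvaResult",
    "FEASIBILITY_TOL",
    "BLOCKED_TOL",
    "build_flux_problem",
    "solve_fba",
    "flux_variability",
    "blocked_reactions",
]

FEASIBILITY_TOL = 1e-9
BLOCKED_TOL = 1e-6


@dataclass
class FluxProblem:
    """S·v = 0 with per-reaction bounds and a linear objective."""

    S: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self):
        n_rows, n_cols = self.S.shape
        if not (len(self.row_ids) == n_rows and len(self.col_ids) == n_cols
                and len(self.lb) == len(self.ub) == len(self.c) == n_cols):
            raise ValueError("inconsistent FluxProblem dimensions")

    def column(self, reaction_id: str) -> int:
        return self.col_ids.index(reaction_id)

    def copy(self) -> "FluxProblem":
        return FluxProblem(self.S.copy(), self.lb.copy(), self.ub.copy(),
                           self.c.copy(), list(self.row_ids), list(self.col_ids))


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded | failed
    objective: float
    v: Optional[np.ndarray] = None


@dataclass
class FvaResult:
    """Per-reaction attainable flux ranges (min, max)."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    status: str = "optimal"


def build_flux_problem(
    model: Model, medium: Medium, objective: Optional[str]
) -> FluxProblem:
    """Assemble the stoichiometric LP for a model under a growth medium.

    Rows cover internal (non-boundary) metabolites only.  The exchange
    reaction of each medium species gets ``lb = -uptake``; every other
    exchange gets ``lb = 0`` (no uptake, secretion still allowed).
    ``objective`` may be ``None`` for structural analyses that need no
    objective (the c vector is then all zero).
    """
    medium.validate(model)
    rows = model.internal_metabolites()
    row_index = {m: i for i, m in enumerate(rows)}
    cols = list(model.reactions)
    col_index = {r: j for j, r in enumerate(cols)}
    if objective is not None and objective not in col_index:
        raise KeyError(f"objective reaction {objective!r} not in model")

    data, ri, ci = [], [], []
    lb = np.zeros(len(cols))
    ub = np.zeros(len(cols))
    for j, rid in enumerate(cols):
        rxn = model.reactions[rid]
        lb[j], ub[j] = rxn.lb, rxn.ub
        for mid, coef in rxn.stoich.items():
            i = row_index.get(mid)
            if i is not None:
                data.append(coef)
                ri.append(i)
                ci.append(j)
    S = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), len(cols)))

    exchanges = exchange_reactions(model)
    # map each medium species to its exchange column
    species_exchange: dict[str, str] = {}
    for rid in exchanges:
        for mid in model.reactions[rid].stoich:
            if not model.metabolites[mid].is_boundary:
                species_exchange.setdefault(mid, rid)
    for rid in exchanges:
        lb[col_index[rid]] = max(lb[col_index[rid]], 0.0)
    for mid, rate in medium.uptake.items():
        rid = species_exchange.get(mid)
        if rid is None:
            raise MediumError(f"medium species {mid} has no exchange reaction")
        lb[col_index[rid]] = -rate

    c = np.zeros(len(cols))
    if objective is not None:
        c[col_index[objective]] = 1.0
    return FluxProblem(S, lb, ub, c, rows, cols)


def _linprog(problem: FluxProblem, c_min: np.ndarray,
             extra_A=None, extra_b=None) -> scipy.optimize.OptimizeResult:
    return scipy.optimize.linprog(
        c_min,
        A_eq=problem.S,
        b_eq=np.zeros(problem.S.shape[0]),
        A_ub=extra_A,
        b_ub=extra_b,
        bounds=np.column_stack([problem.lb, problem.ub]),
        method="highs",
        options={"primal_feasibility_tolerance": max(FEASIBILITY_TOL, 1e-10)},
    )


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def solve_fba(problem: FluxProblem) -> FluxResult:
    """Maximise c·v over the flux cone.

    The objective value is canonical; the flux vector is one optimum among
    possibly many.  Infeasibility and unboundedness are reported in
    ``status``, never as a silent zero.
    """
    if np.any(problem.lb > problem.ub):
        return FluxResult("infeasible", float("nan"))
    res = _linprog(problem, -problem.c)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxResult(status, float("nan"))
    return FluxResult("optimal", float(problem.c @ res.x), res.x)


def flux_variability(
    problem: FluxProblem,
    fraction_of_optimum: Optional[float] = None,
    reactions: Optional[list[str]] = None,
) -> FvaResult:
    """Min and max attainable flux per reaction.

    With ``fraction_of_optimum`` given, the constraint
    ``c·v >= fraction × FBA optimum`` is added first.  ``reactions``
    restricts the sweep (default: every column).
    """
    extra_A = extra_b = None
    if fraction_of_optimum is not None:
        if not 0.0 <= fraction_of_optimum <= 1.0:
            raise ValueError("fraction_of_optimum must be in [0, 1]")
        wt = solve_fba(problem)
        if wt.status != "optimal":
            return FvaResult(status=wt.status)
        extra_A = sp.csr_matrix(-problem.c.reshape(1, -1))
        extra_b = np.array([-fraction_of_optimum * wt.objective])
    if np.any(problem.lb > problem.ub):
        return FvaResult(status="infeasible")

    targets = reactions if reactions is not None else problem.col_ids
    n = len(problem.col_ids)
    result = FvaResult()
    ind = np.zeros(n)
    for rid in targets:
        j = problem.column(rid)
        ind[:] = 0.0
        ind[j] = 1.0
        lo = _linprog(problem, ind, extra_A, extra_b)
        hi = _linprog(problem, -ind, extra_A, extra_b)
        if lo.status != 0 or hi.status != 0:
            status = _STATUS.get(lo.status if lo.status != 0 else hi.status, "failed")
            return FvaResult(status=status)
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        result.ranges[rid] = (min(vmin, vmax), max(vmin, vmax))
    return result


def blocked_reactions(
    problem: FluxProblem,
    tol: float = BLOCKED_TOL,
    reactions: Optional[list[str]] = None,
) -> set[str]:
    """Reactions that mass balancing forces to zero flux.

    Classification runs without any growth constraint: blockage is a
    structural property of the stoichiometry and bounds, independent of
    the objective.  A reaction is blocked iff its FVA range satisfies
    ``|min| <= tol`` and ``|max| <= tol``.  For reactions that cannot go
    negative (``lb >= -tol``) a single maximisation suffices.
    """
    if np.any(problem.lb > problem.ub):
        raise ValueError("problem has lb > ub; no feasible flux cone")
    targets = reactions if reactions is not None else problem.col_ids
    blocked: set[str] = set()
    n = len(problem.col_ids)
    ind = np.zeros(n)
    for rid in targets:
        j = problem.column(rid)
        ind[:] = 0.0
        ind[j] = 1.0
        hi = _linprog(problem, -ind)
        if hi.status != 0 or abs(hi.x[j]) > tol:
            continue
        if problem.lb[j] >= -tol:  # flux cannot be meaningfully negative
            blocked.add(rid)
            continue
        lo = _linprog(problem, ind)
        if lo.status == 0 and abs(lo.x[j]) <= tol:
            blocked.add(rid)
    return blocked
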