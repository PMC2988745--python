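"""Independent oracles used by the test suite.

``fba_by_vertex_enumeration`` maximises c·v over {S·v = 0, lb <= v <= ub}
by enumerating candidate vertices of the flux polytope directly (fix
n - rank(S) variables at a bound, solve for the rest), with no linear
programming involved.  ``to_cobra``/``cobra_*`` route the same problem
through the cobra toolbox (GLPK via optlang), an implementation wholly
separate from the package's scipy/HiGHS path.
"""

import itertools

import numpy as np

from gsmaudit.core import exchange_reactions


def fba_by_vertex_enumeration(S, lb, ub, c, atol=1e-8):
    """Exhaustive optimum of max c·v over the bounded flux polytope.

    Returns the best objective value, or None if no feasible vertex exists.
    Only practical for a handful of reactions.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(lb)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free] if free else None
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # underdetermined: this vertex surfaces via another choice
        for vals in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(vals) if fixed else np.zeros(S.shape[0])
            v = np.empty(n)
            v[list(fixed)] = vals
            if free:
                sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
                if not np.allclose(A @ sol, rhs, atol=atol):
                    continue
                v[free] = sol
            elif not np.allclose(rhs, 0.0, atol=atol):
                continue
            if (np.all(v >= lb - atol) and np.all(v <= ub + atol)
                    and np.allclose(S @ v, 0.0, atol=atol)):
                obj = float(c @ v)
                if best is None or obj > best:
                    best = obj
    return best


def to_cobra(model, medium, objective):
    """Rebuild the flux problem inside the cobra toolbox."""
    import cobra

    internal = set(model.internal_metabolites())
    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m) for m in internal}
    cm.add_reactions([_cobra_reaction(r) for r in model.reactions.values()])
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: coef for m, coef in rxn.stoich.items() if m in internal}
        )
    species_ex = {}
    for rid in exchange_reactions(model):
        cr = cm.reactions.get_by_id(rid)
        cr.lower_bound = max(cr.lower_bound, 0.0)
        for mid in model.reactions[rid].stoich:
            if mid in internal:
                species_ex.setdefault(mid, rid)
    for mid, rate in medium.uptake.items():
        cm.reactions.get_by_id(species_ex[mid]).lower_bound = -rate
    if objective is not None:
        cm.objective = cm.reactions.get_by_id(objective)
    return cm


def _cobra_reaction(rxn):
    import cobra

    r = cobra.Reaction(rxn.id)
    r.lower_bound, r.upper_bound = rxn.lb, rxn.ub
    return r


def cobra_fba(model, medium, objective):
    sol = to_cobra(model, medium, objective).optimize()
    return sol.status, sol.objective_value


def cobra_blocked(model, medium, tol=1e-6):
    """Blocked set via cobra's per-reaction min/max FVA."""
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model, medium, None)
    # dummy objective: an irreversible reaction, so the fraction-0 constraint
    # (objective >= 0) that cobra adds is vacuous
    dummy = next(r for r in cm.reactions if r.lower_bound >= 0)
    cm.objective = dummy
    fva = flux_variability_analysis(cm, fraction_of_optimum=0.0)
    return set(fva[(fva.minimum.abs() <= tol) & (fva.maximum.abs() <= tol)].index)
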