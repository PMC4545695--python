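"""Independent oracles used by the test suite.

These deliberately avoid netreduce's own LP/kernel code paths: FVA-style
checks go through cobrapy with the GLPK solver, and feasibility checks used
by the exhaustive pruning search assemble their own linear programs.  They
are slow brute-force references, not alternative implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from cobra import Metabolite, Model, Reaction

EPS = 1e-6


def to_cobra(model) -> Model:
    """Translate a MetabolicModel into a cobrapy model (internal species only)."""
    cm = Model(model.name)
    mets = {mid: Metabolite(mid) for mid in model.metabolite_ids}
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = Reaction(rid)
        r.add_metabolites(
            {
                mets[mid]: float(model.S[i, j])
                for i, mid in enumerate(model.metabolite_ids)
                if model.S[i, j] != 0
            }
        )
        r.lower_bound = float(model.lower_bounds[j])
        r.upper_bound = float(model.upper_bounds[j])
        rxns.append(r)
    cm.add_reactions(rxns)
    cm.solver = "glpk"
    return cm


def cobra_flux_range(cm: Model, rid: str) -> tuple[float, float]:
    """[min, max] flux of one reaction via two GLPK optimisations."""
    out = []
    for sense in ("minimize", "maximize"):
        with cm as tmp:
            tmp.objective = rid
            tmp.objective_direction = sense
            sol = tmp.optimize()
            assert sol.status == "optimal", (rid, sense, sol.status)
            out.append(sol.objective_value)
    return out[0], out[1]


def cobra_blocked(model) -> set[str]:
    """Blocked reactions via per-reaction min/max GLPK solves."""
    cm = to_cobra(model)
    blocked = set()
    for rid in model.reaction_ids:
        lo, hi = cobra_flux_range(cm, rid)
        if abs(lo) <= EPS and abs(hi) <= EPS:
            blocked.add(rid)
    return blocked


def cobra_subset_partner(model, rid_i: str, rid_j: str) -> float | None:
    """FVA-fixing subset oracle: fix r_i at a feasible nonzero value and
    report r_j / r_i if r_j's range collapses to a point, else None."""
    cm = to_cobra(model)
    lo, hi = cobra_flux_range(cm, rid_i)
    v = hi if abs(hi) > EPS else lo
    if abs(v) <= EPS:
        return None  # r_i blocked: no ratio defined
    with cm as tmp:
        rxn = tmp.reactions.get_by_id(rid_i)
        rxn.lower_bound = rxn.upper_bound = v
        jlo, jhi = cobra_flux_range(tmp, rid_j)
    if abs(jhi - jlo) <= 1e-6 * max(1.0, abs(jhi)):
        return (0.5 * (jlo + jhi)) / v
    return None


# ---------------------------------------------------------------------------
# plain-linprog feasibility, assembled independently of netreduce.lp


def scenario_feasible(model, scenario, deleted: frozenset[str] = frozenset()) -> bool:
    """Is a scenario feasible after deleting the given reactions?"""
    keep = [j for j, r in enumerate(model.reaction_ids) if r not in deleted]
    S = model.S[:, keep]
    lb = model.lower_bounds[keep].copy()
    ub = model.upper_bounds[keep].copy()
    idx = {model.reaction_ids[j]: k for k, j in enumerate(keep)}
    A_ub, b_ub = [], []
    if scenario is not None:
        for rid, (lo, hi) in scenario.bound_overrides.items():
            if rid in idx:
                lb[idx[rid]], ub[idx[rid]] = lo, hi
        for con in scenario.constraints:
            row = np.zeros(len(keep))
            for rid, coef in con.coefs:
                if rid not in idx:
                    if coef != 0:
                        # constrained reaction deleted: it contributes 0
                        pass
                    continue
                row[idx[rid]] = coef
            A_ub.append(row)
            b_ub.append(con.rhs)
    res = linprog(
        np.zeros(len(keep)),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=list(zip(np.maximum(lb, -1e7), np.minimum(ub, 1e7))),
        method="highs",
    )
    return res.status == 0


def can_carry_flux(model, rid: str, scenarios, deleted: frozenset[str]) -> bool:
    keep = [j for j, r in enumerate(model.reaction_ids) if r not in deleted]
    if rid in deleted:
        return False
    idx = {model.reaction_ids[j]: k for k, j in enumerate(keep)}
    scen_list = list(scenarios) if scenarios else [None]
    for sc in scen_list:
        S = model.S[:, keep]
        lb = model.lower_bounds[keep].copy()
        ub = model.upper_bounds[keep].copy()
        A_ub, b_ub = [], []
        if sc is not None:
            for orid, (lo, hi) in sc.bound_overrides.items():
                if orid in idx:
                    lb[idx[orid]], ub[idx[orid]] = lo, hi
            for con in sc.constraints:
                row = np.zeros(len(keep))
                for crid, coef in con.coefs:
                    if crid in idx:
                        row[idx[crid]] = coef
                A_ub.append(row)
                b_ub.append(con.rhs)
        for sense in (-1.0, 1.0):
            c = np.zeros(len(keep))
            c[idx[rid]] = sense
            res = linprog(
                c,
                A_ub=np.array(A_ub) if A_ub else None,
                b_ub=np.array(b_ub) if b_ub else None,
                A_eq=S if S.shape[0] else None,
                b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
                bounds=list(zip(np.maximum(lb, -1e7), np.minimum(ub, 1e7))),
                method="highs",
            )
            if res.status == 0 and abs(res.fun) > EPS:
                return True
    return False


def _deletion_ok(model, spec, deleted: frozenset[str], rid: str) -> bool:
    """Would deleting *rid* (on top of *deleted*) keep the spec satisfied?"""
    if rid in spec.protected_reactions:
        return False
    new = deleted | {rid}
    n_left = model.n_reactions - len(new)
    if n_left < spec.n_min:
        return False
    keep = [j for j, r in enumerate(model.reaction_ids) if r not in new]
    S = model.S[:, keep]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    if n_left - rank < spec.dof_min:
        return False
    scen_list = spec.scenarios if spec.scenarios else [None]
    for sc in scen_list:
        if not scenario_feasible(model, sc, new):
            return False
    if spec.enforce_protected_feasibility:
        for prid in spec.protected_reactions:
            if not can_carry_flux(model, prid, spec.scenarios, new):
                return False
    for mid in spec.protected_metabolites:
        i = model.metabolite_ids.index(mid)
        touching = [
            model.reaction_ids[j]
            for j in np.nonzero(np.abs(model.S[i, :]) > 0)[0]
            if model.reaction_ids[j] not in new
        ]
        if not any(can_carry_flux(model, t, spec.scenarios, new) for t in touching):
            return False
    return True


def exhaustive_fixed_point_sizes(model, spec) -> set[int]:
    """Sizes of all terminal networks over every admissible deletion order.

    Brute-force recursion: from each state, try deleting every remaining
    non-protected reaction; a state where no deletion keeps the protection
    spec satisfied is terminal.  Exponential — tiny fixtures only.
    """
    terminal_sizes: set[int] = set()
    seen: set[frozenset[str]] = set()

    def recurse(deleted: frozenset[str]) -> None:
        if deleted in seen:
            return
        seen.add(deleted)
        candidates = [
            r
            for r in model.reaction_ids
            if r not in deleted and _deletion_ok(model, spec, deleted, r)
        ]
        if not candidates:
            terminal_sizes.add(model.n_reactions - len(deleted))
            return
        for r in candidates:
            recurse(deleted | {r})

    recurse(frozenset())
    return terminal_sizes
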