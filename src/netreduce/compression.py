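"""Loss-free network compression: lumping enzyme subsets.

An *enzyme subset* is a set of reactions whose steady-state fluxes are
always proportional; such a set can be collapsed into one overall reaction
without losing any feasible behaviour.  Detection is kernel-based: two
reactions belong to one subset iff their rows in a nullspace basis of S are
proportional.  The per-member flux ratios then define a transformation
matrix T with ``S_compressed = S · T`` (zero rows deleted), so the
compressed model is exact by construction and neither the degrees of
freedom nor the reachable phenotypes change.

Protected elements are kept: a lumped subset may absorb at most one
protected reaction, which becomes its representative and lends the lumped
reaction its identity (this is how the condensed biomass synthesis reaction
acquires the cumulative precursor/cofactor stoichiometry of the pathways
feeding it); two protected reactions are never merged, and protected
metabolites are never deleted even when their balance row becomes zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .model import MetabolicModel, ModelError, ProtectionSpec
from .lp import DEFAULT_CONFIG, LPConfig, dof as dof_of, nullspace

_PROP_TOL = 1e-8
_ZERO_ROW_TOL = 1e-10


@dataclass
class Subset:
    """One enzyme subset: members with flux ratios relative to the representative."""

    lumped_id: str
    representative: str
    members: list[tuple[str, float]]  # (reaction_id, rho); rho(representative)=1

    @property
    def member_ids(self) -> list[str]:
        return [rid for rid, _ in self.members]


@dataclass
class SubsetMap:
    """All subsets plus the global n_in x n_out transformation matrix T."""

    subsets: list[Subset]
    T: np.ndarray
    input_reactions: list[str]
    output_reactions: list[str]


@dataclass
class CompressedModel:
    """A compressed model plus the bookkeeping to expand fluxes back."""

    model: MetabolicModel
    subset_map: SubsetMap
    eliminated_metabolites: list[str]

    def expand_flux(self, v: np.ndarray) -> np.ndarray:
        """Map a compressed-model flux vector back to the input model (T @ v)."""
        return self.subset_map.T @ np.asarray(v, dtype=float)


def _snap_ratio(x: float) -> float:
    """Snap a ratio onto a nearby small rational (exact stoichiometries)."""
    frac = Fraction(x).limit_denominator(10**6)
    if abs(float(frac) - x) <= 1e-9 * max(1.0, abs(x)):
        return float(frac)
    return x


def _lump_name(member_ids: list[str]) -> str:
    joined = "*".join(member_ids)
    if len(joined) <= 60:
        return joined
    digest = hashlib.sha1(joined.encode()).hexdigest()[:8]
    return joined[:51] + "~" + digest


def _feasible_interval(
    model: MetabolicModel, members: list[tuple[str, float]]
) -> tuple[float, float]:
    """Representative-flux interval implied by all members' bounds."""
    lo, hi = -np.inf, np.inf
    for rid, rho in members:
        j = model.reaction_index(rid)
        a, b = model.lower_bounds[j] / rho, model.upper_bounds[j] / rho
        if rho < 0:
            a, b = b, a
        lo, hi = max(lo, a), min(hi, b)
    return lo, hi


def detect_subsets(
    model: MetabolicModel,
    protected: ProtectionSpec | None = None,
    config: LPConfig = DEFAULT_CONFIG,
) -> SubsetMap:
    """Find enzyme subsets of *model* from a kernel basis of S.

    Reactions with an all-zero kernel row (structurally blocked) are left as
    singletons.  Groups whose implied flux ratios would force an
    irreversible member backward are split by ratio sign.  Protected
    reactions join a lumped subset only as its (single) representative and
    only when that eliminates additional internal metabolites.
    """
    prot = protected.protected_reactions if protected else set()
    n = model.n_reactions
    K = nullspace(model, config)
    norms = np.linalg.norm(K, axis=1)
    scale = norms.max() if norms.size else 0.0
    active = [j for j in range(n) if norms[j] > _PROP_TOL * max(1.0, scale)]

    # union-find over pairwise proportionality of kernel rows
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ii, j1 in enumerate(active):
        for j2 in active[ii + 1 :]:
            cos = abs(K[j1] @ K[j2]) / (norms[j1] * norms[j2])
            if cos >= 1.0 - _PROP_TOL:
                parent[find(j2)] = find(j1)

    groups: dict[int, list[int]] = {}
    for j in active:
        groups.setdefault(find(j), []).append(j)

    subsets: list[Subset] = []
    lumped_members: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        subsets.extend(_form_subsets(model, K, members, prot))
    for s in subsets:
        lumped_members.update(s.member_ids)

    # build T: lumped columns first appear at their representative's position
    out_ids: list[str] = []
    columns: list[np.ndarray] = []
    by_rep = {model.reaction_index(s.representative): s for s in subsets}
    for j, rid in enumerate(model.reaction_ids):
        if rid in lumped_members and j not in by_rep:
            continue
        col = np.zeros(n)
        if j in by_rep:
            s = by_rep[j]
            for mid, rho in s.members:
                col[model.reaction_index(mid)] = rho
            out_ids.append(s.lumped_id)
        else:
            col[j] = 1.0
            out_ids.append(rid)
        columns.append(col)
    T = np.column_stack(columns) if columns else np.zeros((n, 0))
    return SubsetMap(subsets, T, list(model.reaction_ids), out_ids)


def _form_subsets(
    model: MetabolicModel,
    K: np.ndarray,
    members: list[int],
    prot: set[str],
) -> list[Subset]:
    """Turn one proportional class into sign-consistent, protection-aware subsets."""
    ids = [model.reaction_ids[j] for j in members]
    nonprot = [j for j in members if model.reaction_ids[j] not in prot]
    protected = [j for j in members if model.reaction_ids[j] in prot]
    if len(nonprot) == 0:
        return []

    support = (np.abs(model.S) > 0).sum(axis=0)

    def ratios_against(rep: int, mem: list[int]) -> list[tuple[str, float]]:
        denom = K[rep] @ K[rep]
        out = []
        for j in mem:
            rho = 1.0 if j == rep else _snap_ratio(float((K[j] @ K[rep]) / denom))
            out.append((model.reaction_ids[j], rho))
        return out

    def eliminated(mem: list[int]) -> int:
        mem_set = set(mem)
        count = 0
        for i in range(model.n_metabolites):
            touch = set(np.nonzero(np.abs(model.S[i, :]) > 0)[0])
            if touch and touch <= mem_set:
                count += 1
        return count

    # pick the lump membership: all non-protected, plus at most one protected
    # member when absorbing it eliminates additional internal metabolites
    lump = list(nonprot)
    chosen_prot: int | None = None
    if protected:
        base = eliminated(lump)
        best_gain = 0
        for p in sorted(protected):
            gain = eliminated(lump + [p]) - base
            if gain > best_gain:
                best_gain, chosen_prot = gain, p
        if chosen_prot is not None:
            lump = lump + [chosen_prot]
    if len(lump) < 2:
        return []

    # representative: the protected member if one was absorbed, else the
    # member with the largest stoichiometric support (ties: lowest index)
    if chosen_prot is not None:
        rep = chosen_prot
    else:
        rep = min(lump, key=lambda j: (-support[j], j))
    member_ratios = ratios_against(rep, sorted(lump))

    lo, hi = _feasible_interval(model, member_ratios)
    eps = DEFAULT_CONFIG.eps_flux
    if lo <= hi and not (abs(lo) <= eps and abs(hi) <= eps):
        s = _make_subset(model, rep, member_ratios, chosen_prot is not None)
        return [s] if s is not None else []

    # sign conflict (some irreversible member forced backward): split the
    # lump by ratio sign and retry each side
    pos = [(rid, rho) for rid, rho in member_ratios if rho > 0]
    neg = [(rid, rho) for rid, rho in member_ratios if rho < 0]
    out: list[Subset] = []
    for side in (pos, neg):
        if len(side) < 2:
            continue
        side_idx = [model.reaction_index(rid) for rid, _ in side]
        if chosen_prot in side_idx:
            rep2 = chosen_prot
        else:
            rep2 = min(side_idx, key=lambda j: (-support[j], j))
        ratios2 = ratios_against(rep2, sorted(side_idx))
        lo2, hi2 = _feasible_interval(model, ratios2)
        if lo2 > hi2:
            raise ModelError(
                f"empty flux interval for subset {[r for r, _ in ratios2]}"
            )
        if abs(lo2) <= eps and abs(hi2) <= eps:
            continue  # side can never carry flux; leave members unlumped
        s = _make_subset(model, rep2, ratios2, rep2 == chosen_prot)
        if s is not None:
            out.append(s)
    return out


def _net_column(
    model: MetabolicModel, member_ratios: list[tuple[str, float]]
) -> np.ndarray:
    """Ratio-weighted combined stoichiometry (internal + external rows)."""
    col = np.zeros(model.n_metabolites + len(model.external_species))
    full = np.vstack([model.S, model.S_ext]) if len(model.external_species) else model.S
    for rid, rho in member_ratios:
        col += rho * full[:, model.reaction_index(rid)]
    return col


def _make_subset(
    model: MetabolicModel,
    rep: int,
    member_ratios: list[tuple[str, float]],
    rep_is_protected: bool,
) -> Subset | None:
    # a lump whose net stoichiometry cancels completely (e.g. a perfect
    # internal cycle) cannot be represented as a reaction; leave its members
    # unlumped — still loss-free, and dof is untouched either way
    if np.abs(_net_column(model, member_ratios)).max() <= _ZERO_ROW_TOL:
        return None
    rep_id = model.reaction_ids[rep]
    if rep_is_protected:
        lumped_id = rep_id  # protected identity survives compression
    else:
        lumped_id = _lump_name([rid for rid, _ in member_ratios])
    return Subset(lumped_id, rep_id, member_ratios)


def compress(
    model: MetabolicModel,
    protected: ProtectionSpec | None = None,
    subset_map: SubsetMap | None = None,
    config: LPConfig = DEFAULT_CONFIG,
) -> CompressedModel:
    """Collapse every enzyme subset into one overall reaction.

    Each lumped column is the ratio-weighted sum of its members' columns
    (``S_out = S · T``); internal metabolites whose rows become all-zero are
    deleted (never protected ones); lumped bounds are the tightest interval
    implied by the members' bounds mapped through the ratios.  The result is
    loss-free: dof and all FBA optima are preserved.
    """
    if subset_map is None:
        subset_map = detect_subsets(model, protected, config)
    T = subset_map.T
    S_out = model.S @ T
    S_ext_out = model.S_ext @ T
    c_out = T.T @ model.objective

    lb, ub = [], []
    subset_by_lid = {s.lumped_id: s for s in subset_map.subsets}
    for out_id in subset_map.output_reactions:
        s = subset_by_lid.get(out_id)
        if s is not None and len(s.members) > 1:
            lo, hi = _feasible_interval(model, s.members)
            if lo > hi:
                raise ModelError(f"empty bound interval for subset {out_id!r}")
        else:
            j = model.reaction_index(out_id)
            lo, hi = model.lower_bounds[j], model.upper_bounds[j]
        lb.append(lo)
        ub.append(hi)

    keep_mets = protected.protected_metabolites if protected else set()
    scale = max(1.0, np.abs(S_out).max()) if S_out.size else 1.0
    nonzero_row = (np.abs(S_out) > _ZERO_ROW_TOL * scale).any(axis=1)
    rows = [
        i
        for i, mid in enumerate(model.metabolite_ids)
        if nonzero_row[i] or mid in keep_mets
    ]
    eliminated = [
        mid for i, mid in enumerate(model.metabolite_ids) if i not in set(rows)
    ]
    S_out = S_out[rows, :]
    S_out[np.abs(S_out) <= _ZERO_ROW_TOL * scale] = 0.0
    S_ext_out = S_ext_out.copy()
    if S_ext_out.size:
        S_ext_out[np.abs(S_ext_out) <= _ZERO_ROW_TOL * scale] = 0.0

    out = MetabolicModel(
        metabolite_ids=[model.metabolite_ids[i] for i in rows],
        reaction_ids=list(subset_map.output_reactions),
        S=S_out,
        lower_bounds=np.array(lb),
        upper_bounds=np.array(ub),
        objective=c_out,
        external_species=list(model.external_species),
        S_ext=S_ext_out,
        compartments={
            k: v for k, v in model.compartments.items() if k not in set(eliminated)
        },
        name=model.name + "_compressed",
    )
    return CompressedModel(out, subset_map, eliminated)


def condensed_bsr_report(
    model: MetabolicModel | CompressedModel,
    biomass_reaction: str,
) -> pd.DataFrame:
    """Signed stoichiometry of the (condensed) biomass synthesis reaction.

    Negative coefficients indicate consumption during biomass synthesis,
    positive production.  Rows are sorted by metabolite id and flagged
    internal/external, ready for side-by-side diffing of two models.
    """
    if isinstance(model, CompressedModel):
        model = model.model
    if biomass_reaction not in model.reaction_ids:
        raise ModelError(f"biomass reaction {biomass_reaction!r} not in model")
    coefs = model.reaction_stoichiometry(biomass_reaction)
    ext = set(model.external_species)
    rows = [
        {
            "metabolite": mid,
            "coefficient": coef,
            "species": "external" if mid in ext else "internal",
        }
        for mid, coef in sorted(coefs.items())
    ]
    return pd.DataFrame(rows, columns=["metabolite", "coefficient", "species"])


def bsr_diff(
    model_a: MetabolicModel | CompressedModel,
    biomass_a: str,
    model_b: MetabolicModel | CompressedModel,
    biomass_b: str,
    names: tuple[str, str] = ("model_a", "model_b"),
) -> pd.DataFrame:
    """Side-by-side biomass stoichiometry of two models.

    Rows align on the union of metabolite ids; absences are left blank (NaN).
    """
    a = condensed_bsr_report(model_a, biomass_a).set_index("metabolite")
    b = condensed_bsr_report(model_b, biomass_b).set_index("metabolite")
    out = pd.DataFrame(
        {
            names[0]: a["coefficient"],
            names[1]: b["coefficient"],
        }
    ).sort_index()
    return out.reset_index()
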