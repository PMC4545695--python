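"""Iterative network pruning that provably preserves protected parts.

The loop removes one non-protected reaction per iteration, always the one
with the smallest overall (scenario-union) flux range, and accepts the
deletion only if every protected specification still holds:

(a) each protected metabolite keeps at least one feasible reaction,
(b) each protected reaction can still carry flux (when enforced),
(c) each protected phenotype (scenario) stays feasible,
(d) the degrees of freedom stay >= dof_min,
(e) the reaction count stays >= n_min.

A rejected candidate is reinserted untouched and marked non-removable; the
next-smallest candidate from the same range table is tried before any FVA
recomputation.  Reactions whose range is sign-definite under some scenario
are essential and leave the candidate pool permanently.  The result is
always a proper subnetwork of the input.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, ModelError, ProtectionSpec, Scenario
from .lp import (
    DEFAULT_CONFIG,
    LPConfig,
    FluxRangeTable,
    fba,
    feasible,
    find_blocked,
    dof as dof_of,
    range_table,
    _solve,
)

logger = logging.getLogger(__name__)


@dataclass
class LogEntry:
    iteration: int
    reaction_id: str
    action: str  # removed | reinserted | essential | blocked_removed
    width: float | None = None
    scenario_widths: tuple[float, ...] = ()


@dataclass
class PruneResult:
    """Outcome of :func:`prune`: the reduced model plus full provenance."""

    model: MetabolicModel
    log: list[LogEntry]
    essential: set[str]
    removed: list[str]
    removed_metabolites: list[str]
    stats: dict[str, float]
    scenario_optima_before: dict[str, float | None]
    scenario_optima_after: dict[str, float | None]


class InfeasibleProtectionError(ModelError):
    """A protected function or part cannot be satisfied."""


# ---------------------------------------------------------------------------
# feasibility primitives used by the acceptance tests of a tentative deletion


def _can_carry_flux(
    model: MetabolicModel,
    rid: str,
    scenarios: list[Scenario],
    config: LPConfig,
) -> bool:
    """Can reaction *rid* attain |flux| > eps in at least one scenario?"""
    j = model.reaction_index(rid)
    scen_list: list[Scenario | None] = list(scenarios) if scenarios else [None]
    c = np.zeros(model.n_reactions)
    for sc in scen_list:
        c[j] = -1.0  # maximise r_j
        status, fun, _ = _solve(model, c, sc, clip=config.flux_cap)
        if status == "optimal" and -fun > config.eps_flux:
            return True
        c[j] = 1.0  # minimise r_j
        status, fun, _ = _solve(model, c, sc, clip=config.flux_cap)
        if status == "optimal" and fun < -config.eps_flux:
            return True
        c[j] = 0.0
    return False


def _check_specifications(
    model: MetabolicModel,
    spec: ProtectionSpec,
    config: LPConfig,
) -> str | None:
    """Return a violation description, or None if (a)-(c) all hold."""
    for sc in spec.scenarios:
        if not feasible(model, sc):
            return f"scenario {sc.name!r} infeasible"
    if not spec.scenarios and not feasible(model, None):
        return "no feasible steady-state flux vector"
    if spec.enforce_protected_feasibility:
        for rid in sorted(spec.protected_reactions):
            if not _can_carry_flux(model, rid, spec.scenarios, config):
                return f"protected reaction {rid!r} blocked"
    present = set(model.metabolite_ids)
    for mid in sorted(spec.protected_metabolites):
        if mid not in present:
            return f"protected metabolite {mid!r} lost"
        i = model.metabolite_index(mid)
        touching = [
            model.reaction_ids[j]
            for j in np.nonzero(np.abs(model.S[i, :]) > 0)[0]
        ]
        if not any(
            _can_carry_flux(model, rid, spec.scenarios, config) for rid in touching
        ):
            return f"protected metabolite {mid!r} has no feasible reaction"
    return None


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    model: MetabolicModel,
    spec: ProtectionSpec,
    config: LPConfig = DEFAULT_CONFIG,
) -> tuple[MetabolicModel, list[LogEntry]]:
    """Validate protections on the full model and strip blocked reactions.

    Checks that every protected scenario is feasible and that protected
    reactions/metabolites are themselves feasible (where enforced), then
    removes all non-protected blocked reactions and any internal metabolite
    left unconnected.  Raises :class:`InfeasibleProtectionError` naming the
    first violated protection.
    """
    spec.validate_against(model)
    for sc in spec.scenarios:
        if not feasible(model, sc):
            raise InfeasibleProtectionError(
                f"protected function {sc.name!r} is infeasible in the full model"
            )
    blocked = find_blocked(model, config)
    if spec.enforce_protected_feasibility:
        dead = sorted(blocked & spec.protected_reactions)
        if dead:
            raise InfeasibleProtectionError(
                f"protected reactions can never carry flux: {dead}"
            )
    for mid in sorted(spec.protected_metabolites):
        i = model.metabolite_index(mid)
        touching = {
            model.reaction_ids[j] for j in np.nonzero(np.abs(model.S[i, :]) > 0)[0]
        }
        if touching and touching <= blocked:
            raise InfeasibleProtectionError(
                f"all reactions of protected metabolite {mid!r} are blocked"
            )
    removable_blocked = sorted(blocked - spec.protected_reactions)
    log = [LogEntry(0, rid, "blocked_removed", 0.0) for rid in removable_blocked]
    out = model.drop_reactions(removable_blocked) if removable_blocked else model
    out, _dropped = out.drop_unconnected_metabolites(keep=spec.protected_metabolites)
    return out, log


# ---------------------------------------------------------------------------
# candidate classification and selection


def classify_essential(
    table: FluxRangeTable, config: LPConfig = DEFAULT_CONFIG
) -> set[str]:
    """Reactions with an entirely positive/negative range in some scenario.

    Such a reaction must carry flux in that protected function, so deleting
    it would necessarily break the function: it is essential and leaves the
    removable pool for good.
    """
    return {
        rid
        for rid, rr in table.items()
        if any(fr.sign_definite(config.eps_flux) for fr in rr.per_scenario)
    }


def _width_key(rr) -> tuple[float, int]:
    # capped (unbounded) ranges compare by finite width, then by number of
    # capped ends (fewer first)
    return (rr.width, rr.n_capped_ends)


def select_candidates(
    table: FluxRangeTable,
    removable: set[str],
    rng: random.Random,
    tie_break: str = "random",
) -> list[str]:
    """Removable reactions ordered smallest overall flux range first.

    Candidates whose (width, capped-ends) keys tie within tolerance are
    ordered randomly (seeded) or by lowest index, per *tie_break*.
    """
    rids = [r for r in table if r in removable]
    if not rids:
        return []
    keyed = sorted(rids, key=lambda r: _width_key(table[r]))
    ordered: list[str] = []
    i = 0
    while i < len(keyed):
        w, nc = _width_key(table[keyed[i]])
        group = [keyed[i]]
        j = i + 1
        tol = 1e-9 * max(1.0, abs(w))
        while j < len(keyed):
            w2, nc2 = _width_key(table[keyed[j]])
            if abs(w2 - w) <= tol and nc2 == nc:
                group.append(keyed[j])
                j += 1
            else:
                break
        if len(group) > 1 and tie_break == "random":
            rng.shuffle(group)
        ordered.extend(group)
        i = j
    return ordered


def select_candidate(
    table: FluxRangeTable,
    removable: set[str],
    rng: random.Random | None = None,
    tie_break: str = "random",
) -> str | None:
    """The single next deletion candidate (smallest overall range), if any."""
    order = select_candidates(table, removable, rng or random.Random(0), tie_break)
    return order[0] if order else None


def try_delete(
    model: MetabolicModel,
    rid: str,
    spec: ProtectionSpec,
    config: LPConfig = DEFAULT_CONFIG,
) -> tuple[bool, MetabolicModel | None, str | None]:
    """Tentatively delete *rid* and test specifications (a)-(e).

    Returns ``(accepted, new_model, reason)``.  On rejection the input model
    object is untouched (exact restoration) and *reason* names the violated
    specification.
    """
    if model.n_reactions - 1 < spec.n_min:
        return False, None, f"n would fall below n_min={spec.n_min}"
    trial = model.drop_reactions([rid])
    if dof_of(trial, config) < spec.dof_min:
        return False, None, f"dof would fall below dof_min={spec.dof_min}"
    violation = _check_specifications(trial, spec, config)
    if violation is not None:
        return False, None, violation
    return True, trial, None


# ---------------------------------------------------------------------------
# the main loop


def prune(
    model: MetabolicModel,
    spec: ProtectionSpec,
    seed: int = 0,
    tie_break: str = "random",
    config: LPConfig = DEFAULT_CONFIG,
    lazy_fva: bool = False,
) -> PruneResult:
    """Reduce *model* to a minimal subnetwork preserving *spec*.

    Runs preprocessing, then the pruning loop until no further non-protected
    reaction can be deleted without violating a protected specification.
    Unconnected internal metabolites are dropped at the end (protected ones
    are always kept).

    Parameters
    ----------
    seed
        Seed for the tie-breaking RNG; candidates with identical flux-range
        widths (e.g. parallel pathways) are ordered randomly, which makes
        the surviving pathway — not the guarantees — seed-dependent.
    tie_break
        ``"random"`` (default) or ``"index"`` for the deterministic
        lowest-index policy.
    lazy_fva
        Reuse the flux-range table across accepted deletions until a
        rejection occurs.  Cuts LP count; may change (not invalidate) the
        trajectory.
    """
    rng = random.Random(seed)
    stats: dict[str, float] = {
        "n_before": model.n_reactions,
        "m_before": model.n_metabolites,
        "dof_before": dof_of(model, config),
    }
    optima_before = _scenario_optima(model, spec)

    current, log = preprocess(model, spec, config)
    essential: set[str] = set()
    non_removable: set[str] = set()
    removed: list[str] = []
    iteration = 0
    table: FluxRangeTable | None = None

    while True:
        iteration += 1
        removable = (
            set(current.reaction_ids)
            - spec.protected_reactions
            - essential
            - non_removable
        )
        if not removable:
            break
        if table is None or not lazy_fva:
            table = range_table(current, sorted(removable), spec.scenarios, config)
            if table is None:  # pragma: no cover - scenarios were feasible before
                raise InfeasibleProtectionError(
                    "a protected function became infeasible mid-pruning"
                )
            newly_essential = classify_essential(table, config)
            for rid in sorted(newly_essential):
                essential.add(rid)
                log.append(
                    LogEntry(
                        iteration,
                        rid,
                        "essential",
                        table[rid].width,
                        tuple(fr.width for fr in table[rid].per_scenario),
                    )
                )
            removable -= newly_essential
        candidates = select_candidates(table, removable, rng, tie_break)
        accepted_any = False
        for rid in candidates:
            ok, trial, reason = try_delete(current, rid, spec, config)
            if ok:
                current = trial
                removed.append(rid)
                log.append(
                    LogEntry(
                        iteration,
                        rid,
                        "removed",
                        table[rid].width,
                        tuple(fr.width for fr in table[rid].per_scenario),
                    )
                )
                accepted_any = True
                if not lazy_fva:
                    table = None
                else:
                    table = {r: v for r, v in table.items() if r != rid}
                break
            non_removable.add(rid)
            log.append(
                LogEntry(
                    iteration,
                    rid,
                    "reinserted",
                    table[rid].width,
                    tuple(fr.width for fr in table[rid].per_scenario),
                )
            )
            logger.debug("rejected deletion of %s: %s", rid, reason)
        if not accepted_any:
            if lazy_fva and table is not None:
                # stale table may have hidden a viable candidate: refresh once
                lazy_fva = False
                table = None
                iteration -= 1
                continue
            break

    current, dropped_mets = current.drop_unconnected_metabolites(
        keep=spec.protected_metabolites
    )
    stats.update(
        n_after=current.n_reactions,
        m_after=current.n_metabolites,
        dof_after=dof_of(current, config),
    )
    return PruneResult(
        model=current,
        log=log,
        essential=essential,
        removed=removed,
        removed_metabolites=dropped_mets,
        stats=stats,
        scenario_optima_before=optima_before,
        scenario_optima_after=_scenario_optima(current, spec),
    )


def _scenario_optima(
    model: MetabolicModel, spec: ProtectionSpec
) -> dict[str, float | None]:
    """Max of the model objective under each scenario (None if no objective)."""
    out: dict[str, float | None] = {}
    if not np.any(model.objective):
        return {sc.name: None for sc in spec.scenarios}
    for sc in spec.scenarios:
        res = fba(model, None, sc)
        out[sc.name] = res.objective_value if res.status == "optimal" else None
    return out
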