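"""Linear-programming primitives: FBA, FVA, blocked reactions, rank counts.

All solves go through :func:`scipy.optimize.linprog` (HiGHS).  Flux
variability is computed with bounds clipped at ``flux_cap`` so that unbounded
directions (e.g. internal reversible cycles) come back as finite, *flagged*
ranges instead of solver failures; the flags let the pruning step rank
unbounded ranges honestly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, Scenario

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
ERROR = "error"

_STATUS = {0: OPTIMAL, 1: ERROR, 2: INFEASIBLE, 3: UNBOUNDED, 4: ERROR}


@dataclass
class LPConfig:
    """Numerical tolerances shared across the package.

    eps_flux
        Zero/sign classification of a flux value.
    eps_feas
        Constraint-satisfaction tolerance.
    eps_rank
        Relative tolerance for the numerical rank of S (scaled by the largest
        singular value).
    flux_cap
        Clip value for unbounded FVA directions.
    """

    eps_flux: float = 1e-9
    eps_feas: float = 1e-7
    eps_rank: float = 1e-9
    flux_cap: float = 1e5


DEFAULT_CONFIG = LPConfig()


@dataclass(frozen=True)
class FluxRange:
    """Feasible [lo, hi] interval of one reaction under one scenario."""

    lo: float
    hi: float
    capped_lo: bool = False
    capped_hi: bool = False

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains_zero(self, eps: float = DEFAULT_CONFIG.eps_flux) -> bool:
        return self.lo <= eps and self.hi >= -eps

    def sign_definite(self, eps: float = DEFAULT_CONFIG.eps_flux) -> bool:
        """Entirely positive or entirely negative range."""
        return self.lo > eps or self.hi < -eps


@dataclass
class FBAResult:
    status: str
    objective_value: float | None
    fluxes: np.ndarray | None


@dataclass
class FVAResult:
    status: str
    ranges: dict[str, FluxRange] = field(default_factory=dict)


def _scenario_system(
    model: MetabolicModel, scenario: Scenario | None
) -> tuple[np.ndarray | None, np.ndarray | None, list[tuple[float, float]]]:
    """Assemble (A_ub, b_ub, bounds) for a model under an optional scenario."""
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    if scenario is not None:
        for rid, (lo, hi) in scenario.bound_overrides.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = lo, hi
        for con in scenario.constraints:
            row = np.zeros(model.n_reactions)
            for rid, coef in con.coefs:
                row[model.reaction_index(rid)] = coef
            rows.append(row)
            rhs.append(con.rhs)
    A_ub = np.array(rows) if rows else None
    b_ub = np.array(rhs) if rows else None
    bounds = list(zip(lb, ub))
    return A_ub, b_ub, bounds


def _solve(
    model: MetabolicModel,
    c_min: np.ndarray,
    scenario: Scenario | None,
    clip: float | None = None,
) -> tuple[str, float | None, np.ndarray | None]:
    """Minimise ``c_min @ r`` subject to N r = 0, bounds, scenario."""
    A_ub, b_ub, bounds = _scenario_system(model, scenario)
    if clip is not None:
        bounds = [(max(lo, -clip), min(hi, clip)) for lo, hi in bounds]
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    res = linprog(
        c_min,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, ERROR)
    if status == OPTIMAL:
        return status, float(res.fun), np.asarray(res.x)
    return status, None, None


def fba(
    model: MetabolicModel,
    objective: Mapping[str, float] | None = None,
    scenario: Scenario | None = None,
) -> FBAResult:
    """Flux balance analysis: maximise a linear objective at steady state.

    Maximises ``c @ r`` subject to ``N r = 0``, flux bounds, and the
    scenario's inequalities.  With ``objective=None`` the model's own
    objective vector is used.

    Returns an :class:`FBAResult` whose ``status`` is one of ``optimal``,
    ``infeasible``, ``unbounded`` or ``error``; solver failures are never
    reported as a silent zero.
    """
    c = np.zeros(model.n_reactions)
    if objective is None:
        c[:] = model.objective
    else:
        for rid, coef in objective.items():
            c[model.reaction_index(rid)] = coef
    status, fun, x = _solve(model, -c, scenario)
    if status == OPTIMAL:
        return FBAResult(status, -fun, x)
    return FBAResult(status, None, None)


def feasible(
    model: MetabolicModel,
    scenario: Scenario | None = None,
) -> bool:
    """Does any steady-state flux vector satisfy bounds + scenario?"""
    status, _, _ = _solve(model, np.zeros(model.n_reactions), scenario)
    return status == OPTIMAL


def fva(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    scenario: Scenario | None = None,
    config: LPConfig = DEFAULT_CONFIG,
) -> FVAResult:
    """Flux variability analysis: per-reaction [min, max] rate intervals.

    Directions that are unbounded in the true polyhedron are clipped at
    ``config.flux_cap`` and flagged (``capped_lo``/``capped_hi``).  An
    infeasible scenario yields ``FVAResult(status='infeasible')`` with no
    ranges rather than empty or zero intervals.
    """
    if reactions is None:
        reactions = list(model.reaction_ids)
    if not feasible(model, scenario):
        return FVAResult(INFEASIBLE)
    cap = config.flux_cap
    out: dict[str, FluxRange] = {}
    for rid in reactions:
        j = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        st_lo, lo, _ = _solve(model, c, scenario, clip=cap)
        st_hi, hi_neg, _ = _solve(model, -c, scenario, clip=cap)
        if st_lo != OPTIMAL or st_hi != OPTIMAL:
            raise ModelError(
                f"FVA solve failed for reaction {rid!r} "
                f"(statuses {st_lo}/{st_hi})"
            )
        hi = -hi_neg
        capped_lo = bool(
            lo <= -cap + config.eps_feas and not np.isfinite(model.lower_bounds[j])
        )
        capped_hi = bool(
            hi >= cap - config.eps_feas and not np.isfinite(model.upper_bounds[j])
        )
        # snap tiny numerical noise onto zero
        if abs(lo) < config.eps_flux:
            lo = 0.0
        if abs(hi) < config.eps_flux:
            hi = 0.0
        lo = min(lo, hi)
        out[rid] = FluxRange(lo, hi, capped_lo, capped_hi)
    return FVAResult(OPTIMAL, out)


# ---------------------------------------------------------------------------
# range unions


def union_ranges(ranges: Iterable[FluxRange]) -> tuple[list[tuple[float, float]], float]:
    """Union of per-scenario flux ranges as sorted disjoint intervals.

    Returns ``(intervals, total_width)`` where ``total_width`` is the sum of
    interval lengths — the overall flux-range measure used to pick deletion
    candidates.
    """
    ivs = sorted((r.lo, r.hi) for r in ranges)
    if not ivs:
        raise ModelError("union_ranges requires at least one range")
    merged: list[list[float]] = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = [(lo, hi) for lo, hi in merged]
    width = float(sum(hi - lo for lo, hi in out))
    return out, width


@dataclass
class ReactionRanges:
    """All per-scenario ranges of one reaction plus their union."""

    per_scenario: list[FluxRange]
    union: list[tuple[float, float]]
    width: float
    n_capped_ends: int

    @staticmethod
    def from_scenarios(ranges: list[FluxRange]) -> "ReactionRanges":
        union, width = union_ranges(ranges)
        n_capped = sum(int(r.capped_lo) + int(r.capped_hi) for r in ranges)
        return ReactionRanges(ranges, union, width, n_capped)


FluxRangeTable = dict[str, ReactionRanges]


def range_table(
    model: MetabolicModel,
    reactions: Sequence[str],
    scenarios: Sequence[Scenario],
    config: LPConfig = DEFAULT_CONFIG,
) -> FluxRangeTable | None:
    """Per-reaction per-scenario FVA table with scenario unions.

    With no scenarios the full (base-bounds) flux range is used as the single
    "scenario".  Returns ``None`` if any scenario is infeasible.
    """
    scen_list: list[Scenario | None] = list(scenarios) if scenarios else [None]
    per_scen: list[dict[str, FluxRange]] = []
    for sc in scen_list:
        res = fva(model, reactions, sc, config)
        if res.status != OPTIMAL:
            return None
        per_scen.append(res.ranges)
    return {
        rid: ReactionRanges.from_scenarios([ranges[rid] for ranges in per_scen])
        for rid in reactions
    }


# ---------------------------------------------------------------------------
# structural statistics


def find_blocked(
    model: MetabolicModel, config: LPConfig = DEFAULT_CONFIG
) -> set[str]:
    """Reactions whose base-bound flux range is exactly [0, 0].

    A blocked reaction can never carry flux at steady state under the model's
    own bounds; scenarios only tighten the polyhedron, so scenario-blocked
    sets are supersets of this one.
    """
    res = fva(model, None, None, config)
    if res.status != OPTIMAL:
        # no feasible steady-state flux at all: every reaction is blocked
        return set(model.reaction_ids)
    return {
        rid
        for rid, r in res.ranges.items()
        if abs(r.lo) <= config.eps_flux and abs(r.hi) <= config.eps_flux
    }


def _rank(S: np.ndarray, config: LPConfig) -> int:
    if S.size == 0 or min(S.shape) == 0:
        return 0
    sv = np.linalg.svd(S, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > config.eps_rank * sv[0] * max(S.shape)))


def dof(model: MetabolicModel, config: LPConfig = DEFAULT_CONFIG) -> int:
    """Degrees of freedom of the steady-state flux space: n - rank(N).

    A model with no internal metabolites has rank 0, so a single
    pure-exchange reaction yields dof = 1.
    """
    return model.n_reactions - _rank(model.S, config)


def conservation_relations(
    model: MetabolicModel, config: LPConfig = DEFAULT_CONFIG
) -> tuple[int, np.ndarray]:
    """Number of conserved moieties, m - rank(N), plus a left-null basis.

    Each basis row ``y`` satisfies ``y @ S = 0``; classic examples are
    conserved cofactor pools such as ATP+ADP.
    """
    m = model.n_metabolites
    r = _rank(model.S, config)
    count = m - r
    if count == 0 or m == 0:
        return count, np.zeros((0, m))
    # left null space via SVD of S^T
    u, sv, vt = np.linalg.svd(model.S.T, full_matrices=True)
    basis = vt[r:, :]
    return count, basis


def nullspace(model: MetabolicModel, config: LPConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Orthonormal kernel basis K (n x dof) of S, with S @ K ~ 0."""
    n = model.n_reactions
    r = _rank(model.S, config)
    if model.n_metabolites == 0 or model.S.size == 0:
        return np.eye(n)
    u, sv, vt = np.linalg.svd(model.S, full_matrices=True)
    return vt[r:, :].T
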