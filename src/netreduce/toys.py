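"""Packaged toy networks and a random-network generator.

Every toy builder returns ``(model, spec, expected)`` where *expected* is a
descriptor of the documented reduction outcome, asserted end-to-end in the
test suite.  External species follow the ``*_ext`` id convention.

Catalog
-------
worked_example
    A protected precursor/cofactor core feeding a three-step amino-acid
    synthesis chain (2 P -> D; D + NADPH -> F; F + ATP -> A) whose product
    enters the biomass synthesis reaction as ``2 A``; plus a wasteful
    alternative route that pruning removes.  Compression must fold the chain
    into the BSR, which becomes ``4 P + 2 ATP + 2 NADPH -> biomass``.
diamond
    Two parallel two-step paths between a protected source and sink; with a
    max-export phenotype exactly one path survives (4 reactions), whichever
    the tie-breaking seed picks.
oxidase_pair
    A chemiosmotic mini-network with two ubiquinol oxidases that differ in
    translocated protons (2 H+ vs 4 H+ per 0.5 O2); only the 4-proton pump
    sustains maximal growth, so it must survive pruning.
trace_element
    The worked example plus a trace-element uptake/consumption pair that
    compression collapses into the condensed BSR.
cycle_unbounded
    A feasible linear chain next to an isolated reversible 2-cycle whose
    flux range is unbounded (capped + flagged by FVA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel, ModelError, ProtectionSpec, Scenario
from .io import build_protection_spec
from . import lp

_INF = float("inf")


def _build(
    reactions: dict[str, tuple[dict[str, float], float, float, float]],
    name: str,
) -> MetabolicModel:
    """Assemble a model from {rid: (stoichiometry, lb, ub, objective)}."""
    mets = sorted(
        {m for stoich, *_ in reactions.values() for m in stoich if not m.endswith("_ext")}
    )
    exts = sorted(
        {m for stoich, *_ in reactions.values() for m in stoich if m.endswith("_ext")}
    )
    rids = list(reactions)
    S = np.zeros((len(mets), len(rids)))
    S_ext = np.zeros((len(exts), len(rids)))
    lb, ub, c = np.zeros(len(rids)), np.zeros(len(rids)), np.zeros(len(rids))
    for j, rid in enumerate(rids):
        stoich, lo, hi, obj = reactions[rid]
        for m, coef in stoich.items():
            if m.endswith("_ext"):
                S_ext[exts.index(m), j] = coef
            else:
                S[mets.index(m), j] = coef
        lb[j], ub[j], c[j] = lo, hi, obj
    return MetabolicModel(mets, rids, S, lb, ub, c, exts, S_ext, name=name)


def _worked_example_model(with_trace_element: bool) -> MetabolicModel:
    bsr_stoich: dict[str, float] = {"A": -2, "Biomass_ext": 1}
    rxns: dict[str, tuple[dict[str, float], float, float, float]] = {
        # protected core: precursor and cofactor supply with independent drains
        "R_P_supply": ({"S_ext": -1, "P": 1}, 0, 1000, 0),
        "R_P_overflow": ({"P": -1, "Pex_ext": 1}, 0, 1000, 0),
        "R_atp_syn": ({"E_ext": -1, "ATP": 1}, 0, 1000, 0),
        "R_atp_maint": ({"ATP": -1, "W_ext": 1}, 0, 1000, 0),
        "R_nadph_syn": ({"E_ext": -1, "NADPH": 1}, 0, 1000, 0),
        "R_nadph_ox": ({"NADPH": -1, "W_ext": 1}, 0, 1000, 0),
        # the amino-acid synthesis chain (non-protected)
        "R_D": ({"P": -2, "D": 1}, 0, 1000, 0),
        "R_F": ({"D": -1, "NADPH": -1, "F": 1}, 0, 1000, 0),
        "R_A": ({"F": -1, "ATP": -1, "A": 1}, 0, 1000, 0),
        # wasteful alternative route (3 P per F): pruning removes it
        "R_alt1": ({"P": -3, "D2": 1}, 0, 1000, 0),
        "R_alt2": ({"D2": -1, "NADPH": -1, "F": 1}, 0, 1000, 0),
    }
    if with_trace_element:
        rxns["R_te_up"] = ({"TE_ext": -1, "TE": 1}, 0, 1000, 0)
        bsr_stoich["TE"] = -0.1
    rxns["BSR"] = (bsr_stoich, 0, 1000, 1)
    return _build(rxns, "trace_element" if with_trace_element else "worked_example")


def _worked_example_spec(model: MetabolicModel) -> ProtectionSpec:
    return build_protection_spec(
        {
            "protected_metabolites": ["P"],
            "protected_reactions": [
                "R_P_supply",
                "R_P_overflow",
                "R_atp_syn",
                "R_atp_maint",
                "R_nadph_syn",
                "R_nadph_ox",
                "BSR",
            ],
            "enforce_protected_feasibility": True,
            "dof_min": 1,
            "n_min": 1,
            "scenarios": [
                {
                    "name": "max_growth",
                    "constraints": [
                        "R_P_supply <= 10",
                        "-BSR <= -0.999 * FBA_MAX(BSR)",
                    ],
                }
            ],
        },
        model,
    )


def build_toy(name: str):
    """Return ``(model, spec, expected)`` for one catalog entry.

    *expected* documents the reduction outcome the builder guarantees; the
    test suite asserts every field end-to-end.
    """
    if name == "worked_example":
        model = _worked_example_model(False)
        spec = _worked_example_spec(model)
        expected = {
            "pruned_reactions": 10,
            "removed": {"R_alt1", "R_alt2"},
            "bsr_id": "BSR",
            "condensed_bsr": {
                "P": -4.0,
                "ATP": -2.0,
                "NADPH": -2.0,
                "Biomass_ext": 1.0,
            },
            "eliminated_metabolites": {"D", "F", "A"},
        }
        return model, spec, expected

    if name == "trace_element":
        model = _worked_example_model(True)
        spec = _worked_example_spec(model)
        expected = {
            "pruned_reactions": 11,
            "bsr_id": "BSR",
            "condensed_bsr": {
                "P": -4.0,
                "ATP": -2.0,
                "NADPH": -2.0,
                "TE_ext": -0.1,
                "Biomass_ext": 1.0,
            },
            "eliminated_metabolites": {"D", "F", "A", "TE"},
        }
        return model, spec, expected

    if name == "diamond":
        model = _build(
            {
                "R_in": ({"X_ext": -1, "S1": 1}, 0, 10, 0),
                "P1a": ({"S1": -1, "M1": 1}, 0, 1000, 0),
                "P1b": ({"M1": -1, "T": 1}, 0, 1000, 0),
                "P2a": ({"S1": -1, "M2": 1}, 0, 1000, 0),
                "P2b": ({"M2": -1, "T": 1}, 0, 1000, 0),
                "R_out": ({"T": -1, "Y_ext": 1}, 0, 1000, 1),
            },
            "diamond",
        )
        spec = build_protection_spec(
            {
                "protected_reactions": ["R_in", "R_out"],
                "enforce_protected_feasibility": True,
                "dof_min": 1,
                "n_min": 1,
                "scenarios": [
                    {
                        "name": "max_export",
                        "constraints": ["-R_out <= -0.999 * FBA_MAX(R_out)"],
                    }
                ],
            },
            model,
        )
        expected = {"pruned_reactions": 4, "max_export": 10.0}
        return model, spec, expected

    if name == "oxidase_pair":
        model = _build(
            {
                "R_sub_up": ({"S_ext": -1, "Sb": 1}, 0, 10, 0),
                "R_o2_up": ({"O2_ext": -1, "O2": 1}, 0, 1000, 0),
                "R_red": ({"Sb": -1, "Q8": -1, "Q8H2": 1}, 0, 1000, 0),
                # cytochrome bd oxidase: 2 H+ + 0.5 O2 + Q8H2 -> H2O + 2 H+_p + Q8
                "OX2": (
                    {"Hc": -2, "O2": -0.5, "Q8H2": -1, "H2O": 1, "Hp": 2, "Q8": 1},
                    0,
                    1000,
                    0,
                ),
                # cytochrome bo3 oxidase: 4 H+ + 0.5 O2 + Q8H2 -> H2O + 4 H+_p + Q8
                "OX4": (
                    {"Hc": -4, "O2": -0.5, "Q8H2": -1, "H2O": 1, "Hp": 4, "Q8": 1},
                    0,
                    1000,
                    0,
                ),
                "R_atps": ({"Hp": -4, "Hc": 4, "ATP": 1}, 0, 1000, 0),
                "R_gro": ({"ATP": -1, "Biomass_ext": 1}, 0, 1000, 1),
                "R_h2o_ex": ({"H2O": -1, "H2O_ext": 1}, 0, 1000, 0),
            },
            "oxidase_pair",
        )
        spec = build_protection_spec(
            {
                "protected_metabolites": ["O2"],
                "protected_reactions": ["R_sub_up", "R_o2_up", "R_gro"],
                "enforce_protected_feasibility": True,
                "dof_min": 1,
                "n_min": 1,
                "scenarios": [
                    {
                        "name": "max_growth",
                        "constraints": ["-R_gro <= -0.999 * FBA_MAX(R_gro)"],
                    }
                ],
            },
            model,
        )
        expected = {
            "retained": "OX4",
            "removed": "OX2",
            "max_growth": 10.0,
            "max_growth_without_OX4": 5.0,
        }
        return model, spec, expected

    if name == "cycle_unbounded":
        model = _build(
            {
                "R_up": ({"X_ext": -1, "A": 1}, 0, 10, 0),
                "R_ex": ({"A": -1, "Y_ext": 1}, 0, 1000, 1),
                "R_c1": ({"B": -1, "C": 1}, -_INF, _INF, 0),
                "R_c2": ({"C": -1, "B": 1}, -_INF, _INF, 0),
            },
            "cycle_unbounded",
        )
        spec = build_protection_spec(
            {
                "protected_reactions": ["R_up", "R_ex"],
                "enforce_protected_feasibility": True,
                "dof_min": 1,
                "n_min": 1,
                "scenarios": [],
            },
            model,
        )
        expected = {"pruned_reactions": 2, "capped": {"R_c1", "R_c2"}}
        return model, spec, expected

    raise ModelError(f"unknown toy {name!r}")


TOY_NAMES = (
    "worked_example",
    "diamond",
    "oxidase_pair",
    "trace_element",
    "cycle_unbounded",
)


# ---------------------------------------------------------------------------
# random networks


@dataclass
class RandomNetworkConfig:
    """Knobs of the random-network generator used by the property tests."""

    n_metabolites: int = 8
    n_reactions: int = 15
    density: float = 0.25
    fraction_reversible: float = 0.3
    n_exchanges: int = 4
    seed: int = 0
    max_attempts: int = 300


def _connected(model: MetabolicModel, exchange_cols: list[int]) -> bool:
    """Every metabolite reachable from an exchange via shared reactions."""
    m, n = model.S.shape
    touch = np.abs(model.S) > 0
    reached_mets = set()
    frontier = list(exchange_cols)
    seen_rxns = set(frontier)
    while frontier:
        j = frontier.pop()
        for i in np.nonzero(touch[:, j])[0]:
            if i not in reached_mets:
                reached_mets.add(int(i))
                for j2 in np.nonzero(touch[i, :])[0]:
                    if j2 not in seen_rxns:
                        seen_rxns.add(int(j2))
                        frontier.append(int(j2))
    return len(reached_mets) == m


def random_network(config: RandomNetworkConfig) -> MetabolicModel:
    """Generate a feasible, mass-connected random stoichiometric network.

    Rejection-samples until the network is connected and carries at least
    one nonzero steady-state flux; identical configs (incl. seed) give
    identical models.  Raises :class:`ModelError` when the rejection budget
    is exhausted (e.g. density 0 admits no feasible flux).
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.n_metabolites, config.n_reactions
    if config.n_exchanges > n:
        raise ModelError("n_exchanges cannot exceed n_reactions")
    for _attempt in range(config.max_attempts):
        S = np.zeros((m, n))
        S_ext = np.zeros((config.n_exchanges, n))
        n_entries = int(round(config.density * m))
        exchange_cols = list(range(config.n_exchanges))
        try:
            for j in range(n):
                if j in exchange_cols:
                    i = int(rng.integers(m))
                    # alternate uptake (+1) and export (-1); the boundary
                    # species balances the mass outside the system
                    S[i, j] = 1.0 if j % 2 == 0 else -1.0
                    S_ext[j, j] = -S[i, j]
                    continue
                k = min(n_entries, m)
                mets = rng.choice(m, size=k, replace=False) if k > 0 else []
                half = max(1, k // 2) if k else 0
                for idx, i in enumerate(mets):
                    coef = float(rng.integers(1, 3))
                    S[i, j] = -coef if idx < half else coef
            rev = rng.random(n) < config.fraction_reversible
            lb = np.where(rev, -1000.0, 0.0)
            ub = np.full(n, 1000.0)
            model = MetabolicModel(
                metabolite_ids=[f"M{i}" for i in range(m)],
                reaction_ids=[f"R{j}" for j in range(n)],
                S=S,
                lower_bounds=lb,
                upper_bounds=ub,
                objective=np.zeros(n),
                external_species=[f"X{j}_ext" for j in exchange_cols],
                S_ext=S_ext,
                name=f"random_{config.seed}",
            )
        except ModelError:
            continue
        if not _connected(model, exchange_cols):
            continue
        blocked = lp.find_blocked(model)
        if len(blocked) < n:
            return model
    raise ModelError(
        f"rejection budget exhausted ({config.max_attempts} attempts): "
        "no feasible connected network under this configuration"
    )
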