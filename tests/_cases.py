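"""Shared construction of random reduction test cases."""

from __future__ import annotations

from netreduce import (
    ProtectionSpec,
    RandomNetworkConfig,
    Scenario,
    fba,
    find_blocked,
    random_network,
)

PRESERVE_FRACTION = 0.999


def make_random_case(
    seed: int,
    n_metabolites: int = 8,
    n_reactions: int = 15,
):
    """A random network plus a protection spec demanding that one reaction's
    maximal rate stays attainable to 99.9 %.

    Returns ``(model, spec, target, optimum)``; the target reaction is the
    first non-blocked one, protected together with one exchange.
    """
    model = random_network(
        RandomNetworkConfig(
            n_metabolites=n_metabolites, n_reactions=n_reactions, seed=seed
        )
    )
    blocked = find_blocked(model)
    target = next(r for r in model.reaction_ids if r not in blocked)
    res = fba(model, {target: 1.0})
    assert res.status == "optimal"
    scenario = Scenario("preserve_target")
    scenario.add({target: 1.0}, ">=", PRESERVE_FRACTION * res.objective_value)
    spec = ProtectionSpec(
        protected_reactions={target, model.reaction_ids[0]},
        scenarios=[scenario],
        enforce_protected_feasibility=False,
        dof_min=1,
        n_min=1,
    )
    return model, spec, target, res.objective_value
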