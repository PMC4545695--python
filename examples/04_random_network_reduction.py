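"""Reducing a random network while preserving one optimum.

Generates a seeded random stoichiometric network, protects a single target
reaction's maximal rate (99.9 %), prunes, and compresses.  The pruned model
is a proper subnetwork; compression changes neither the degrees of freedom
nor the attainable optimum.
"""

import numpy as np

from netreduce import (
    ProtectionSpec, RandomNetworkConfig, Scenario,
    compress, dof, fba, find_blocked, prune, random_network,
)

model = random_network(RandomNetworkConfig(n_metabolites=8, n_reactions=15, seed=7))
target = next(r for r in model.reaction_ids if r not in find_blocked(model))
opt = fba(model, {target: 1.0}).objective_value
print(f"random network: n={model.n_reactions}, m={model.n_metabolites}, "
      f"dof={dof(model)}; max {target} = {opt:g}")

scenario = Scenario("preserve_target")
scenario.add({target: 1.0}, ">=", 0.999 * opt)
spec = ProtectionSpec(protected_reactions={target}, scenarios=[scenario])

pruned = prune(model, spec, seed=7).model
comp = compress(pruned, spec)
print(f"pruned:     n={pruned.n_reactions}, dof={dof(pruned)}, "
      f"max {target} = {fba(pruned, {target: 1.0}).objective_value:g}")
print(f"compressed: n={comp.model.n_reactions}, dof={dof(comp.model)}, "
      f"max {target} = {fba(comp.model, {target: 1.0}).objective_value:g}")

# expanding a compressed flux vector gives a steady state of the pruned model
v = fba(comp.model, {target: 1.0}).fluxes
print("expansion residual ||S v||_inf =",
      float(np.abs(pruned.S @ comp.expand_flux(v)).max()))
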