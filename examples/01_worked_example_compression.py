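"""Condensed biomass synthesis via prune + loss-free compression.

The worked-example toy contains a protected core (precursor P and the
cofactors ATP/NADPH, each with its own supply and drain) feeding a
three-step amino-acid synthesis chain 2 P -> D; D + NADPH -> F;
F + ATP -> A; the biomass reaction consumes 2 A.  Pruning removes a
wasteful alternative route; compression folds the chain into the biomass
reaction, whose stoichiometry then states the *cumulative* precursor and
cofactor demand per unit biomass.
"""

from netreduce import build_toy, compress, condensed_bsr_report, prune

model, spec, _ = build_toy("worked_example")
print(f"full model: {model.n_reactions} reactions, {model.n_metabolites} metabolites")

result = prune(model, spec, seed=0)
print(f"pruned:     {result.model.n_reactions} reactions "
      f"(removed {sorted(result.removed)})")

comp = compress(result.model, spec)
print(f"compressed: {comp.model.n_reactions} reactions "
      f"(eliminated metabolites {sorted(comp.eliminated_metabolites)})")

print("\ncondensed biomass synthesis reaction (negative = consumed):")
print(condensed_bsr_report(comp, "BSR").to_string(index=False))
# 4 P + 2 ATP + 2 NADPH -> 1 biomass: exactly 2x the per-A chain demand,
# because each biomass unit needs 2 A.
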