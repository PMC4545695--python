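"""Smallest-flux-range pruning with random tie-breaking.

The diamond network offers two equivalent 2-step paths from a protected
source to a protected sink.  Under a max-export protected phenotype both
paths have identical flux-range widths, so the deletion candidate is chosen
randomly (seeded); exactly one path survives either way and the export
optimum is untouched.
"""

from netreduce import build_toy, fba, prune

model, spec, _ = build_toy("diamond")
for seed in (0, 2):
    result = prune(model, spec, seed=seed)
    kept = sorted(set(result.model.reaction_ids) - {"R_in", "R_out"})
    opt = fba(result.model).objective_value
    print(f"seed {seed}: kept path {kept}, {result.model.n_reactions} reactions, "
          f"max export = {opt:g}")
    for entry in result.log:
        print(f"   iter {entry.iteration}: {entry.action:>10} "
              f"{entry.reaction_id} (width {entry.width:g})")
# Both seeds end at 4 reactions; which parallel path survives is the only
# seed-dependent part, mirroring the non-uniqueness of order-dependent pruning.
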