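# netreduce

**netreduce** reduces stoichiometric (constraint-based) metabolic network
models to meaningful core models. Genome-scale reconstructions with
thousands of reactions defeat many stoichiometric methods (elementary-mode
enumeration, metabolic flux analysis, kinetic modelling) and obscure the
central metabolism they contain. netreduce automates the extraction of a
small model from a large one while *provably preserving* everything the
user declares worth keeping: specific metabolites and reactions, and —
crucially — whole phenotypes such as "99.9 % of the maximal aerobic growth
rate must remain attainable".

It is a library first (importable API, `examples/` scripts) with a thin
`netreduce` command-line wrapper. Intended users are systems-biology
modellers working with SBML/FBC models, e.g. via cobrapy.

## The method

A network with *m* internal metabolites and *n* reactions is the matrix
**N** with steady state **N r = 0**, flux bounds αᵢ ≤ rᵢ ≤ βᵢ, and
degrees of freedom *dof* = n − rank(**N**). Protected phenotypes are
inequality systems **D**ₖ**r** ≤ **d**ₖ (k = 1…s), each of which must stay
satisfiable by at least one steady-state flux vector.

**Pruning** iterates: flux variability analysis (FVA) computes each
removable reaction's flux range Fᵢᵏ under every protected phenotype and
their union Fᵢ = ∪ₖ Fᵢᵏ. A reaction with a strictly positive or strictly
negative Fᵢᵏ is *essential* and leaves the candidate pool. Otherwise the
reaction with the smallest overall range width is deleted tentatively
(ties broken by a seeded random draw); the deletion is kept only if every
protected phenotype stays feasible, protected reactions can still carry
flux, protected metabolites keep a feasible reaction, and *dof* ≥ dof_min,
n ≥ n_min — otherwise the reaction is reinserted and marked non-removable.
The result is always a proper subnetwork: every flux distribution of the
pruned model, zero-padded, is a flux distribution of the full model.

**Compression** then lumps *enzyme subsets* — reactions whose steady-state
fluxes are always proportional, detected from a nullspace basis of **N** —
into single overall reactions (column sums weighted by the flux ratios).
This is loss-free: it changes neither *dof* nor the attainable phenotypes.
A lumped subset may absorb at most one protected reaction, which keeps its
identity; this is how the biomass synthesis reaction (BSR) ends up
*condensed*, expressing monomer demands as cumulative precursor and
cofactor demands consistent with the full model.

## Worked example

The packaged `worked_example` toy has a protected core (precursor P,
cofactors ATP and NADPH, each with supply and drain) feeding the synthesis
chain `2 P -> D`, `D + NADPH -> F`, `F + ATP -> A`, with biomass made by
`2 A -> biomass`:

```bash
python examples/01_worked_example_compression.py
```

prints

```
full model: 12 reactions, 7 metabolites
pruned:     10 reactions (removed ['R_alt1', 'R_alt2'])
compressed: 7 reactions (eliminated metabolites ['A', 'D', 'F'])

condensed biomass synthesis reaction (negative = consumed):
 metabolite  coefficient  species
        ATP         -2.0 internal
Biomass_ext          1.0 external
      NADPH         -2.0 internal
          P         -4.0 internal
```

Pruning removed the wasteful alternative route; compression folded the
chain into the BSR, which now reads `4 P + 2 ATP + 2 NADPH -> biomass` —
each biomass unit needs 2 A, and each A costs 2 P, 1 NADPH, 1 ATP. The
intermediates D, F, A disappear from the model entirely.

Other examples: `02_diamond_pruning.py` (seeded tie-breaking between
equivalent parallel paths), `03_oxidase_preference.py` (a max-growth
phenotype forces retention of the 4-proton-pumping ubiquinol oxidase over
the 2-proton isoenzyme), `04_random_network_reduction.py` (subnetwork and
loss-freeness guarantees on a random network).

## Command line

```bash
netreduce prune    --model model.xml --spec spec.yaml --seed 0 \
                   --out pruned.xml --log removal_log.tsv
netreduce compress --model pruned.xml --spec spec.yaml --out comp.xml \
                   --map subsets.tsv --bsr-report bsr.tsv
netreduce bench    --model genome_scale.xml --spec spec.yaml --report t.tsv
```

The YAML protection spec names protected metabolites/reactions, dof_min,
n_min, and scenarios built from linear constraint strings; the token
`FBA_MAX(reaction)` is resolved against the full model at load time, so
"99.9 % of the full model's optimum" never needs hard-coding (schema in
`src/netreduce/schemas/`). `netreduce bench` is opt-in and expects an
externally downloaded genome-scale SBML model; nothing is fetched
automatically.

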