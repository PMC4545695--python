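# Methods

## Model and scope

netreduce operates on constraint-based metabolic models: an m × n
stoichiometric matrix **N** over *internal* (balanced) metabolites, flux
bounds α ≤ r ≤ β, and a linear objective c. Steady state (**N r = 0**)
plus bounds define a flux polyhedron; flux balance analysis (FBA)
maximises cᵀr over it and flux variability analysis (FVA) computes each
reaction's attainable [min, max] rate. External (boundary) species impose
no constraint but are carried in a separate matrix so that compression can
surface them (e.g. a trace element folded into the condensed biomass
reaction). Gene–protein–reaction rules, thermodynamic/loopless
constraints, and kinetics are out of scope.

All linear programs go through scipy's HiGHS interface. The package
assumes the usual FBA idealisations: perfect steady state, a single
biomass/objective abstraction, and bounds that encode reversibility
(a reaction is reversible iff α < 0; SBML `reversible` attributes are
ignored when explicit FBC bounds exist).

## Protected specifications

A reduction is driven entirely by a protection spec:

* **protected metabolites** — must remain, each touched by ≥ 1 feasible
  (non-blocked) reaction;
* **protected reactions** — never deleted; optionally each must be able to
  carry nonzero flux in at least one protected scenario
  (`enforce_protected_feasibility`);
* **scenarios** (protected phenotypes) — inequality systems Dₖ r ≤ dₖ over
  named fluxes, each of which must stay satisfiable; ≥/= relations are
  normalised to ≤ at parse time, so constraint application is
  order-independent and idempotent;
* **dof_min / n_min** — floors on the degrees of freedom (n − rank N) and
  the reaction count. dof_min = 0 is accepted (a non-binding floor);
  n_min ≥ 1.

Constraint strings support linear expressions with literal coefficients
plus the `FBA_MAX(reaction)` token, resolved at load time by maximising
that reaction on the *full* model under the same scenario's bound
overrides and plain constraints. This keeps "fraction of the full-model
optimum" phenotypes exact and reproducible without hard-coded numbers; the
resolved values are logged and stored on the spec.

## Pruning loop

Preprocessing verifies every scenario is feasible on the full model,
errors out if a protected reaction can never carry flux (when enforced),
removes non-protected blocked reactions (base-bound FVA range [0,0] —
scenarios only tighten the polyhedron, so nothing a scenario could use is
lost), and drops unconnected metabolites.

Each iteration recomputes, for every removable reaction, the FVA range
under every scenario and the union's total width (with no scenarios the
full flux range is used). Reactions with a sign-definite range in *some*
scenario are essential and permanently leave the pool. Candidates are
tried in order of increasing width; on rejection the next-smallest
candidate from the *same* table is tried before any recomputation. A
trial deletes the column and re-tests all five specification classes
((a) protected-metabolite feasibility, (b) protected-reaction feasibility,
(c) scenario feasibility, (d) dof ≥ dof_min on the tentative model,
(e) n ≥ n_min); rejection leaves the original model object untouched, so
restoration is exact by construction. The loop stops when no remaining
candidate is deletable; unconnected metabolites are dropped at the end
(protected ones always kept).

Numerical choices: ε_flux = 1e-9 for zero/sign classification,
ε_feas = 1e-7 for constraint satisfaction, rank tolerance 1e-9 relative to
the largest singular value, and a flux cap of 1e5 for FVA directions that
are truly unbounded (internal cycles). Capped ranges carry flags; two
candidates tie-break by (finite width, number of capped ends, then a
seeded uniform draw — or lowest index under the `index` policy). The seed
is a first-class option and is written into the removal log, because
equal-width candidates (parallel pathways) make the pruned network
order-dependent and non-unique; only its *size and guarantees* are stable,
as the diamond fixture demonstrates. An opt-in `lazy_fva` mode reuses the
range table across accepted deletions until a rejection; it can change
(never invalidate) the trajectory and falls back to a fresh table before
concluding a fixed point.

Whether dof should be tested on the tentative or the accepted model was an
open design point; it is tested on the tentative model, so a deletion that
would undershoot dof_min is rejected outright.

## Compression

Enzyme subsets are detected from an orthonormal nullspace basis K of
**N**: reactions i, j are in one proportional class iff their kernel rows
are parallel (|cos| ≥ 1 − 1e-8); the ratio ρ = (Kⱼ·Kᵢ)/(Kᵢ·Kᵢ) is snapped
to a nearby small rational so toy stoichiometries stay exact. Structurally
blocked reactions (zero kernel rows) stay singletons. The FVA-fixing
characterisation (fix rᵢ, watch rⱼ collapse to a point) is retained as the
independent test oracle; the kernel route costs one SVD instead of O(n²)
LPs.

Each subset becomes one lumped reaction: the ratio-weighted column sum,
with S_out = S·T for the block transformation matrix T, internal
metabolites whose rows become all-zero deleted, and bounds the tightest
intersection of member bounds mapped through the ratios (the paperwork of
an always-valid representative-flux interval; an empty intersection is an
error). Degenerate cases: a class whose implied ratios would force an
irreversible member backward is split by ratio sign; a lump whose net
stoichiometry cancels completely (a perfect internal cycle) is left
unlumped — both choices are loss-free. Compression preserves dof exactly
and every FBA optimum (objective mapped as Tᵀc), and T expands compressed
flux vectors back to steady states of the input model.

Protected handling required one genuine design decision. Protected
reactions must survive compression with their identity, yet the condensed
biomass synthesis reaction is *defined* by absorbing the non-protected
synthesis chains that feed it. The rule implemented: a proportional class
contributes **at most one** protected reaction to a lump; that reaction
becomes the representative and the lumped reaction keeps its id; it is
absorbed only when doing so eliminates additional internal metabolites
(otherwise protected reactions stay out of lumps entirely); two protected
reactions are never merged; protected metabolites are never deleted even
with an all-zero row. This reproduces the condensed-BSR behaviour while
keeping every protected element nameable in the output.

## Fixtures and the random-network generator

The toy catalog pins down the documented behaviours: `worked_example`
(condensed BSR = 4 P + 2 ATP + 2 NADPH per biomass; the core embeds
independent P/ATP/NADPH drains so that only the chain, not the whole
network, is proportional), `diamond` (unique 4-reaction fixed point,
confirmed by exhaustive search over deletion orders), `oxidase_pair`
(2- vs 4-proton ubiquinol oxidase; the max-growth phenotype makes the
4-proton pump essential), `trace_element` (uptake + consumption collapse
into the BSR, surfacing the external species), and `cycle_unbounded`
(capped FVA flags).

The random generator emulates small metabolic networks: integer
stoichiometries in {±1, ±2}, a configurable density (default 2 internal
metabolites per reaction at m = 8), 30 % reversible reactions with ±1000
bounds, and 4 boundary exchanges, rejection-sampled until the network is
mass-connected and carries a nonzero steady-state flux. Property tests run
50 such networks of 12–20 reactions with a "preserve 99.9 % of one
reaction's optimum" phenotype — sizes chosen so the whole suite runs in a
few minutes on one CPU. These networks lack realistic features (no
cofactor pools, no compartments, no biomass hierarchy), so passing tests
certify the algorithmic guarantees (subnetwork property, optimum
preservation, loss-freeness, oracle agreement), not biological fidelity on
curated reconstructions.

Elementary-mode counting (classical tableau algorithm, ≤ 25 reactions) is
included purely as a validation statistic: compression must not change the
mode count, which the toy fixtures assert.

## Known limitations

* Pruning is greedy and order-dependent; it finds *a* minimal-by-inclusion
  subnetwork, not a minimum-cardinality one, and different seeds may keep
  different (equally valid) pathways.
* Unbounded FVA ranges are ranked via the cap-and-flag scheme; genuinely
  unbounded candidate widths are therefore compared at the cap.
* The LP layer rebuilds each program from scratch; fine at package scale,
  but genome-scale runs would benefit from a warm-started incremental
  backend behind the same interface.
* SBML export sanitises ids outside the SId alphabet (e.g. `*` in lumped
  names), keeping the original in the `name` attribute.
* External genome-scale benchmark models are user-supplied; the harness
  documents expected provenance and never downloads.
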