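# Methods

This note documents the models, algorithms, parameter choices and
limitations of glioma-gem in the package's own terms: what each stage
assumes, which knobs matter, what the synthetic study does and does
not emulate, and where design was genuinely open.

## Constraint-based core

All computations operate on the steady-state flux polytope
{v : S·v = 0, lb ≤ v ≤ ub}. Flux balance analysis maximizes the
biomass pseudo-reaction's flux; flux variability analysis minimizes
and maximizes each reaction independently with the biomass flux pinned
to at least a fraction f of its optimum. LPs are solved with HiGHS
through `scipy.optimize.linprog`.

Numerical choices:

- Feasibility tolerance τ_feas = 1e−9; flux-consistency threshold
  ε = 1e−4 (the FASTCORE-family convention). Both are configurable.
- At f = 1.0 the optimum constraint is relaxed to (1 − 1e−6)·z* so the
  optimal face itself stays numerically feasible — the standard FVA
  practice; without it, the pinned LP can be declared infeasible by
  round-off.
- FVA directions the solver reports unbounded are capped at the
  reaction's own box bounds; realistic reconstructions carry ±1000
  caps, so this is a formality.
- Exchange sign convention: an exchange is a single-metabolite
  reaction `met_e →`; positive flux releases, uptake is negative, and
  a medium entry with maximum uptake rate u sets the exchange lower
  bound to −u. Media are specified in rate units directly; no
  concentration-to-rate kinetic conversion is attempted, because no
  defensible conversion exists without uptake kinetics.

## Flux consistency

`find_consistent_subnetwork` returns the reactions able to carry
|v| ≥ ε in some steady state. Rather than two LPs per reaction, it
uses the FASTCORE-family block-detection strategy: one LP pushes all
irreversible reactions toward ε simultaneously (auxiliary variables
z_j ∈ [0, ε], z_j ≤ v_j, maximize Σz), then a shrinking worklist of
unresolved reactions is probed jointly and, when stuck, individually.
Probing the backward direction of a reversible reaction negates its
stoichiometric column and mirrors its bounds — swapping bounds alone
would still probe the forward direction, a subtlety the test suite
pins with an exhaustive per-reaction oracle on randomized networks.

## Context-specific extraction

Per sample, gene expression is discretized on log2(x+1) of the
nonzero-expression genes with a two-component Gaussian mixture; the
higher-mean component is "expressed". Calls: +1 if the posterior of
the expressed component is ≥ p_hi = 0.9, −1 if ≤ p_lo = 0.1, else 0
(unknown); zero-expression genes are −1. Gene calls map to reaction
calls through the GPR rules with AND → min and OR → max over
{−1, 0, +1}; empty-GPR reactions are unknown. Consensus over a sample
group calls a reaction core (inactive) when it is core (inactive) in
at least q = 0.9 of the samples. A pooled mode (majority-pool the gene
calls first, then map once) is available via config; per-sample
agreement is the default because it keeps the per-sample models
available for heterogeneity analysis.

Extraction is the two-LP FASTCORE scheme on the flux-consistent part
of the network: LP7 pushes as many uncovered core reactions as
possible above ε; LP10 finds a flux mode through the covered ones with
minimal L1 weight on non-core reactions; reversible core reactions
unreachable forward are retried with sign-flipped columns. Determinism
comes from processing reactions in sorted-id order. Reversible
handling uses bound-and-column flipping rather than splitting into
irreversible pairs: splitting creates spurious two-cycles
(v_fwd = v_bwd > 0 satisfies S·v = 0), which would make every split
reaction trivially "consistent".

The biomass objective, the ATP-demand reaction (when present) and the
medium's exchange reactions are force-included in the core — otherwise
no growth objective would survive extraction. Unknown reactions are
neither forced nor closed: they are available to the extractor but
penalized, so they enter a model only when the core needs them.
Consensus-inactive reactions are closed before extraction. Core
reactions that are flux-inconsistent under the medium (e.g. the
exchange of a nutrient whose transporter the group does not express)
are dropped with a log note rather than treated as an error.

## Exchange profiling

Each exchange of a growing model is profiled at f = 1.0 (presets 0.95
and 0.9 are provided; relaxing f can only widen ranges). The
narrow-bounded flag compares the optimal-growth range with the
**attainable** range of the same reaction — the FVA range with the
growth constraint removed — and calls the exchange narrow when the
ratio is ≤ 0.10, boundary inclusive. The attainable-range denominator
was an open choice (the raw bound span is the alternative, available
via flag); it is the default because it makes the ratio medium-aware:
an exchange capped at 5 by the medium and fixed at 5 by growth is
maximally informative, not 0.5% of a ±1000 box. A reaction with zero
attainable range is reported narrow (fully fixed), not as a division
error. Cross-model comparison emits a long table with per-metabolite
presence (a metabolite absent from a model is "absent", never zero),
directionality, uptake ranks and pan/specific narrowness labels.

## Essentiality and drug screening

Gene knockouts close every reaction whose GPR evaluates false without
the gene; growth ratios are clipped to [0, 1]; essential means
grRatio ≤ 0.5 with an inclusive boundary ("at least 50%" growth
reduction), lethal means grRatio ≤ τ_feas. Drugs delete their whole
target set jointly (union semantics for combinations, overlaps
logged); drugs with no target in a model's genes have effect 0.
Combination candidates pair FDA-category drugs that are not lethal
singles with AntiBC/IAG partners; a drug lethal in *any* screened
subtype model is excluded from all pairs, giving one deterministic
candidate list across models. Bliss classification uses the
excess-over-expectation form with tolerance δ = 0.05 (the margin is
not quantified in the literature the defaults follow; a ratio-form
index is available by config). The safety check applies the joint
deletion to the healthy-control model and requires both maximal ATP
demand and maximal biomass to retain ≥ 95% (η = 0.05) of wild type.

## Prioritization

Evidence arrives as curated TSVs; nothing is mined automatically.
Potency is the median IC50 across cell lines after averaging duplicate
(drug, line) records. Tier rules (all boundaries inclusive, encoded in
a replaceable `RulesConfig`): in vitro effective iff median viability
reduction ≥ 50% or potency at most the AntiBC reference median;
xenograft effective iff median growth reduction ≥ 25%; clinical
effective iff any two-arm record of phase ≥ I/II reports an improved
primary survival outcome, with contradictions resolved by majority and
ties conservatively to ineffective (logged). CSF LogBB is preferred
over binary BBB permeability when both exist. Ranking is lexicographic
— effective-tier count, DDI severity (none < minor/unknown < major;
combinations only), potency ascending, LogBB descending, id — so it is
a deterministic total order, stable under record shuffling and
invariant to uniform IC50 rescaling. Candidates with no tested tier
are listed last, flagged, and carry no rank; exclusion-flagged drugs
(cofactor of target, proliferation-inducing) never enter the ranking
and appear once each in the audit log.

## The synthetic study

The generator builds a ~60-reaction toy reconstruction (a carbon
backbone with ATP demand, a growth-limiting nutrient, four biomass
precursors with single, subtype-split, and redundant gated routes, a
free side nutrient and ~10 decoy uptake–convert–excrete paths with
randomized GPR shapes and group activity), a rate-valued medium,
bimodal expression (silent ≈ LogNormal(log 1, 0.5), expressed ≈
LogNormal(log 64, 0.5)) for k = 3 subtype groups × 8 samples plus 4
healthy-control samples, a 12-drug catalog and evidence tables.
Planted truths: the growth-limiting uptake is narrow everywhere and a
subtype-specific nutrient uptake is narrow only in S1; each group has
a known essential-gene set; one redundant-route target pair is
synergistic in all groups ("pan") and a second only in S1, both
bypassed in the control model so they pass the safety check; a lethal
single FDA drug is excluded from combinations; evidence plants fix the
per-tier calls, exclusions and the DDI-driven rank order.
`verify_scenario` re-derives every claim by brute force (per-gene KO
LPs, pair KOs, exchange FVA, tier classification) on the intended
group sub-networks — defined directly from the planted active-gene
sets, independent of the extraction pipeline.

Problem sizes used throughout (toy network ~62 reactions, 8 samples
per group, 20 seeds for the essentiality sweep, 200 randomized
networks for the solver cross-checks, 50 planted extraction toys) were
chosen so the full suite and the acceptance script run comfortably on
one CPU while still exercising every code path with non-trivial LPs.

What the toy does *not* emulate — and hence what passing tests do not
show about real data: human-reconstruction scale and GPR complexity,
real CSF composition, expression noise structure (dropout, batch
effects, within-subtype heterogeneity), partial growth-reduction
knockouts at realistic frequencies, or curated-database target
coverage. Results on real cohorts additionally depend on biomass
formulation and GPR curation quality, which dominate essentiality
accuracy in practice.

## Known limitations

- No thermodynamic or loop-law constraints; FVA ranges may include
  loop fluxes on networks with internal cycles.
- Knockouts are binary; no dose–response modelling.
- FASTCORE-style extraction is greedy-compact, not globally minimal;
  on pathological networks the extracted set can exceed the true
  minimum (the planted toys in the tests have unique minima by
  construction).
- The consensus threshold q, the discretization posteriors and the
  Bliss tolerance δ are study-level choices; none can be estimated
  from the data the pipeline sees.
- Clinical tier calls reduce trial evidence to a single
  improved/not-improved bit per record; no survival modelling is
  attempted.
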