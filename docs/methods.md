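# Methods

This note documents the models, conventions and numerical choices in
`rootscope`, the reasoning behind the genuinely open design decisions,
and what the synthetic benchmarks do and do not demonstrate.

## Network expansion (the scope)

A network is a set of reactions, each a pair of metabolite *sets*
(reactants, products) with a reversibility flag. Semantics are Boolean
reachability:

- stoichiometric coefficients are ignored — on draft networks without
  gap-filling or curation, qualitative producibility is the defensible
  question and flux balance is not attempted;
- a reversible reaction is treated as two independent directed
  reactions (standard network-expansion convention);
- a reaction with an empty reactant set fires at the first sweep; the
  generators never emit such reactions unless a model explicitly wants
  an unconditional source;
- metabolite identifiers are compared verbatim, compartment suffixes
  included. Cross-organism exchange presumes one shared namespace, and
  rewriting ids silently would corrupt community scopes; the SBML
  layer therefore escapes/unescapes ids reversibly instead of munging
  them.

Expansion runs in synchronous sweeps: every pending direction whose
reactants are all available fires, the union of fired products is
added, and iteration continues until no pending direction can fire.
The result is the least fixed point, independent of reaction order and
monotone in the seed set. `n_iterations` counts sweeps and is bounded
by the number of directions, since each counted sweep retires at least
one.

**Seed counting convention.** The returned producible set excludes the
seeds except where a fired reaction (re)produces a seed, in which case
it counts — "producible" describes products of fired reactions, and
this is the only convention under which seed-monotonicity holds (if
seeds were excluded unconditionally, seeding an already-producible
compound would shrink the result). A consequence worth spelling out:
for a reversible `x ↔ y` seeded with `{y}`, the reverse direction
yields `x`, after which the forward direction fires and regenerates
`y`, so the scope is `{x, y}`. An `include_seeds` flag adds the seeds
unconditionally for callers who want the closure instead.

The unconstrained *potential* of a network is the union of
product-sides over all allowed directions — everything the repertoire
could conceivably emit under some nutrient regime.

## Communities

A community's meta-GEM is the union of member repertoires with
reaction ids prefixed by the owner (identical reaction content carried
by two members is deliberately kept twice; membership bookkeeping
matters for enumeration). From the meta-GEM scope and the members'
individual scopes under the same seeds:

- *added value* = community scope − union of individual scopes,
- *core (CPPM)* = intersection of individual scopes,
- *cooperative gain* = 100 · |added value| / |union of individual
  scopes| (undefined, and raised as such, when no member produces
  anything).

## Growth media

A medium is a named nutrient set with category `poor` (mainly mineral)
or `rich` (more carbon sources). A registry-wide cofactor list is
added to every medium at registration; the shipped default
({ATP, NAD, NADP, CO-A, WATER, PROTON}) is a documented placeholder
for the ubiquitous carriers most seed-set conventions grant, and is a
registry-level input precisely because conventions differ.

Every base medium has an ARE-enriched sibling (`name+ARE`): nutrients
unioned with the registry's artificial-root-exudate set. The default
ARE composition is 3 sugars + 3 organic acids + 3 amino acids, the
amino acids being serine, alanine and glutamate — exactly the three
excluded from the amino-acid targets, since the medium would supply
them. Enriching an already-enriched medium is an error, keeping the
base/enriched pairing one-to-one. No global media count is asserted
anywhere: registries are data-driven.

**Validity rules for target analyses.** A medium is inadmissible for a
target group when (1) a target of that group appears among its
nutrients, or (2) the medium contains a blacklisted *mixture*
ingredient (tryptone, yeast extract, peptone, casamino acids by
default) whose implied content covers the group. The shipped
implication map — tryptone/peptone/casamino acids → amino acids; yeast
extract → amino acids + vitamins; unmapped mixtures block everything —
reproduces the usual laboratory-media taxonomy (an LB-style broth stays
admissible only for phytohormones). The map is data, overridable in the
media file. Validation is total: it reports violations and per-group
admissibility and never raises.

In the production-fraction matrix, inadmissible (medium, target) cells
are *masked* (serialized as null), never 0 — a zero would silently
poison downstream summaries with answers to meaningless questions.

## Target registry

Thirty focal end products in three disjoint groups: 17 proteinogenic
amino acids (20 minus Ser/Ala/Glu), 8 B vitamins (thiamine
diphosphate, riboflavin, nicotinate, (R)-pantothenate, pyridoxine,
biotin, tetrahydrofolate, adenosylcobalamin), 5 phytohormones (auxin,
salicylic acid, abscisic acid, ethylene, jasmonic acid). Identifiers
are MetaCyc-style where the mapping is standard; auxin is registered
as indole-3-acetate (one id per target, synonyms resolved at load).
The whole registry is best-effort and overridable from JSON, since
different reconstruction pipelines emit different synonyms.

## Minimal communities

Given a community, seeds and targets (targets may never appear among
the seeds), the *achievable* set T\* is the intersection of the targets
with the full community's cooperative scope. The enumeration returns
**all** subsets of minimum cardinality whose merged scope covers T\*
jointly — one community must cover everything achievable, not
per-target communities — by iterative deepening over subset size.
Cardinality is the only minimized quantity.

Soundness of the pruning: a member is dropped before enumeration only
if every direction it carries either cannot fire even with the whole
community's scope available (by monotonicity, then in no subset
either) or produces only seed metabolites; such a member contributes
nothing to any subset's scope, so no true solution is lost. Subsets
are tested by expanding pooled per-member direction lists (identical
set semantics to merging, without object construction) with an early
exit once T\* is covered.

The worst case is exponential, so a `max_subsets` budget bounds the
number of subsets examined; exhausting it sets an explicit `truncated`
flag on the result rather than returning a silently partial answer.
Solutions are reported in lexicographic order of sorted member ids;
target tiers are *individual* (some single member's scope contains
it), *cooperative* (only the community reaches it) or *unproducible*;
frequency tables sort by descending count with ties broken by id.

## SynCom sampling and regression

SynComs are drawn uniformly without replacement from the organism
pool: sizes 2–20 in steps of 1, 500 replicates per size, all
randomness from a single seeded generator. Repeated member sets across
replicates are permitted — uniform resampling is unbiased and the
simplest defensible design. Per sample the record holds S (size), P
(mean pairwise patristic distance, unscaled branch-length sums — no
ultrametric normalization), G (mean genome size, bp), and the two
counts: Y₁ = |union of members' unconstrained potentials| and Y₂ =
|intersection|. The union is the right community potential here: with
no seeds applied, no cooperative added value can arise, so merged and
unioned potentials coincide. A flagged whole-pool row is appended.
Samples touching an organism without a recorded genome size are
skipped, warned about, and counted in the run report.

The two GLMs model Y₁ and Y₂ with log link and variance φμ: IRLS with
the Poisson deviance (relative tolerance 1e-8, at most 100 iterations,
non-convergence is an error), dispersion φ estimated as Pearson
χ²/df, standard errors inflated by √φ, and pseudo-R² = 1 − residual
deviance / null deviance (defined as 0 for a constant response, whose
null deviance is 0). Records above 12 members are excluded by default:
the count responses plateau there, and beyond the plateau additional
sizes only replicate the same information. P² enters as the raw
square, not an orthogonal polynomial — the sign pattern, which is the
scientifically interpreted quantity, is invariant to that choice and
the raw parametrization is the simpler to document. Degree-2 is where
the model stops because the observed response is a single hump or
plateau; higher orders would fit sampling noise.

## Other statistics

- **Cliff's delta**: (#{xᵢ>yⱼ} − #{xᵢ<yⱼ})/(nm), ties contribute 0.
- **Jaccard distance** on sets, with the empty-vs-empty case defined
  as 0; **Bray–Curtis** on non-negative count vectors (negative counts
  and two all-zero vectors are errors).
- **Complete linkage** is implemented directly so the tie-break is
  pinned (lowest index pair at equal heights); it agrees with scipy's
  implementation on tie-free inputs, which the tests assert.
- **PCoA** is classical scaling: eigendecomposition of the
  double-centered −½D², axes ordered by eigenvalue, only positive
  eigenvalues kept as coordinates while the full spectrum (including
  negatives from non-Euclidean distances) is returned for inspection.
  Axis signs are fixed by making the largest-magnitude loading
  positive.
- **PERMANOVA** partitions ΣSS (sum over pairs of d²/n) into between-
  and within-group parts; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)
  with label permutations from an injected generator, so runs are
  reproducible; R² = SS_between/SS_total. Singleton groups are
  rejected. scikit-bio's implementation serves as an independent
  cross-check in the tests, never as the implementation.
- The conventional significance threshold in the analysis scripts
  is 0.01.

## The synthetic generator

`make_community` emulates the statistical structure of a
root-microbiome culture collection at desk scale. Defaults
("demo193-mini"): 20 organisms, 300 metabolites, ~60 reactions per
organism, 8 mineral seed compounds.

- **Phylogeny**: a Kingman-style coalescent (exponential waiting
  times), so trees are random, ultrametric and have realistic depth
  ~1; taxonomy labels (phylum/class) derive from the root bipartition
  and the next splits, giving the PERMANOVA demos honest group
  structure.
- **Layered reaction pool**: metabolites are ordered; every reaction's
  reactants sit strictly below its products, with the lowest layer
  being the minerals. Substrates are drawn with an exponential bias
  toward the low layers (`precursor_bias` = 0.05 of the universe as
  e-folding) — the funneling of biosynthesis through a handful of
  central precursors. Without this bias, mineral-seeded scopes are
  only 2–3 compounds deep and media comparisons degenerate; with it,
  roughly a quarter to a half of an organism's potential is reachable
  from a full mineral medium.
- **Inheritance**: a shared core (30 % of the pool) is kept by
  everyone; each accessory reaction is lost on any tree edge with
  probability 1 − exp(−phylo_decay · branch length), and a leaf
  retains it only if no loss occurred on its root path. Loss events on
  shared edges are shared, so repertoire dissimilarity grows with
  patristic distance for *any* leaf pair (Spearman ρ ≈ 0.9 at the
  defaults) — the property the SynCom analysis assumes. The root
  plays the role of the reference point from which divergence
  accumulates.
- **Private reactions** (~10 % of the mean, spread controlled by the
  dispersion parameter) differentiate even identical twins; genome
  size is 500 kb + 25 kb per reaction with 5 % lognormal noise, so
  genome size and repertoire size correlate strongly, as in real
  collections.
- **Media suites** draw supplements (rich-media extras, ARE set,
  cofactors) with the same central bias — root exudates and broth
  carbon are central metabolites — and every rich medium strictly
  contains a poor medium, making the poor ⊂ rich monotonicity checks
  meaningful.
- **Focal targets**, when a reference medium is supplied, are drawn
  half from compounds some member produces individually under it and
  half from the community's added value. This mirrors the profile of
  curated focal compounds (core products most organisms encode, a few
  requiring exchange) and keeps minimal communities small; drawing
  targets uniformly from the potential instead yields deep, rarely
  reachable compounds and minimal communities of most of the pool.
- **Planted cross-feeding**: `plant_split_pathway` inserts a linear
  chain from a medium compound to a fresh target with fresh
  intermediates, its segments distributed over chosen organisms
  (redundant copies allowed). Because the intermediates exist nowhere
  else, the minimal covering sets are exactly the planted assignments
  — an instance with a known answer for the enumerator.

**What the generator does not emulate**, and hence what passing tests
do not show about real data: stoichiometry and cofactor balance,
compartments and transport, a curated pathway ontology (chains are
random, not named pathways), annotation error structure (false
negatives correlated within pathways), horizontal gene transfer
(inheritance is strictly vertical), realistic genome sizes or reaction
counts (both are ~25× smaller than real GEMs), and real media
compositions. Results on synthetic communities validate the
*algorithms* and the qualitative mechanisms, not quantitative claims
about any real collection.

## Numerical choices and degenerate inputs

- GLM: IRLS tolerance 1e-8, max 100 iterations; rank-deficient designs
  and n < p + 2 are errors; dispersion is NaN when residual df is 0.
- Expansion: all set operations on frozensets; outputs serialized in
  sorted order everywhere, so identical inputs give byte-identical
  files.
- PCoA eigenvalue cutoff: 1e-10 relative to the leading eigenvalue.
- Empty cases are explicit: empty reaction set → empty potential (not
  an error); no producing member → cooperative gain raises; no
  achievable target → a no-solution result object, not an exception;
  gain with empty added value → exactly 0.

## Problem sizes

The test and acceptance workloads are sized to be decisive yet quick:
200 random networks (≤100 metabolites, ≤150 reactions) for oracle
equivalence, 100 random ≤12-member communities for exhaustive
enumeration agreement, 100 planted instances (2–4 segments), 500
randomized monotonicity checks, 20 × n=2000 regression replicates, 500
null PERMANOVA simulations at 999 permutations, and the full 9 500
sample SynCom study on the 20-organism default scenario. The whole
suite runs in well under a minute on one CPU.

## Known limitations

- Reachability ignores stoichiometric balance, so scopes are an upper
  bound on what a flux-consistent model would produce.
- Cardinality-minimal communities say nothing about exchange cost or
  direction; mutualistic and unidirectional cross-feeding are not
  distinguished.
- The minimal-community search is exponential in the worst case; the
  subset budget makes failure explicit rather than fast.
- Whether the union of all-target runs equals the concatenation of
  per-group runs is configuration-dependent; both are supported and
  neither is asserted equal to the other.
- The quasi-Poisson fit reports the Pearson dispersion; for responses
  that are nearly deterministic functions of the covariates (as in
  small synthetic universes) φ can fall below 1, which is legitimate
  under-dispersion, not an error.
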