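# Methods

## Problem setting

Environmental-diversity (ED) surrogates select sites spanning continuous
environmental space, betting that environmental distance predicts
species-composition difference. `edselect` implements the two standard ED
selectors — greedy maximum dispersion and continuous p-median — together with
the Species Accumulation Index (SAI) benchmark that scores any selector
between a random baseline and a near-optimal reference.

## Synthetic landscapes

Real atlas or inventory data are site × environment and site × species
tables; the generator emulates their statistical structure.

**Environment.** Each of n sites gets latent coordinates z ~ N(0, I_L) in an
L-dimensional gradient space (default L = 3). Observed variable v in type
group g is x_v = w_vᵀ z + ε, ε ~ N(0, noise_sd²); the unit loading w_v mixes
a direction shared by group g with a per-variable random direction
(`loading_jitter`, default 0.5), so within-group correlations exceed
between-group ones, as in real multicollinear predictor stacks. Defaults: 38
variables in five groups (temperature 11, precipitation 8, insolation 8,
NDVI 4, topography 7), noise_sd = 0.3, n = 300 sites.

**Species.** Species j has a Gaussian (unimodal) niche: center c_j sampled
uniformly over the per-axis bounding box of the latent coordinates, breadth
σ_j ~ U(0.5, 1.5) in latent units, and occurrence probability at site i of
max_prevalence · exp(−‖z_i − c_j‖² / 2σ_j²), with max_prevalence = 0.9 so
even a site at the niche center is not a guaranteed record (imperfect
detection). Presence is one Bernoulli draw per site × species; a species left
with zero occurrences is assigned presence at the site nearest its center, so
species counts are stable across seeds. Default 120 species.

These defaults define the package's reference study conditions. The
max_prevalence and per-group variable counts were fixed once as field-typical
values; the remaining defaults are the reference configuration used
throughout the tests.

The latent coordinates are exposed for testing only. The analysis pipeline
sees the noisy observed variables and must rediscover the gradients via PCA —
with three latent axes and 38 noisy readouts, Kaiser retention recovers three
components on typical draws.

**What the generator does not emulate:** spatial autocorrelation in
geographic space, survey-effort gaps, species interactions, and non-Gaussian
(skewed or bimodal) niches. Passing tests show the machinery works where the
ED premise holds by construction; they say nothing about how strongly real
landscapes satisfy that premise.

## Environmental spaces

- **CVT subsetting.** Five fixed combinations of variable types: CVT1 = all
  five types; CVT2 = temperature + precipitation + NDVI; CVT3 = temperature +
  precipitation + topography; CVT4 = temperature + precipitation; CVT5 =
  insolation + topography. Requesting a CVT whose types are absent is an
  error.
- **PCA.** On the correlation matrix (variables standardized to zero mean,
  unit variance) — the Kaiser eigenvalue > 1 rule is only meaningful there.
  Retained coordinates are the component scores. If no eigenvalue exceeds 1
  (possible only for near-orthogonal designs), the largest component is kept
  and flagged rather than failing, so parameter sweeps stay runnable.
  Component signs are fixed by making each component's largest-magnitude
  loading positive. Zero-variance columns must be dropped by the caller (the
  pipeline does this and logs it).
- **NMDS.** Nonmetric SMACOF (scikit-learn) minimizing Kruskal stress-1 in
  2-D, initialized from classical (Torgerson) metric scaling of the input
  distances plus a seeded jitter of 10⁻⁴ × max distance to break degeneracy;
  deterministic given the seed; default cap 300 iterations, convergence
  tolerance 10⁻⁹. The input is the Euclidean distance matrix in retained-PCA
  space, so the 2-D embedding reflects full-PCA-space distances. Stress is
  reported; an independent stress-1 evaluator (isotonic regression of
  configuration distances on input dissimilarity ranks) is provided for
  checking embeddings.

## Maxdisp selector

Objective: ∑ over selected pairs of 1/d²ᵢⱼ, minimized subject to selecting
exactly m sites. Conventions where the objective alone is silent:

- initialization is the maximum-distance pair — the exact optimum at m = 2 —
  keeping the whole procedure deterministic;
- each subsequent step adds the site with the smallest marginal
  ∑_{s selected} 1/d²ᵢₛ;
- coincident sites contribute a finite sentinel 1/ε² with ε = 10⁻¹²
  (coordinate units) instead of infinity, so duplicated sites are maximally
  penalized but objectives remain comparable;
- ties break to the lowest site index;
- m = 1 returns the most isolated site (maximum of the minimum distance to
  all others), objective 0.

The swap-based "interchange" variant is deliberately not implemented; greedy
addition mirrors incremental reserve acquisition and performs comparably.

## Continuous p-median selector

Demand is uniform over environmental space: each NMDS axis range [min, max]
is split into g equal intervals (g = 50, i.e. 2,500 demand points) and every
cell centroid is a demand point, including cells holding no sites. Grid
bounds are the observed coordinate extrema with no padding. Cost of a
selection = ∑ over demand points of the Euclidean distance to the nearest
selected site.

The solver is a GRASP-like multistart heuristic:

1. **Construction** (per start): greedy insertion where each addition is
   drawn uniformly from the 3 best candidates by cost reduction (seeded).
2. **Local search**: vertex substitution with first-improvement in seeded
   candidate order; for a candidate insertion the best paired removal is
   found in O(#demand) from nearest/second-nearest bookkeeping (Whitaker's
   profit computation). A swap is applied when it improves cost by more than
   10⁻⁹; `max_swaps` (default 10,000) caps the total.
3. **Recombination**: the `elite_size` best distinct local optima are
   combined pairwise — union of the two selections, greedily reduced back to
   p by repeatedly dropping the site whose removal increases cost least, then
   re-polished by local search.

Defaults: 32 starts, elite pool of 10. All randomness flows from one seed
through a spawned seed sequence, so results are reproducible and independent
of iteration order. On small instances (n ≤ 12, p ≤ 3) the heuristic matches
exhaustive enumeration in ≥ 95% of seeded trials (it is a heuristic; global
optimality is not guaranteed).

## SAI benchmark

- **S** — species represented at least once in the surrogate selection.
- **R** — mean species count of 1,000 seeded uniform p-site subsets. The
  closed form E = ∑_j [1 − C(n−n_j, p)/C(n, p)] (n_j = occupancy of species
  j) and the exact variance (via pairwise joint miss probabilities from site
  -set unions) are implemented as oracles for the Monte-Carlo estimate.
- **O** — by default the top-p prefix of a core-area reverse stepwise
  ranking: repeatedly remove the site minimizing
  δ_i = max_{j present at i} 1/(remaining occurrences of j), ties to the
  lowest index; removal order reversed is the priority ranking. This is the
  core-area prioritization rule specialized to binary occurrences with unit
  weights and costs (cell-removal rate, warp, and boundary terms collapse or
  sit at neutral values). Because it is itself heuristic, greedy maximum
  coverage and exact enumeration (feasible for C(n,p) ≤ 10⁶) are provided as
  alternatives and dominance oracles.
- **SAI** = (S − R)/(O − R). O = R yields an explicit undefined flag (NaN);
  O < R raises, since the optimum heuristic failed to beat the random mean.
- **Fraction sweep** — p = round(fraction · n), floored at 1, at fractions
  15%, 20%, 25%, 30%, 35%; the summary is the median SAI over fractions with
  defined values (undefined fractions are flagged, warned about, and
  excluded; all-undefined is an error).

## Pipeline and reproducibility

`run_pipeline` composes: input (files or synthetic block) → CVT subset →
drop zero-variance columns → PCA → maxdisp on PCA distances, or NMDS →
demand grid → p-median → fraction sweep → CSV report and provenance sidecar.
One root seed fans out to per-stage seeds by fixed offsets (environment +11,
species +23, NMDS +37, p-median +53, baseline +71, mod 2³¹), so each stage is
independently reproducible and a report regenerates bit-identically from its
logged configuration.

## Problem sizes

The reference synthetic configuration (300 sites, 120 species, 38 variables)
runs the maxdisp pipeline in well under a second and the p-median pipeline in
about a minute (five fractions × 32 starts against 2,500 demand points); the
test suite exercises the p-median solver mainly on reduced grids and start
counts, which the solver's determinism makes equivalent in coverage.

## Known limitations

- The p-median solver is a stand-in for GRASP-with-path-relinking solvers; it
  shares the multistart + elite-recombination design but not their exact
  moves, so selected sets can differ from other software even at equal cost.
- The core-area O is heuristic; exact enumeration is exponential and only
  used as a small-instance oracle. When O falls below R the fraction is
  flagged rather than silently clamped.
- NMDS stress depends on the initialization; only one (seeded) start is run
  per embedding. Degenerate duplicate sites are permitted throughout, handled
  by the maxdisp sentinel and by zero-distance columns in the p-median cost.
- SAI compares selectors at equal p only; it does not account for site costs,
  connectivity, or complementarity weighting.
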