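# edselect

Environmental-diversity (ED) surrogate site selection for conservation
planning, with benchmarking against random and near-optimal baselines.

When true species distributions are unknown, ED strategies pick survey or
reserve sites that span *environmental* space, on the assumption that
environmentally distant sites differ in species composition. `edselect`
implements and compares the two main ED selectors:

- **Greedy maximum dispersion (maxdisp)** — select m sites minimizing
  ∑_{i<j} 1/d²ᵢⱼ over selected pairs, where dᵢⱼ is the Euclidean distance in
  the retained-PCA environmental space. Works in any number of dimensions;
  the greedy heuristic adds one site per step.
- **Continuous p-median** — embed sites in 2-D by nonmetric multidimensional
  scaling (NMDS), lay a 50 × 50 grid of "demand points" over the ordination,
  and select p sites minimizing ∑ over demand points of the distance to the
  nearest selected site. Solved by a multistart hybrid heuristic (randomized
  greedy construction, vertex-substitution local search, recombination of an
  elite pool; defaults 32 starts, elite 10).

Selector quality is scored with the **Species Accumulation Index**

    SAI = (S − R) / (O − R)

where S is the species count represented by the surrogate selection, R the
mean count of random selections of the same size (1,000 Monte-Carlo
replicates, with an exact hypergeometric oracle), and O a near-optimal count
from a core-area reverse stepwise ranking (greedy maximum coverage and exact
enumeration are available as cross-checks). SAI is computed at 15–35% of the
landscape and summarized by the median of the five fractions: 1 ≈ optimal,
0 ≈ random, negative = worse than random.

Environmental tables carry per-variable type tags (temperature,
precipitation, insolation, NDVI, topography) and can be subset into the five
standard combinations of variable types, CVT1 (all) through CVT5
(insolation + topography), before PCA with Kaiser retention (eigenvalue > 1).

A synthetic-data module generates landscapes where the ED premise holds by
construction — noisy, group-correlated environmental variables read out from
a low-dimensional latent gradient space, and species with unimodal (Gaussian)
niches in that space — so the whole pipeline is testable without field data.

## Worked example

Generate a 150-site landscape with 60 species, then evaluate maxdisp ED on
the climate + topography variables (CVT3):

```sh
edselect simulate --n-sites 150 --n-species 60 --seed 11 --out-dir demo
edselect run --config run.yaml
```

with `run.yaml`:

```yaml
environment_path: demo/environment.csv
presence_path: demo/presence_absence.csv
cvt: CVT3
approach: maxdisp
reps: 1000
seed: 11
```

prints

```
 fraction  p  S      R  O      SAI flag
     0.15 23 43 39.463 60 0.172226
     0.20 30 47 42.211 60 0.269211
     0.25 38 50 44.606 60 0.350396
     0.30 45 53 46.245 60 0.491094
     0.35 53 56 47.848 60 0.670836
median SAI = 0.3504
```

Reading the 25% row: selecting 38 of 150 sites by maxdisp represents 50 of
the 60 species; random 38-site selections represent 44.6 on average and the
best achievable is all 60, so the surrogate realizes 35% of the possible
improvement over random. Rerunning with `approach: pmedian` on the same
tables gives a median SAI of 0.1568 — here the 2-D collapse required by the
demand grid costs the p-median approach part of the environmental signal that
maxdisp retains by working in the full 3-component PCA space.

The same pipeline is available as a library:

```python
import edselect as ed

land = ed.generate_environment(ed.LandscapeConfig(seed=1))
pa = ed.generate_species(land.latent, ed.NicheConfig(seed=2))
pca = ed.pca_kaiser(land.environment)
dist = ed.euclidean_distances(pca)
selector = lambda p: ed.greedy_maxdisp(ed.SelectionProblem(dist, p)).selected
report = ed.fraction_sweep(pa, selector, reps=1000, seed=3)
print(report.to_frame(), report.median_sai)
```

Subcommands `simulate`, `ordinate`, `select`, `evaluate` and `run` expose the
individual stages; every stage seed is derived from one root seed and logged,
so any report regenerates bit-identically.

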