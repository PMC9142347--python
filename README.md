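# metstab

Multi-environment-trial (MET) statistics for small plant-breeding
programs — written for the kind of participatory organic wheat breeding
network where 50 genotypes enter replicated trials at two or three
locations, a selection funnel thins them over five years, and the same
lines are later judged by farmers and artisan bakers.

The package answers the questions such a program actually asks:

* **What is each genotype worth in each environment?**
  Per-environment BLUEs from the mixed model
  `y_ijkl = mu + G_i + b_j + R_k + C_l + e_ijkl`
  with genotype fixed and block, row and column random; the row/column
  spatial terms enter only when they improve the REML AIC.
* **How much of the genetic signal survives a change of environment?**
  REML variance decomposition of the crossed all-random model
  `y = mu + G + L + A + LA + block(LA) + GL + GA + GLA + e`
  (L = location, A = year), with each genetic component expressed as a
  share of the total genetic variance `s2_G + s2_GL + s2_GA + s2_GLA`.
* **How heritable is the trait on an entry-mean basis?**
  `H2 = s2_g / (s2_g + s2_ga/n_a + s2_gl/n_l + s2_gal/n_al + s2_e/n_alr)`
  with harmonic-mean divisors computed from the realized (funnel-unbalanced)
  observation incidence.
* **Which genotypes are stable?** Finlay–Wilkinson joint regression
  (sensitivity `beta_i` of each genotype on the environment mean, with
  per-genotype R²) and Wricke's ecovalence
  `W_i = sum_j (y_ij - ybar_i. - ybar_.j + ybar_..)^2`,
  plus a "no extremes" re-analysis after dropping extreme seasons.
* **Which genotype wins where?** GGE analysis: SVD of the
  environment-centered BLUE table, biplot coordinates, and mega-environments
  grouped by winning genotype.
* **Do any lines beat the check on-farm?** Dunnett many-to-one comparison
  with familywise-adjusted p-values from the k-variate t distribution of
  all genotype-minus-check contrasts (A = superior, B = inferior, ns).
* **What do the bakers think?** Evaluator score models
  `score = mu + G_i + evaluator_j (+ stage_k) + e` that separate genotype
  quality from evaluator severity on 10-point (baker) and 5-point (taster)
  scales.

Because plot-level data from real programs are rarely public, the package
ships a first-class synthetic generator (`simulate_met`, `simulate_fw`,
`simulate_scores`) that reproduces the full crossed stochastic structure
of these models and returns every drawn true effect, so the whole pipeline
is testable end-to-end by parameter recovery.

The crossed REML engine is implemented in the package itself (profiled
restricted likelihood on the Woodbury form with analytic gradients, exact
strata-based fast path for balanced layouts): crossed random effects of
this kind are not expressible in the grouped mixed-model interfaces of the
usual Python statistics stack.

## Worked example

```python
import metstab as ms
from metstab.quantgen import heritability, incidence_counts, variance_proportions

cfg = ms.SimulationConfig(seed=7)   # 50 genotypes x 2 locations x 5 years x 3 reps
plots, _ = ms.simulate_met(cfg)

vc = ms.estimate_variance_components(plots, "yield_kg_ha")
shares = variance_proportions(vc)
h2 = heritability(vc, incidence_counts(plots, "yield_kg_ha"))
```

prints (see `examples/03_variance_and_heritability.py`):

```
shares of total genetic variance (G + GL + GA + GLA):
  G     60.3%
  GL    10.5%
  GA     0.0%
  GLA   29.2%

entry-mean heritability H2 = 0.821
harmonic-mean divisors: years 5.0, locations 2.0, env 10.0, plots 30.0
```

The G share is the fraction of genetic variance that transfers across
environments (here the generator's truth is 54%, and a single 5-year
network estimates it with the spread the strata degrees of freedom allow);
H² = 0.82 says entry means computed over this network are sharp enough for
selection. The `examples/` directory has one short script per capability
(simulation, BLUEs and spatial correction, variance/heritability,
stability, GGE, Dunnett, baking scores, full pipeline); each prints the
numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
metstab simulate --config sim.yaml --out plots.csv
metstab blues --plots plots.csv --trait yield_kg_ha --env L1:2019 --out blues.csv
metstab run --config pipeline.yaml
```

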