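# Methods

## Models

All analyses are built on Gaussian linear mixed models with independent
random effects (all covariances between effects are zero).

**Per-environment genotype means.** Within one environment (a location-year),
`y_ijkl = mu + G_i + b_j + R_k + C_l + e_ijkl` with genotype `G_i` fixed and
block `b_j ~ N(0, s2_b)`, row `R_k ~ N(0, s2_R)`, column `C_l ~ N(0, s2_C)`
random. Row and column are post-blocking controls for field trends; they are
candidates, not defaults — the four inclusion combinations are fitted with
identical fixed effects (so restricted likelihoods are comparable) and the
lowest REML AIC wins, ties going to the smaller model. AIC admits a boundary
variance term with roughly 8% probability per candidate under the null; a
likelihood-ratio mode (50:50 chi²₀/chi²₁ mixture threshold at 5%) is
available for users who want a stricter gate. Genotype estimates are the
model's estimated marginal means (equal weight over the levels of any other
fixed factor, random effects at zero). Incomplete blocks of augmented alpha
designs are carried by the same random block term; unreplicated entries are
adjusted through the block/row/column effects estimated from the replicated
checks, which is exactly the GLS solution and is tested against an explicit
dense solve.

**Variance decomposition.** Across the network,
`y = mu + G + L + A + LA + block(LA) + GL + GA + GLA + e` with every term
random. The genetic shares reported are each genetic component divided by
`s2_G + s2_GL + s2_GA + s2_GLA`; location, year, block and residual variances
never enter that denominator. Reduced scopes drop the location terms
(per-location) or all but genotype and block (per-environment).

**Entry-mean heritability.**
`H2 = s2_g / (s2_g + s2_ga/n_a + s2_gl/n_l + s2_gal/n_al + s2_e/n_alr)`.
The divisors are harmonic means of the *realized* per-genotype counts of
years, locations, location-years and plots, not nominal design counts: a
selection funnel leaves late-surviving genotypes with many observations and
early casualties with few, and harmonic means are the right average for the
variance of an unbalanced mean. Genotypes with zero observations are dropped
and reported, never imputed. No standard error for H² is provided.

**Stability.** Two-stage Finlay-Wilkinson: the environment index is the
per-environment mean of the BLUEs over genotypes present in every
environment (complete-case index), centered; each genotype's BLUEs are then
regressed on the index by OLS. The slope is the sensitivity (0 = static,
~1 = dynamic, >1 = hypersensitive; default class bands 0.5 / 0.8–1.2), R² is
the squared correlation of fitted and observed. On a complete table the
slopes average exactly 1. Wricke's ecovalence is the standard
double-centering form `W_i = sum_j (y_ij - ybar_i. - ybar_.j + ybar_..)^2`,
whose genotype-wise sum is the two-way interaction SS; an additive table
gives every `W_i = 0`. W is reported in raw squared trait units — the
`x 10^6` display convention for yield is left to report formatting.

**GGE.** Column (environment) centering only, no SD scaling by default (a
`scale` flag offers it); SVD with a deterministic sign convention (largest
|genotype score| per axis made positive) so repeated fits are byte-identical.
Biplot coordinates use the singular-value partition `U D^f`, `V D^(1-f)`,
default `f = 0.5`. Which-won-where winners are computed on the exact
centered matrix; the rank-2 polygon-sector winners of the visual convention
are reported alongside but treated as a display approximation.

**Dunnett comparison-to-check.** Within a trial, genotype fixed and block
random, no spatial terms (on-farm strip trials cannot support them). All
genotype-minus-check contrasts are formed from the marginal means and their
covariance; adjusted p-values are `1 - P(max|T| <= |t_i|)` under the central
k-variate t with the contrasts' estimated correlation and the classical
ANOVA error degrees of freedom `n - rank([X Z])` (e.g. `(g-1)(r-1)` in an
RCBD) — the choice that keeps the test exactly calibrated in balanced
two-replicate designs, where the df is painfully small and is therefore
reported prominently. Comparisons are two-sided; both per-mean and
per-difference standard errors are emitted because published summary tables
are ambiguous about which they print.

## REML engine

The restricted likelihood of `y ~ N(X tau, sum_r s2_r Z_r Z_r' + s2_e I)` is
profiled over `s2_e` and maximised over log variance ratios
`gamma_r = s2_r / s2_e` with analytic gradients (L-BFGS-B; a bounded scalar
search when only one component is present). Each evaluation uses the
Woodbury identity, costing one Cholesky factorisation of the q x q matrix
`Gamma^{-1} + Z'Z` (q = total random levels), so a 1,500-plot network with
~950 levels fits in well under a second. Convergence: relative change of the
criterion below 1e-12, projected gradient below 1e-7, at most 500 iterations;
the restricted log-likelihood follows the Patterson-Thompson convention (it
matches lme4's `logLik` and is verified against a frozen lme4 fit to 1e-4).

Nonnegativity is handled by an explicit boundary profile: components whose
ratio falls below 1e-6 are removed, the reduced model is refitted, and the
reduction is kept when its restricted likelihood is no worse; such
components are reported as exactly zero with a `clamped` flag. Fixed-effect
estimates at the optimum are the GLS solution at the estimated covariance
(asserted against dense-matrix oracles); a rank-deficient fixed design
raises an error naming the aliased columns.

**Balanced fast path.** A complete balanced RCBD network is a full
(genotype x location x year x replicate) crossing, so the covariance is
simultaneously diagonalised by the factorial contrast subspaces: the
restricted likelihood separates into ANOVA strata
`sum_U [df_U log(lam_U) + SS_U / lam_U]` with
`lam_U = s2_e + sum_{T >= U} c_T s2_T`. `estimate_variance_components`
detects balance and optimises this closed form (same parameter space, same
nonnegativity constraints, identical likelihood — equality with the general
engine is asserted in tests), which makes 200-replicate recovery studies a
matter of seconds. Any unbalance (funnel selection, missing plots) falls
back to the general engine.

**Multivariate-t probabilities** for the Dunnett procedure are evaluated by
quasi-Monte-Carlo integration (scipy's Genz-Bretz implementation) with a
fixed generator seed and point budget (50,000 by default, ~3e-5 integration
error; raised to 1e6 where quantile-grade accuracy is needed), making every
p-value bit-for-bit reproducible. k = 1 uses the exact t distribution.

## Synthetic data

The generator draws every effect of the models above from independent
zero-mean Gaussians and returns the draws, so each estimator is tested by
parameter recovery. Defaults emulate a small organic hard winter wheat
network on a grain-yield scale: mu = 2800 kg/ha; genetic variances
54,000 / 9,000 / 12,000 / 25,000 (kg/ha)² for G / GL / GA / GLA — shares of
54 / 9 / 12 / 25% of the genetic total, a strong-main-effect trait —
environmental variances 400,000 (location), 600,000 (year), 1,200,000
(location-year), 20,000 (block), and 150,000 residual (plot CV ~ 14%,
typical of organic yield trials). The optional funnel (50 -> 42 -> 24 ->
16 -> 16) truncates on observed cumulative trait means; the real program's
multi-trait judgment calls are not reproducible, so truncation on one trait
stands in for them. RCBD layouts place each block on its own band of field
rows with randomized genotype order; augmented layouts replicate only the
checks in every incomplete block. Scores are clipped to their scale bounds
(the models treat scores as continuous; the clipping fraction is reported so
users can see when the Gaussian approximation is strained).

One master seed spawns a named substream per effect component, so adding a
component never perturbs the others, and identical configs are
byte-identical.

What the generator does *not* emulate — spatially correlated error beyond
independent row/column effects, non-Gaussian trait distributions, missing
plots from winterkill, genotype-specific error variances, ordinal score
granularity — bounds what passing tests show: they certify the estimators
under the models' own assumptions, not robustness to field pathologies
beyond them. Mid-season killed plots are treated as missing, with an
explicit flag philosophy (never silently zero-filled); winter-survival
percentages are the trait that carries that information instead.

## Problem sizes and numerical choices

Simulation studies in the test suite use the sizes the models are meant
for: recovery studies at 50 genotypes x 2 locations x 5 years x 3
replicates (200 replicates via the strata fast path), joint-regression
recovery at 20 genotypes x 10 environments, Dunnett calibration on
7-genotype two-rep trials with a 10,000-trial null study against a
1e6-draw Monte-Carlo max-|t| oracle, and evaluator panels of 6 bakers x 8
genotypes. The G-share coverage envelope ([0.3, 0.5] around a truth of
0.4) sits within about one Monte-Carlo standard error of its 80% pass mark
at these sizes — the share estimator's spread is set by the strata degrees
of freedom of the design itself, so the check is a sharp one.

Percentile selection uses linear-interpolation percentiles with strict
"above"; threshold rules are strict "below"; top-n keeps boundary ties.
The FHB severity map (0/6.7/13.3/50/75/100% for spike scores 0-5) is a
15-spikelet reading of the standard visual anchors and is configurable.
FW needs at least 3 environments per genotype; ecovalence and GGE require
complete tables (environments with missing cells can be dropped
explicitly; no EM imputation).

## Known limitations

* Standard errors use residual degrees of freedom without small-sample
  (Kenward-Roger-type) adjustment; with two replicates they are honest but
  coarse, and the df is surfaced everywhere rather than hidden.
* No spatial correlation models (AR1xAR1) — row/column effects are
  independent; no heterogeneous residual variances per environment; no
  Bayesian fitting.
* No AMMI, superiority index, or non-parametric rank stability; no
  confidence intervals for H² or for variance shares.
* The score models treat bounded ordinal scores as continuous Gaussian;
  heavy clipping (visible in the reported clip fraction) will bias
  variance components toward zero.
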