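"""Dunnett many-to-one comparison of genotypes against a named check.

Within one trial, a mixed model with fixed genotype and random block is
fitted (no spatial terms: on-farm strip trials are too small to support
them), all genotype-minus-check contrasts are formed, and familywise
adjusted p-values are computed from the k-variate t distribution of the
max-|t| statistic with the contrasts' estimated correlation structure.

The multivariate-t box probabilities are evaluated by quasi-Monte-Carlo
integration with a fixed generator seed and a fixed point budget, so every
p-value is bit-for-bit reproducible across runs.  Residual degrees of
freedom are the classical ANOVA error df, n - rank([X Z]) (e.g. (g-1)(r-1)
in an RCBD), which keeps the test exactly calibrated in the balanced
two-replicate on-farm designs where df is painfully small — the df is
reported prominently in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import EnvironmentKey, PlotTable
from .reml import ModelSpec, RemlError, reml_fit
from .synthetic import SimulationConfig, simulate_met

__all__ = ["DunnettResult", "dunnett_test", "fwer_simulation"]

_MVT_SEED = 271828  # fixed QMC stream for reproducible box probabilities
_MVT_MAXPTS = 50_000  # ~3e-5 QMC error; raise for quantile-grade accuracy


def _max_abs_t_prob(c: float, R: np.ndarray, df: int,
                    maxpts: int = _MVT_MAXPTS) -> float:
    """P(max_i |T_i| <= c) for a central k-variate t with correlation R."""
    k = R.shape[0]
    if c <= 0:
        return 0.0
    if k == 1:
        return float(2.0 * stats.t.cdf(c, df) - 1.0)
    x = np.full(k, float(c))
    return float(stats.multivariate_t.cdf(
        x, shape=R, df=df, lower_limit=-x,
        random_state=np.random.default_rng(_MVT_SEED), maxpts=maxpts))


def critical_value(R: np.ndarray, df: int, alpha: float,
                   maxpts: int = _MVT_MAXPTS) -> float:
    """Two-sided equicoordinate quantile: P(max|T| <= c) = 1 - alpha."""
    if alpha <= 0.0:
        return np.inf
    if alpha >= 1.0:
        return 0.0
    lo = float(stats.t.ppf(1 - alpha / 2, df))      # unadjusted bound (too small)
    hi = float(stats.t.ppf(1 - alpha / (2 * 2 * R.shape[0]), df)) + 1.0  # > Bonferroni
    return float(optimize.brentq(
        lambda c: _max_abs_t_prob(c, R, df, maxpts) - (1 - alpha),
        lo * 0.99, hi, xtol=1e-6))


@dataclass
class DunnettResult:
    """Genotype-vs-check comparisons for one trial."""

    check: str
    trait: str
    alpha: float
    df: int                         # residual (ANOVA error) degrees of freedom
    table: pd.DataFrame             # per genotype: mean, se_mean, diff, se_diff,
                                    # t, p_adj, label
    critical_t: float               # equicoordinate |t| quantile at alpha
    critical_difference: float      # critical_t x median se_diff (Table-style row)
    sigma2_e: float


def _trial_frame(plots: PlotTable, trait: str,
                 environment: EnvironmentKey | None) -> pd.DataFrame:
    sub = plots.subset(environment=environment, trait=trait).df
    sub = sub[np.isfinite(sub["value"])]
    return sub.reset_index(drop=True)


def _anova_error_df(df: pd.DataFrame, random_terms: tuple[str, ...]) -> int:
    """n - rank([X Z]): classical error df with all factors in the mean space."""
    n = len(df)
    mats = [np.ones((n, 1)), pd.get_dummies(df["genotype"]).to_numpy(float)]
    for term in random_terms:
        mats.append(pd.get_dummies(df[term]).to_numpy(float))
    return n - int(np.linalg.matrix_rank(np.concatenate(mats, axis=1)))


def _dunnett_core(df: pd.DataFrame, check_id: str, include_block: bool = True):
    """Fit the trial model and return contrasts, SEs, t stats, R and df."""
    if check_id not in set(df["genotype"]):
        raise RemlError(f"check genotype {check_id!r} not present in trial")
    if df["genotype"].nunique() < 2:
        raise RemlError("need at least 2 genotypes")
    random_terms: tuple[str, ...] = ()
    if include_block and df["block"].nunique() > 1:
        random_terms = ("block",)
    dof = _anova_error_df(df, random_terms)
    if dof < 1:
        raise RemlError("no residual degrees of freedom (single replicate overall)")
    fit = reml_fit(df, ModelSpec("value", ("genotype",), random_terms))
    labels, est, cov = fit.emmeans_full("genotype")
    idx0 = labels.index(check_id)
    others = [i for i in range(len(labels)) if i != idx0]
    C = np.zeros((len(others), len(labels)))
    for r, i in enumerate(others):
        C[r, i] = 1.0
        C[r, idx0] = -1.0
    dcov = C @ cov @ C.T
    diffs = C @ est
    se = np.sqrt(np.diag(dcov))
    R = dcov / np.outer(se, se)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    t = diffs / se
    return fit, labels, est, cov, others, diffs, se, t, R, dof


def dunnett_test(plots: PlotTable, trait: str, check_id: str,
                 alpha: float = 0.05, environment: EnvironmentKey | None = None,
                 include_block: bool = True, maxpts: int = _MVT_MAXPTS) -> DunnettResult:
    """Compare every genotype in a trial against the check genotype.

    Two-sided comparisons with familywise error control at ``alpha``: the
    adjusted p-value of each contrast is ``1 - P(max|T| <= |t_i|)`` under
    the joint k-variate t distribution of all contrasts.  Labels follow the
    usual summary convention: ``A`` significantly superior to the check,
    ``B`` significantly inferior, ``ns`` otherwise; the check's own row
    carries a zero difference and ``ns``.

    Both the per-mean and the per-difference standard errors are reported
    (summary tables in the field are ambiguous about which they print).
    """
    df = _trial_frame(plots, trait, environment)
    fit, labels, est, cov, others, diffs, se, t, R, dof = _dunnett_core(
        df, check_id, include_block)

    p_adj = np.array([1.0 - _max_abs_t_prob(abs(ti), R, dof, maxpts) for ti in t])
    p_adj = np.clip(p_adj, 0.0, 1.0)
    crit = critical_value(R, dof, alpha, maxpts)

    se_mean = np.sqrt(np.diag(cov))
    rows = []
    k = 0
    for i, g in enumerate(labels):
        if i in others:
            d, s, ti, pi = diffs[k], se[k], t[k], p_adj[k]
            label = "ns"
            if pi < alpha:
                label = "A" if d > 0 else "B"
            k += 1
        else:
            d, s, ti, pi, label = 0.0, np.nan, np.nan, np.nan, "ns"
        rows.append({"genotype": g, "mean": est[i], "se_mean": se_mean[i],
                     "diff": d, "se_diff": s, "t": ti, "p_adj": pi, "label": label})
    table = pd.DataFrame(rows)
    cd = crit * float(np.median(se))
    return DunnettResult(check_id, trait, alpha, dof, table, crit, cd, fit.sigma2_e)


def fwer_simulation(config: SimulationConfig, check_id: str, alpha: float,
                    n_sims: int, include_block: bool = True) -> dict:
    """Empirical familywise error rate of the Dunnett procedure under the null.

    Requires ``config.sigma2_g == 0`` (global null: all genotypes equal).
    Simulates ``n_sims`` trials, applies the Dunnett rejection rule at
    ``alpha`` and reports the fraction of trials with at least one
    rejection, with a 95% Clopper-Pearson interval.  The per-comparison
    unadjusted t-test familywise rate is reported as a sanity contrast.

    The critical value is computed once from the common design (the
    correlation structure and df are identical across balanced simulated
    trials), so each simulation only needs its max-|t| statistic.
    """
    if config.sigma2_g != 0:
        raise ValueError("fwer_simulation requires a global-null config (sigma2_g = 0)")
    seeds = (np.random.SeedSequence(config.seed).generate_state(n_sims)
             & 0x7FFFFFFF).astype(int)

    crit = None
    t_crit_unadj = None
    n_reject = 0
    n_reject_unadj = 0
    for s in seeds:
        cfg = SimulationConfig(**{**config.__dict__, "seed": int(s),
                                  "funnel": config.funnel})
        plots, _ = simulate_met(cfg)
        df = plots.df[np.isfinite(plots.df["value"])]
        env = plots.environments[0]
        df = df[(df["location"] == env.location) & (df["year"] == env.year)]
        _, _, _, _, _, _, _, t, R, dof = _dunnett_core(
            df.reset_index(drop=True), check_id, include_block)
        if crit is None:
            crit = critical_value(R, dof, alpha)
            t_crit_unadj = (stats.t.ppf(1 - alpha / 2, dof)
                            if alpha > 0 else np.inf)
        mt = float(np.max(np.abs(t)))
        n_reject += int(mt > crit)
        n_reject_unadj += int(mt > t_crit_unadj)

    ci = stats.binomtest(n_reject, n_sims).proportion_ci(0.95, method="exact")
    return {
        "fwer": n_reject / n_sims,
        "ci_low": float(ci.low), "ci_high": float(ci.high),
        "fwer_unadjusted": n_reject_unadj / n_sims,
        "n_sims": n_sims, "alpha": alpha,
        "critical_t": float(crit) if crit is not None else np.nan,
        "df": dof,
    }
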