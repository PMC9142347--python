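"""The package's three mixed-model families, built on the REML engine.

* :func:`estimate_blues` — per-environment genotype BLUEs with random
  block and optional row/column spatial post-blocking, the inclusion of
  which is decided by :func:`select_spatial_terms`.
* :func:`estimate_variance_components` — the crossed all-random
  genotype x location x year decomposition (with block nested in
  environment), the currency of heritability and variance-share summaries.
* :func:`fit_score_model` — evaluator panels: fixed genotype, random
  evaluator and (optionally) baking stage.

For completely balanced MET layouts the variance decomposition uses an
exact closed-form restricted likelihood over the ANOVA strata of the
four-way (genotype, location, year, replicate) crossing, which is
identical to the general engine's criterion but evaluates in microseconds;
the general engine handles every unbalanced case.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import BlueMatrix, EnvironmentKey, PlotTable, ScoreRecord, scores_to_frame, two_way_table
from .reml import ModelSpec, RemlError, RemlFit, reml_fit

__all__ = [
    "VarianceComponents",
    "BluesResult",
    "ScoreModelResult",
    "estimate_blues",
    "blues_all_environments",
    "select_spatial_terms",
    "estimate_variance_components",
    "fit_score_model",
]


@dataclass
class VarianceComponents:
    """The named variance components of the crossed MET decomposition.

    Components absent from a reduced-scope model are ``None``.  All values
    are in squared trait units.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_l: float | None = None
    sigma2_a: float | None = None
    sigma2_la: float | None = None
    sigma2_block: float | None = None
    sigma2_gl: float | None = None
    sigma2_ga: float | None = None
    sigma2_gla: float | None = None
    scope: str = "all"
    trait: str | None = None
    clamped: frozenset = frozenset()
    loglik: float | None = None
    method: str = "general"

    def total_genetic(self) -> float:
        """sigma2_G + sigma2_GL + sigma2_GA + sigma2_GLA (absent terms as 0)."""
        return sum(v or 0.0 for v in
                   (self.sigma2_g, self.sigma2_gl, self.sigma2_ga, self.sigma2_gla))

    def as_dict(self) -> dict[str, float | None]:
        return {
            "G": self.sigma2_g, "L": self.sigma2_l, "A": self.sigma2_a,
            "LA": self.sigma2_la, "block": self.sigma2_block, "GL": self.sigma2_gl,
            "GA": self.sigma2_ga, "GLA": self.sigma2_gla, "residual": self.sigma2_e,
        }


@dataclass
class BluesResult:
    """Per-genotype BLUEs for one environment."""

    environment: EnvironmentKey
    trait: str
    table: pd.DataFrame            # columns: genotype, blue, se
    fit: RemlFit
    excluded: list[str]            # genotypes absent from the environment
    selection: pd.DataFrame | None = None  # spatial-term selection audit table


@dataclass
class ScoreModelResult:
    """Genotype BLUEs on the score scale plus panel variance components."""

    table: pd.DataFrame            # columns: genotype, blue, se
    evaluator_variance: float | None
    stage_variance: float | None
    sigma2_e: float
    fit: RemlFit


def _env_frame(plots: PlotTable, trait: str, environment: EnvironmentKey) -> pd.DataFrame:
    sub = plots.subset(environment=environment, trait=trait).df
    sub = sub[np.isfinite(sub["value"])]
    return sub.reset_index(drop=True)


def select_spatial_terms(
    df: pd.DataFrame,
    response: str = "value",
    fixed: tuple[str, ...] = ("genotype",),
    base_random: tuple[str, ...] = (),
    candidates: tuple[str, ...] = ("row", "column"),
    criterion: str = "aic",
):
    """Decide which row/column post-blocking terms enter the model.

    Fits every subset of ``candidates`` on top of ``base_random`` (the fixed
    part is identical across candidates, so the restricted likelihoods are
    comparable) and selects by REML AIC, breaking ties toward the smaller
    model.  ``criterion="lrt"`` instead keeps a term when it improves
    -2*logLik by more than the 5% threshold of the 50:50 chi2(0)/chi2(1)
    boundary mixture.  Returns ``(chosen_random_terms, audit_table)``.
    """
    rows = []
    fits: dict[tuple[str, ...], RemlFit] = {}
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            terms = tuple(base_random) + combo
            try:
                fit = reml_fit(df, ModelSpec(response, fixed, terms))
            except (RemlError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"candidate model {terms} failed: {exc}", stacklevel=2)
                continue
            n_var = len(terms) + 1
            rows.append({
                "extra_terms": "+".join(combo) if combo else "(none)",
                "n_extra": len(combo), "minus2_reml": fit.minus2_reml,
                "aic": fit.minus2_reml + 2.0 * n_var,
            })
            fits[combo] = fit
    if not fits:
        raise RemlError("all candidate spatial models failed")
    table = pd.DataFrame(rows)

    if criterion == "aic":
        best = min(table["aic"])
        tied = table[table["aic"] <= best + 1e-9]
        pick = tied.sort_values(["n_extra", "extra_terms"]).iloc[0]
    elif criterion == "lrt":
        base = table[table["n_extra"] == 0]["minus2_reml"].iloc[0]
        thresh = 2.705543454095404  # 5% point of 0.5*chi2(0) + 0.5*chi2(1)
        keep = table[(table["n_extra"] > 0) & (base - table["minus2_reml"] > thresh)]
        pick = (keep.sort_values("minus2_reml").iloc[0] if len(keep)
                else table[table["n_extra"] == 0].iloc[0])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    combo = () if pick["extra_terms"] == "(none)" else tuple(pick["extra_terms"].split("+"))
    table = table.assign(chosen=table["extra_terms"] == pick["extra_terms"])
    return tuple(base_random) + combo, table


def estimate_blues(
    plots: PlotTable,
    trait: str,
    environment: EnvironmentKey,
    spatial: str | tuple[str, ...] = "auto",
    include_block: bool = True,
    selection_criterion: str = "aic",
) -> BluesResult:
    """Spatially corrected genotype BLUEs for one environment.

    The model has genotype fixed and block random (when the trial is
    replicated), with row and/or column random terms added when ``spatial``
    is ``"auto"`` and their inclusion improves the REML AIC.  Genotype
    estimates are the marginal means of the fitted model; unreplicated
    entries in augmented designs are adjusted through the block/row/column
    effects estimated from the replicated checks.  Genotypes absent from
    the environment are excluded and listed, never imputed.
    """
    df = _env_frame(plots, trait, environment)
    if len(df) == 0:
        raise RemlError(f"no observations for {trait} in {environment}")
    excluded = sorted(set(plots.genotypes) - set(df["genotype"]))

    base: tuple[str, ...] = ()
    if include_block and df["block"].nunique() > 1:
        base = ("block",)

    selection = None
    if spatial == "auto":
        candidates = tuple(c for c in ("row", "column") if df[c].nunique() > 1)
        if candidates and len(df) > df["genotype"].nunique() + 1:
            random_terms, selection = select_spatial_terms(
                df, fixed=("genotype",), base_random=base,
                candidates=candidates, criterion=selection_criterion)
        else:
            random_terms = base
    elif spatial == "none":
        random_terms = base
    else:
        random_terms = base + tuple(spatial)

    fit = reml_fit(df, ModelSpec("value", ("genotype",), random_terms))
    em = fit.emmeans("genotype").rename(columns={"estimate": "blue"})
    return BluesResult(environment, trait, em, fit, excluded, selection)


def blues_all_environments(plots: PlotTable, trait: str, spatial="auto") -> BlueMatrix:
    """Run :func:`estimate_blues` in every environment and assemble the
    genotype x environment :class:`BlueMatrix`."""
    records = []
    for env in plots.environments:
        sub = plots.subset(environment=env, trait=trait).df
        if not np.isfinite(sub["value"]).any():
            continue
        res = estimate_blues(plots, trait, env, spatial=spatial)
        for rec in res.table.itertuples(index=False):
            records.append((env, rec.genotype, rec.blue, rec.se))
    return two_way_table(records)


# ---------------------------------------------------------------------------
# variance components


_TERM_AXES = {
    "genotype": frozenset({0}),
    "location": frozenset({1}),
    "year": frozenset({2}),
    "location:year": frozenset({1, 2}),
    "env_block": frozenset({1, 2, 3}),
    "genotype:location": frozenset({0, 1}),
    "genotype:year": frozenset({0, 2}),
    "genotype:location:year": frozenset({0, 1, 2}),
}

_VC_FIELD = {
    "genotype": "sigma2_g", "location": "sigma2_l", "year": "sigma2_a",
    "location:year": "sigma2_la", "env_block": "sigma2_block",
    "genotype:location": "sigma2_gl", "genotype:year": "sigma2_ga",
    "genotype:location:year": "sigma2_gla", "residual": "sigma2_e",
}


def _balanced_array(df: pd.DataFrame) -> np.ndarray | None:
    """Reshape a complete balanced RCBD MET to a (g, l, a, r) array, or None."""
    if df["value"].isna().any():
        return None
    gens = np.sort(df["genotype"].unique())
    locs = np.sort(df["location"].unique())
    years = np.sort(df["year"].unique())
    g, l, a = len(gens), len(locs), len(years)
    if min(g, l, a) < 2:
        return None
    counts = df.groupby(["location", "year"])["block"].nunique()
    if len(counts) != l * a or counts.nunique() != 1:
        return None
    r = int(counts.iloc[0])
    if r < 2 or len(df) != g * l * a * r:
        return None
    # each block must contain every genotype exactly once
    per_block = df.groupby(["location", "year", "block"])["genotype"].agg(["count", "nunique"])
    if not ((per_block["count"] == g) & (per_block["nunique"] == g)).all():
        return None
    work = df.copy()
    work["rep"] = work.groupby(["location", "year"])["block"].transform(
        lambda s: s.map({b: i for i, b in enumerate(np.sort(s.unique()))}))
    gi = pd.Categorical(work["genotype"], categories=gens).codes
    li = pd.Categorical(work["location"], categories=locs).codes
    ai = pd.Categorical(work["year"], categories=years).codes
    y4 = np.full((g, l, a, r), np.nan)
    y4[gi, li, ai, work["rep"].to_numpy(int)] = work["value"].to_numpy(float)
    if np.isnan(y4).any():
        return None
    return y4


def _strata_decomposition(y4: np.ndarray):
    """ANOVA strata (df, SS, per-term coefficient) of the balanced crossing.

    For each non-empty subset U of the four axes, the projection of the data
    onto the U-interaction contrast subspace has squared norm SS_U and
    dimension df_U, and the covariance eigenvalue on that subspace is
    sigma2_e + sum over random terms T containing U of c_T sigma2_T with
    c_T the number of observations per level of T.
    """
    dims = y4.shape
    axes = (0, 1, 2, 3)
    n = y4.size
    means: dict[frozenset, np.ndarray] = {}
    for k in range(5):
        for U in itertools.combinations(axes, k):
            Uf = frozenset(U)
            means[Uf] = y4.mean(axis=tuple(f for f in axes if f not in Uf), keepdims=True)
    strata = []
    terms = list(_TERM_AXES)
    for k in range(1, 5):
        for U in itertools.combinations(axes, k):
            Uf = frozenset(U)
            eff = np.zeros_like(means[Uf])
            for j in range(k + 1):
                for V in itertools.combinations(U, j):
                    eff = eff + (-1) ** (k - j) * means[frozenset(V)]
            df_U = int(np.prod([dims[f] - 1 for f in Uf]))
            if df_U == 0:
                continue
            ss = float(np.prod([dims[f] for f in axes if f not in Uf]) * np.sum(eff ** 2))
            coef = np.array([
                float(np.prod([dims[f] for f in axes if f not in _TERM_AXES[t]]))
                if Uf <= _TERM_AXES[t] else 0.0
                for t in terms])
            strata.append((df_U, ss, coef))
    return strata, terms, n


def _strata_reml(y4: np.ndarray):
    """Exact REML on a balanced complete layout via its strata likelihood."""
    strata, terms, n = _strata_decomposition(y4)
    dfs = np.array([s[0] for s in strata], float)
    sss = np.array([s[1] for s in strata], float)
    coefs = np.vstack([s[2] for s in strata])          # strata x terms
    scale = max(float(np.var(y4)), 1e-12)
    R = len(terms)

    def crit_parts(sig_terms, sig_e):
        lam = sig_e + coefs @ sig_terms
        return lam

    def objective(x, active):
        sig = np.zeros(R)
        sig[active] = np.exp(x[:-1])
        sig_e = np.exp(x[-1])
        lam = crit_parts(sig, sig_e)
        f = float(np.sum(dfs * np.log(lam) + sss / lam))
        w = dfs / lam - sss / lam ** 2
        grad_terms = (coefs.T @ w)[active] * sig[active]
        grad_e = float(np.sum(w)) * sig_e
        return f, np.append(grad_terms, grad_e)

    # method-of-moments start from the expected-mean-squares equations
    ms = sss / dfs
    A = np.column_stack([coefs, np.ones(len(ms))])
    sol, _ = optimize.nnls(A, ms)
    start = np.maximum(sol, scale * 1e-6)

    lo, hi = np.log(scale) - 30.0, np.log(scale) + 30.0

    def solve(active):
        x0 = np.log(np.append(start[active], start[-1]))
        res = optimize.minimize(
            objective, np.clip(x0, lo + 1, hi - 1), args=(active,), jac=True,
            method="L-BFGS-B", bounds=[(lo, hi)] * (len(active) + 1),
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
        sig = np.zeros(R)
        sig[active] = np.exp(res.x[:-1])
        return sig, float(np.exp(res.x[-1])), float(res.fun)

    active = list(range(R))
    sig, sig_e, fval = solve(active)
    clamped: set[str] = set()
    while True:
        low = [i for i in active if sig[i] < scale * 1e-7]
        if not low:
            break
        trial = [i for i in active if i not in low]
        sig2, sig_e2, f2 = solve(trial)
        if f2 <= fval + 1e-6:
            sig, sig_e, fval, active = sig2, sig_e2, f2, trial
            clamped |= {terms[i] for i in low}
        else:
            break
    sig[[i for i in range(R) if i not in active]] = 0.0

    loglik = -0.5 * (fval + (n - 1) * np.log(2 * np.pi) + np.log(n))
    variances = {t: float(s) for t, s in zip(terms, sig)}
    variances["residual"] = sig_e
    return variances, frozenset(clamped), loglik


def estimate_variance_components(
    plots: PlotTable,
    trait: str,
    scope: str = "all",
    location: str | None = None,
    environment: EnvironmentKey | None = None,
    use_fast_path: bool = True,
) -> VarianceComponents:
    """REML variance decomposition of a trait across the trial network.

    ``scope="all"`` fits the full crossed model (genotype, location, year,
    location x year, block within environment, and the three genotype
    interactions); it requires at least two locations and two years.
    ``scope="per_location"`` drops the location terms and
    ``scope="per_environment"`` additionally drops the year terms,
    mirroring the reduced analyses used for single-location and
    single-environment heritabilities.  Components estimated at the zero
    boundary are reported in ``clamped``.
    """
    df = plots.subset(trait=trait).df
    df = df[np.isfinite(df["value"])].copy()

    if scope == "all":
        n_loc, n_yr = df["location"].nunique(), df["year"].nunique()
        if n_loc < 2 or n_yr < 2:
            raise RemlError(
                "full model needs >= 2 locations and >= 2 years; "
                "use scope='per_location' or scope='per_environment'")
        if use_fast_path:
            y4 = _balanced_array(df)
            if y4 is not None:
                variances, clamped, ll = _strata_reml(y4)
                return VarianceComponents(
                    sigma2_g=variances["genotype"], sigma2_e=variances["residual"],
                    sigma2_l=variances["location"], sigma2_a=variances["year"],
                    sigma2_la=variances["location:year"], sigma2_block=variances["env_block"],
                    sigma2_gl=variances["genotype:location"], sigma2_ga=variances["genotype:year"],
                    sigma2_gla=variances["genotype:location:year"],
                    scope=scope, trait=trait, clamped=clamped, loglik=ll, method="strata")
        df["env_block"] = (df["location"] + ":" + df["year"].astype(str)
                           + ":" + df["block"])
        terms = ("genotype", "location", "year", "location:year", "env_block",
                 "genotype:location", "genotype:year", "genotype:location:year")
    elif scope == "per_location":
        if location is not None:
            df = df[df["location"] == location]
        df["env_block"] = df["year"].astype(str) + ":" + df["block"]
        terms = ("genotype", "year", "env_block", "genotype:year")
    elif scope == "per_environment":
        if environment is not None:
            df = df[(df["location"] == environment.location) & (df["year"] == environment.year)]
        terms = ("genotype", "block")
    else:
        raise ValueError(f"unknown scope {scope!r}")

    if len(df) == 0:
        raise RemlError(f"no observations for {trait} in requested scope")
    fit = reml_fit(df, ModelSpec("value", (), terms))
    v = fit.variances

    def get(term):
        return v.get(term)

    return VarianceComponents(
        sigma2_g=v["genotype"], sigma2_e=v["residual"],
        sigma2_l=get("location"), sigma2_a=get("year"), sigma2_la=get("location:year"),
        sigma2_block=get("env_block") if "env_block" in v else get("block"),
        sigma2_gl=get("genotype:location"), sigma2_ga=get("genotype:year"),
        sigma2_gla=get("genotype:location:year"),
        scope=scope, trait=trait, clamped=fit.clamped, loglik=fit.loglik, method="general")


def fit_score_model(records: list[ScoreRecord] | pd.DataFrame,
                    include_stage: bool = False) -> ScoreModelResult:
    """Genotype BLUEs from evaluator panel scores.

    Genotype is fixed; evaluator is random, and with ``include_stage`` the
    baking stage enters as an additional random term.  With a single
    evaluator the evaluator variance is unidentifiable and the model falls
    back to a fixed-effects fit (with a warning); the BLUEs are then the
    per-genotype score means.
    """
    df = records if isinstance(records, pd.DataFrame) else scores_to_frame(records)
    df = df.rename(columns={"evaluator_id": "evaluator", "genotype_id": "genotype"})
    df = df[np.isfinite(df["score"])].copy()
    n_eval = df["evaluator"].nunique()

    random_terms: tuple[str, ...] = ()
    if n_eval >= 2:
        random_terms += ("evaluator",)
    else:
        warnings.warn("single evaluator: evaluator variance not identifiable; "
                      "falling back to a fixed-effects fit", stacklevel=2)
    if include_stage:
        if df["stage"].isna().all():
            raise RemlError("include_stage=True but no stage information present")
        df["stage"] = df["stage"].fillna("(none)")
        if df["stage"].nunique() >= 2:
            random_terms += ("stage",)

    fit = reml_fit(df, ModelSpec("score", ("genotype",), random_terms))
    em = fit.emmeans("genotype").rename(columns={"estimate": "blue"})
    return ScoreModelResult(
        table=em,
        evaluator_variance=fit.variances.get("evaluator"),
        stage_variance=fit.variances.get("stage"),
        sigma2_e=fit.sigma2_e, fit=fit)
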