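"""Restricted maximum likelihood (REML) engine for crossed random effects.

Fits linear mixed models of the form

    y ~ N(X tau,  sum_r sigma2_r Z_r Z_r' + sigma2_e I)

where every random term ``r`` is a (possibly crossed or nested) grouping
factor with its own variance component.  This covers the three model
families used throughout the package:

* per-environment genotype means: fixed genotype, random block / row /
  column (post-blocking spatial control);
* multi-environment variance decomposition: all-random genotype, location,
  year, their interactions, and block within environment;
* evaluator score models: fixed genotype, random evaluator and baking stage.

The restricted likelihood is profiled over the residual variance and
maximised over the log variance ratios ``gamma_r = sigma2_r / sigma2_e``
with analytic gradients, using the Woodbury identity so that each
evaluation costs one Cholesky factorisation of a q x q matrix (q = total
number of random-effect levels).  Components that converge to the lower
boundary are profiled at exactly zero and flagged.

Crossed designs of this kind are not expressible in the grouped
random-effects interfaces of the common Python statistics packages, which
is why the engine is implemented here from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = ["ModelSpec", "RemlFit", "RemlError", "reml_fit"]

_LOG2PI = float(np.log(2.0 * np.pi))
_LOG_GAMMA_LO, _LOG_GAMMA_HI = -30.0, 30.0
_CLAMP_GAMMA = 1e-6  # variance ratio below which the zero boundary is profiled


class RemlError(RuntimeError):
    """Raised for singular designs or failed REML optimisation."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed_terms`` and ``random_terms`` name factor columns of the data
    frame; an interaction is written ``"a:b"``.  The intercept is implicit.
    No factor may appear on both sides.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))
        overlap = set(self.fixed_terms) & set(self.random_terms)
        if overlap:
            raise RemlError(f"terms {sorted(overlap)} are both fixed and random")


@dataclass
class RemlFit:
    """Result of a REML fit."""

    spec: ModelSpec
    variances: dict[str, float]        # per random term, residual under "residual"
    sigma2_e: float
    beta: pd.Series                    # fixed effects (treatment coding)
    cov_beta: pd.DataFrame
    loglik: float                      # restricted log-likelihood
    n_obs: int
    n_fixed: int
    n_iter: int
    converged: bool
    clamped: frozenset[str]            # random terms estimated at the zero bound
    trace: list[float] = field(default_factory=list)  # -2*loglik per accepted iterate
    _design: dict | None = None

    @property
    def minus2_reml(self) -> float:
        return -2.0 * self.loglik

    def emmeans_full(self, factor: str):
        """Estimated marginal means for one fixed factor with full covariance.

        Other fixed factors are averaged with equal weight over their levels;
        random effects enter at their population mean (zero).  Returns
        ``(levels, estimates, covariance)``.
        """
        d = self._design
        if d is None or factor not in d["fixed_levels"]:
            raise RemlError(f"{factor!r} is not a fixed factor of this model")
        rows, labels = [], []
        for level in d["fixed_levels"][factor]:
            L = np.zeros(len(self.beta))
            L[0] = 1.0
            for name, (fac, lev, n_lev) in d["column_info"].items():
                j = d["column_index"][name]
                if fac == factor:
                    L[j] = 1.0 if lev == level else 0.0
                else:
                    L[j] = 1.0 / n_lev
            rows.append(L)
            labels.append(level)
        L = np.asarray(rows)
        est = L @ self.beta.to_numpy()
        cov = L @ self.cov_beta.to_numpy() @ L.T
        return labels, est, 0.5 * (cov + cov.T)

    def emmeans(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means for one fixed factor, as a table."""
        labels, est, cov = self.emmeans_full(factor)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return pd.DataFrame({factor: labels, "estimate": est, "se": se})


def _factor_codes(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    for p in parts:
        if p not in df.columns:
            raise RemlError(f"term {term!r} references missing column {p!r}")
    key = df[parts[0]].astype(str)
    for p in parts[1:]:
        key = key + ":" + df[p].astype(str)
    levels, codes = np.unique(key.to_numpy(), return_inverse=True)
    return codes, list(levels)


def _build_fixed(df: pd.DataFrame, spec: ModelSpec):
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    fixed_levels: dict[str, list[str]] = {}
    column_info: dict[str, tuple[str, str, int]] = {}
    for term in spec.fixed_terms:
        codes, levels = _factor_codes(df, term)
        fixed_levels[term] = levels
        for j, lev in enumerate(levels[1:], start=1):
            cols.append((codes == j).astype(float))
            name = f"{term}[{lev}]"
            names.append(name)
            column_info[name] = (term, lev, len(levels))
    X = np.column_stack(cols)
    # rank check with aliased-column diagnosis
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * len(df) * np.finfo(float).eps if diag.size else 0.0
    aliased = [names[i] for i in np.where(diag <= tol)[0]]
    if aliased:
        raise RemlError(f"singular fixed-effects design; aliased columns: {aliased}")
    design = {
        "fixed_levels": fixed_levels,
        "column_info": column_info,
        "column_index": {name: i for i, name in enumerate(names)},
    }
    return X, names, design


def _build_random(df: pd.DataFrame, spec: ModelSpec):
    Zs, sizes = [], []
    for term in spec.random_terms:
        codes, levels = _factor_codes(df, term)
        q = len(levels)
        Z = np.zeros((len(df), q))
        Z[np.arange(len(df)), codes] = 1.0
        Zs.append(Z)
        sizes.append(q)
    return Zs, sizes


class _RemlProblem:
    """Profiled REML criterion on the Woodbury form, with analytic gradient."""

    def __init__(self, y, X, Zs, sizes):
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.sizes = sizes
        self.Z = np.concatenate(Zs, axis=1) if Zs else np.zeros((self.n, 0))
        self.q = self.Z.shape[1]
        self.slices = []
        off = 0
        for s in sizes:
            self.slices.append(slice(off, off + s))
            off += s
        self.S = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ X
        self.Zty = self.Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, gamma: np.ndarray):
        ginv = np.concatenate([np.full(s, 1.0 / g) for s, g in zip(self.sizes, gamma)]) \
            if self.q else np.zeros(0)
        M = self.S + np.diag(ginv)
        cM = linalg.cho_factor(M, lower=True, check_finite=False)
        AX = linalg.cho_solve(cM, self.ZtX, check_finite=False)
        ay = linalg.cho_solve(cM, self.Zty, check_finite=False)
        XtHiX = self.XtX - self.ZtX.T @ AX
        XtHiy = self.Xty - self.ZtX.T @ ay
        ytHiy = self.yty - self.Zty @ ay
        cB = linalg.cho_factor(XtHiX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cB, XtHiy, check_finite=False)
        ypy = float(ytHiy - XtHiy @ beta)
        ypy = max(ypy, 1e-300)
        logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
        logdetH = logdetM + sum(s * np.log(g) for s, g in zip(self.sizes, gamma))
        logdetB = 2.0 * np.sum(np.log(np.diag(cB[0])))
        return cM, cB, beta, ypy, logdetH, logdetB

    def value(self, log_gamma: np.ndarray) -> float:
        gamma = np.exp(log_gamma)
        _, _, _, ypy, logdetH, logdetB = self._core(gamma)
        nmp = self.n - self.p
        sigma2 = ypy / nmp
        return nmp * np.log(sigma2) + logdetH + logdetB

    def value_grad(self, log_gamma: np.ndarray):
        gamma = np.exp(log_gamma)
        cM, cB, beta, ypy, logdetH, logdetB = self._core(gamma)
        nmp = self.n - self.p
        f = nmp * np.log(ypy / nmp) + logdetH + logdetB

        # u_r = || Z_r' P y ||^2  via  Z' P y = Z'res - S M^{-1} Z'res
        res = self.y - self.X @ beta
        ztr = self.Z.T @ res
        zpy = ztr - self.S @ linalg.cho_solve(cM, ztr, check_finite=False)

        # tr(P Z_r Z_r') = tr(Z_r' H^{-1} Z_r) - tr(G_r' B^{-1} G_r)
        T = linalg.cho_solve(cM, self.S, check_finite=False)
        col_hi = np.diag(self.S) - np.einsum("ij,ij->j", self.S, T)
        G = self.ZtX.T - (linalg.cho_solve(cM, self.ZtX, check_finite=False)).T @ self.S
        K = linalg.cho_solve(cB, G, check_finite=False)
        col_b = np.einsum("ij,ij->j", G, K)

        grad = np.empty(len(gamma))
        for r, sl in enumerate(self.slices):
            tr_pzz = float(np.sum(col_hi[sl] - col_b[sl]))
            u = float(zpy[sl] @ zpy[sl])
            grad[r] = gamma[r] * (tr_pzz - nmp * u / ypy)
        return f, grad

    def fit_at(self, gamma: np.ndarray):
        """Fixed effects, covariance and restricted log-likelihood at gamma."""
        nmp = self.n - self.p
        if self.q:
            cM, cB, beta, ypy, logdetH, logdetB = self._core(gamma)
            sigma2 = ypy / nmp
            cov = sigma2 * linalg.cho_solve(cB, np.eye(self.p), check_finite=False)
        else:
            cB = linalg.cho_factor(self.XtX, lower=True, check_finite=False)
            beta = linalg.cho_solve(cB, self.Xty, check_finite=False)
            ypy = float(self.yty - 2 * beta @ self.Xty + beta @ self.XtX @ beta)
            sigma2 = ypy / nmp if nmp > 0 else np.nan
            logdetH = 0.0
            logdetB = 2.0 * np.sum(np.log(np.diag(cB[0])))
            cov = (sigma2 if nmp > 0 else np.nan) * linalg.cho_solve(
                cB, np.eye(self.p), check_finite=False)
        if nmp > 0 and np.isfinite(sigma2) and sigma2 > 0:
            m2ll = nmp * (_LOG2PI + 1.0 + np.log(sigma2)) + logdetH + logdetB
        else:
            m2ll = np.nan
        cov = 0.5 * (cov + cov.T)
        return beta, cov, sigma2, -0.5 * m2ll


def _optimize(y, X, Zs, sizes, active: list[int], n_random: int,
              start: np.ndarray | None, maxiter: int, ftol: float, gtol: float):
    """Maximise restricted likelihood over the active components only.

    Inactive components are excluded from the model (variance exactly zero).
    Returns (gamma over all components with zeros for inactive, objective
    value, subproblem, iterations, converged, trace).
    """
    problem = _RemlProblem(y, X, [Zs[i] for i in active], [sizes[i] for i in active])
    if not active:
        beta, cov, sigma2, ll = problem.fit_at(np.zeros(0))
        nmp = problem.n - problem.p
        return np.zeros(n_random), -2.0 * ll - nmp * (_LOG2PI + 1.0), problem, 0, True, []

    x0 = np.log(start[active]) if start is not None else np.zeros(len(active))
    x0 = np.clip(x0, _LOG_GAMMA_LO + 1.0, _LOG_GAMMA_HI - 1.0)
    trace: list[float] = []

    if len(active) == 1:
        res = optimize.minimize_scalar(
            lambda t: problem.value(np.array([t])),
            bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI), method="bounded",
            options={"xatol": 1e-11, "maxiter": maxiter},
        )
        x, fval, nit, ok = np.array([res.x]), res.fun, res.nfev, res.success
    else:
        def cb(xk):
            trace.append(problem.value(xk))
        res = optimize.minimize(
            problem.value_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * len(active),
            callback=cb,
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
        )
        x, fval, nit, ok = res.x, res.fun, res.nit, bool(res.success or res.status == 2)
    gamma = np.zeros(n_random)
    gamma[active] = np.exp(x)
    return gamma, fval, problem, nit, ok, trace


def reml_fit(data: pd.DataFrame, spec: ModelSpec, *, start: dict[str, float] | None = None,
             maxiter: int = 500, ftol: float = 1e-12, gtol: float = 1e-7) -> RemlFit:
    """Fit a linear mixed model by REML.

    Rows with a missing response are dropped.  Variance components are
    constrained to the nonnegative orthant; a component whose estimate sits
    at the boundary is profiled at exactly zero (the reduced model is
    refitted and kept when its restricted likelihood is no worse) and
    reported in ``clamped``.  The fit is deterministic: no random
    initialisation is used.
    """
    if spec.response not in data.columns:
        raise RemlError(f"response column {spec.response!r} not found")
    df = data.loc[np.isfinite(pd.to_numeric(data[spec.response], errors="coerce"))].copy()
    if len(df) == 0:
        raise RemlError("no non-missing observations")
    y = df[spec.response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        warnings.warn("response is degenerate (constant)", stacklevel=2)

    X, names, design = _build_fixed(df, spec)
    Zs, sizes = _build_random(df, spec)
    n, p = X.shape
    if n <= p and spec.random_terms:
        raise RemlError("no residual degrees of freedom")
    R = len(sizes)

    start_vec = None
    if start is not None and R:
        s2e0 = max(start.get("residual", np.var(y) / 2.0), 1e-12)
        start_vec = np.array([
            max(start.get(t, s2e0), 1e-10) / s2e0 for t in spec.random_terms])

    active = list(range(R))
    gamma, fval, problem, nit, ok, trace = _optimize(
        y, X, Zs, sizes, active, R, start_vec, maxiter, ftol, gtol)
    total_iter = nit

    # profile boundary components at exactly zero
    clamped: set[str] = set()
    while True:
        low = [i for i in active if gamma[i] < _CLAMP_GAMMA]
        if not low:
            break
        trial_active = [i for i in active if i not in low]
        g2, f2, prob2, nit2, ok2, tr2 = _optimize(
            y, X, Zs, sizes, trial_active, R, start_vec, maxiter, ftol, gtol)
        total_iter += nit2
        if f2 <= fval + 1e-6:
            gamma, fval, problem, ok, active = g2, f2, prob2, ok and ok2, trial_active
            trace += tr2
            clamped |= {spec.random_terms[i] for i in low}
        else:  # boundary not actually supported; keep the interior fit
            break

    beta, cov, sigma2, ll = problem.fit_at(gamma[active])
    variances = {t: float(g * sigma2) for t, g in zip(spec.random_terms, gamma)}
    for t in clamped:
        variances[t] = 0.0
    variances["residual"] = float(sigma2)

    nmp = n - p
    offset = nmp * (_LOG2PI + 1.0)
    trace_m2ll = [t + offset for t in trace]

    return RemlFit(
        spec=spec, variances=variances, sigma2_e=float(sigma2),
        beta=pd.Series(beta, index=names), cov_beta=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(ll), n_obs=n, n_fixed=p, n_iter=int(total_iter),
        converged=bool(ok), clamped=frozenset(clamped), trace=trace_m2ll,
        _design=design,
    )
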