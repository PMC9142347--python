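"""Per-genotype stability statistics on a genotype x environment BLUE table.

Two complementary views of genotype-by-environment interaction:

* **Finlay-Wilkinson joint regression** — each genotype's BLUEs regressed
  on the environment index (the centered per-environment mean over all
  genotypes).  The slope ("sensitivity") is ~0 for statically stable
  genotypes, ~1 for dynamically stable ones that track the environment,
  and >1 for hypersensitive ones; the per-genotype R2 measures how
  predictable the response is.
* **Wricke's ecovalence** — each genotype's contribution to the
  interaction sum of squares of the double-centered table; 0 means no
  interaction at all.  The sum over genotypes equals the two-way
  genotype x environment interaction sum of squares.

Both are two-stage analyses operating on a complete BLUE matrix, plus a
helper to drop extreme environments and re-run the "no extremes"
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BlueMatrix, EnvironmentKey, MetDataError

__all__ = [
    "FWResult",
    "EcovalenceResult",
    "finlay_wilkinson",
    "classify_sensitivity",
    "wricke_ecovalence",
    "drop_environments",
]

#: Default sensitivity bands: |beta| <= 0.5 static; 0.8 <= beta <= 1.2 dynamic;
#: beta > 1.2 hypersensitive; anything between static and dynamic sub-sensitive.
DEFAULT_BANDS: tuple[float, float, float] = (0.5, 0.8, 1.2)


@dataclass
class FWResult:
    """Finlay-Wilkinson joint-regression estimates.

    ``table`` has one row per genotype: mean, slope (sensitivity),
    intercept, R2, residual variance and the sensitivity class label.
    """

    table: pd.DataFrame
    env_index: pd.Series            # centered environment index per environment
    excluded: list[str]             # genotypes seen in < 3 environments
    index_genotypes: list[str]      # genotypes used to form the environment index


@dataclass
class EcovalenceResult:
    """Wricke ecovalence per genotype, in squared trait units."""

    table: pd.DataFrame             # columns: genotype, mean, W
    total: float                    # sum of W_i = interaction SS
    environments: list[EnvironmentKey]


def classify_sensitivity(beta: float,
                         bands: tuple[float, float, float] = DEFAULT_BANDS) -> str:
    """Band a Finlay-Wilkinson slope into a stability class."""
    static_max, dynamic_lo, dynamic_hi = bands
    if not static_max <= dynamic_lo <= dynamic_hi:
        raise ValueError("bands must be ordered (static_max <= dynamic_lo <= dynamic_hi)")
    if abs(beta) <= static_max:
        return "static"
    if dynamic_lo <= beta <= dynamic_hi:
        return "dynamic"
    if beta > dynamic_hi:
        return "hypersensitive"
    return "sub-sensitive"


def finlay_wilkinson(blues: BlueMatrix, min_envs: int = 3,
                     bands: tuple[float, float, float] = DEFAULT_BANDS) -> FWResult:
    """Finlay-Wilkinson joint regression of each genotype on the environment index.

    The environment index is the per-environment mean of the BLUEs over the
    genotypes observed in *every* environment (complete-case index),
    centered to mean zero.  Each genotype's observed BLUEs are then
    regressed on the index by ordinary least squares.  Genotypes observed
    in fewer than ``min_envs`` environments are excluded and reported.
    """
    V = blues.values
    if V.shape[1] < 3:
        raise MetDataError("Finlay-Wilkinson needs at least 3 environments")
    complete = V.dropna(axis=0)
    if complete.shape[0] < 2:
        raise MetDataError("need >= 2 genotypes observed in all environments "
                           "to form the environment index")
    env_mean = complete.mean(axis=0)
    index = env_mean - env_mean.mean()
    if float(np.var(index.to_numpy())) <= 0:
        raise MetDataError("environment index has zero variance")

    rows, excluded = [], []
    x_full = index.to_numpy(dtype=float)
    for g in V.index:
        yv = V.loc[g].to_numpy(dtype=float)
        ok = np.isfinite(yv)
        if ok.sum() < min_envs:
            excluded.append(g)
            continue
        x, y = x_full[ok], yv[ok]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        beta = float(xc @ y) / sxx
        intercept = float(y.mean() - beta * x.mean())
        fitted = intercept + beta * x
        resid = y - fitted
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else (1.0 if np.allclose(resid, 0) else 0.0)
        r2 = min(max(r2, 0.0), 1.0)
        dof = len(y) - 2
        rows.append({
            "genotype": g, "mean": float(y.mean()), "beta": beta,
            "intercept": intercept, "r2": r2,
            "resid_var": float(resid @ resid) / dof if dof > 0 else np.nan,
            "n_envs": int(ok.sum()),
            "label": classify_sensitivity(beta, bands),
        })
    return FWResult(pd.DataFrame(rows), index, excluded, list(complete.index))


def wricke_ecovalence(blues: BlueMatrix, on_missing: str = "error") -> EcovalenceResult:
    """Wricke's ecovalence W_i from the double-centered BLUE table.

    W_i = sum_j (y_ij - ybar_i. - ybar_.j + ybar_..)^2, the genotype's
    contribution to the interaction sum of squares; a genotype with a
    purely additive response (no GEI) has W_i = 0.  ``on_missing="drop"``
    removes environments with any missing cell before computing.
    """
    V = blues.values
    if V.isna().to_numpy().any():
        if on_missing == "drop":
            keep = [c for c in V.columns if V[c].notna().all()]
            V = V[keep]
        else:
            raise MetDataError("ecovalence requires a complete table "
                               "(or on_missing='drop')")
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise MetDataError("ecovalence needs >= 2 genotypes and >= 2 environments")
    Y = V.to_numpy(dtype=float)
    resid = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + Y.mean()
    W = np.sum(resid ** 2, axis=1)
    table = pd.DataFrame({
        "genotype": list(V.index),
        "mean": Y.mean(axis=1),
        "W": W,
    })
    return EcovalenceResult(table, float(W.sum()), list(V.columns))


def drop_environments(blues: BlueMatrix, drop) -> BlueMatrix:
    """Remove environments (e.g. extreme seasons) before re-running stability.

    ``drop`` is a list of :class:`EnvironmentKey` (or ``"Location:Year"``
    strings).  Refuses to drop below three environments, the minimum for a
    meaningful joint regression.
    """
    keys = [EnvironmentKey.parse(d) if isinstance(d, str) else d for d in drop]
    if len(blues.environments) - len(keys) < 3:
        raise MetDataError("cannot drop below 3 environments")
    return blues.drop_environments(keys)
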