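"""GGE analysis: environment-centered SVD of the BLUE table.

Column-centering the genotype x environment table removes the environment
main effects and leaves genotype main effect plus genotype-by-environment
interaction (G + GE), which the singular value decomposition then splits
into orthogonal axes.  The first two axes give the usual biplot; the
"which-won-where" view assigns each environment its winning genotype and
groups environments that share a winner into mega-environments.

Winners are computed on the exact centered matrix (the rank-2 polygon
sectors of the visual convention are also reported, but they are a
display approximation, not the statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BlueMatrix, EnvironmentKey, MetDataError

__all__ = ["GGEModel", "gge_fit", "biplot_coords", "which_won_where", "plot_biplot"]


@dataclass
class GGEModel:
    """Environment-centered SVD of a complete BLUE table."""

    genotypes: list[str]
    environments: list[EnvironmentKey]
    centered: np.ndarray            # genotype x environment, column-centered
    U: np.ndarray                   # genotype scores (left singular vectors)
    d: np.ndarray                   # singular values, descending
    Vt: np.ndarray                  # environment loadings (right singular vectors, transposed)
    scaled: bool = False            # whether columns were scaled by their SD

    @property
    def variance_explained(self) -> np.ndarray:
        """Fraction of the centered sum of squares captured per axis."""
        ss = self.d ** 2
        return ss / ss.sum() if ss.sum() > 0 else ss


def gge_fit(blues: BlueMatrix, scale: bool = False) -> GGEModel:
    """Fit the GGE model: column-center (optionally SD-scale) and decompose.

    Requires a complete table with at least two genotypes and two
    environments.  The sign of each axis is made deterministic by forcing
    the largest-magnitude genotype score on that axis to be positive, so
    repeated fits are byte-identical.
    """
    V = blues.values
    if V.isna().to_numpy().any():
        raise MetDataError("GGE requires a complete table (no missing cells)")
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise MetDataError("GGE needs >= 2 genotypes and >= 2 environments")
    Y = V.to_numpy(dtype=float)
    centered = Y - Y.mean(axis=0, keepdims=True)
    if scale:
        sd = centered.std(axis=0, ddof=1, keepdims=True)
        if (sd <= 0).any():
            raise MetDataError("cannot SD-scale: an environment has zero variance")
        centered = centered / sd
    U, d, Vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(len(d)):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return GGEModel(list(V.index), list(V.columns), centered, U, d, Vt, scaled=scale)


def biplot_coords(model: GGEModel, f: float = 0.5, n_axes: int = 2):
    """Biplot coordinates with singular-value partitioning exponent ``f``.

    Genotype coordinates are ``U D^f`` and environment coordinates
    ``V D^(1-f)``; ``f=0.5`` (default) is the symmetric scaling, ``f=1``
    genotype-focused, ``f=0`` environment-focused.  The inner product of
    the two coordinate sets over the kept axes reconstructs the rank-``n_axes``
    approximation of the centered table at any ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("scaling exponent f must lie in [0, 1]")
    k = min(n_axes, len(model.d))
    dg = model.d[:k] ** f
    de = model.d[:k] ** (1.0 - f)
    gen = pd.DataFrame(model.U[:, :k] * dg, index=model.genotypes,
                       columns=[f"PC{i + 1}" for i in range(k)])
    env = pd.DataFrame(model.Vt[:k, :].T * de, index=[str(e) for e in model.environments],
                       columns=[f"PC{i + 1}" for i in range(k)])
    return gen, env


def _rank2_sector_winners(model: GGEModel) -> dict[str, str]:
    """Winning genotype per environment under the rank-2 biplot convention.

    In the rank-2 projection the winner in an environment is the genotype
    whose projection onto that environment's loading vector is largest —
    the polygon-vertex genotype of the sector containing the environment.
    """
    k = min(2, len(model.d))
    G = model.U[:, :k] * model.d[:k]
    E = model.Vt[:k, :].T
    proj = G @ E.T                   # genotype x environment rank-2 values
    winners = {}
    for j, env in enumerate(model.environments):
        winners[str(env)] = model.genotypes[int(np.argmax(proj[:, j]))]
    return winners


def which_won_where(model: GGEModel) -> dict:
    """Mega-environment partition: environments grouped by shared winner.

    Winners use the exact centered values; the rank-2 sector winners of the
    visual convention are reported alongside for comparison.
    """
    winners = {}
    for j, env in enumerate(model.environments):
        winners[str(env)] = model.genotypes[int(np.argmax(model.centered[:, j]))]
    mega: dict[str, list[str]] = {}
    for env, win in winners.items():
        mega.setdefault(win, []).append(env)
    return {
        "winners": winners,
        "mega_environments": [sorted(v) for _, v in sorted(mega.items())],
        "n_mega_environments": len(mega),
        "rank2_winners": _rank2_sector_winners(model),
    }


def plot_biplot(model: GGEModel, path, f: float = 0.5) -> None:
    """Render the axes-1/2 biplot to an SVG/PNG file (thin display layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gen, env = biplot_coords(model, f=f)
    ve = model.variance_explained
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.scatter(gen["PC1"], gen.get("PC2", 0), s=12, color="tab:blue")
    for name, row in gen.iterrows():
        ax.annotate(name, (row["PC1"], row.get("PC2", 0)), fontsize=7, color="tab:blue")
    for name, row in env.iterrows():
        ax.annotate(name, (row["PC1"], row.get("PC2", 0)), fontsize=8, color="tab:red")
        ax.plot([0, row["PC1"]], [0, row.get("PC2", 0)], color="tab:red", lw=0.8, alpha=0.6)
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.set_title("GGE biplot (environment-centered)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
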