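"""Synthetic multi-environment-trial generator.

Generates plot-level MET datasets with the full crossed stochastic
structure of the package's mixed models — genotype, location, year,
location x year, block within environment, row/column spatial trends, the
three genotype interactions, and residual plot error, every effect an
independent zero-mean Gaussian draw — plus joint-regression-structured
BLUE tables and evaluator score panels.  All true effect draws are
returned alongside the data so that every downstream estimator can be
tested by parameter recovery.

The default configuration emulates a small participatory organic winter
wheat breeding network: 50 genotypes evaluated in 2-3 locations over five
years in replicated RCBD trials, grain yield around 2800 kg/ha with a
plot-level CV of ~14%, genetic variance split 54/9/12/25 percent between
the genotype main effect and its location/year/location-year interactions,
and an optional selection funnel that truncates the population each year
(50 -> 42 -> 24 -> 16) on observed performance.

Seed handling: one master seed spawns an independent, named substream per
effect component, so adding a component never perturbs the draws of the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data import BlueMatrix, EnvironmentKey, PlotTable, ScoreRecord, TrialLayout

__all__ = [
    "SimulationConfig",
    "DEFAULT_FUNNEL",
    "simulate_met",
    "simulate_fw",
    "simulate_scores",
]

#: Selection funnel of the emulated breeding program: genotypes retained in
#: each successive trial year (truncation selection on observed performance).
DEFAULT_FUNNEL: tuple[int, ...] = (50, 42, 24, 16, 16)

# fixed substream indices per effect component (never reorder)
_STREAMS = {
    "genotype": 0, "location": 1, "year": 2, "location_year": 3, "block": 4,
    "row": 5, "column": 6, "gl": 7, "ga": 8, "gla": 9, "residual": 10,
    "layout": 11, "fw": 12, "scores": 13,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],)))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic MET.

    Variance components are in squared trait units; the defaults are on a
    grain-yield (kg/ha) scale.
    """

    n_genotypes: int = 50
    n_locations: int = 2
    n_years: int = 5
    n_replicates: int = 3
    layout: TrialLayout | None = None
    trait: str = "yield_kg_ha"
    mu: float = 2800.0
    sigma2_g: float = 54_000.0
    sigma2_l: float = 400_000.0
    sigma2_a: float = 600_000.0
    sigma2_la: float = 1_200_000.0
    sigma2_block: float = 20_000.0
    sigma2_row: float = 0.0
    sigma2_col: float = 0.0
    sigma2_gl: float = 9_000.0
    sigma2_ga: float = 12_000.0
    sigma2_gla: float = 25_000.0
    sigma2_e: float = 150_000.0
    funnel: tuple[int, ...] | None = None
    start_year: int = 2017
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if name.startswith("sigma2") and val < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.funnel is not None:
            f = tuple(int(k) for k in self.funnel)
            if len(f) != self.n_years:
                raise ValueError("funnel must give one genotype count per year")
            if f[0] != self.n_genotypes or any(b > a for a, b in zip(f, f[1:])):
                raise ValueError("funnel must be non-increasing and start at n_genotypes")
            self.funnel = f

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "funnel" in raw and raw["funnel"] is not None:
            raw["funnel"] = tuple(raw["funnel"])
        if "layout" in raw and raw["layout"] is not None:
            lay = dict(raw["layout"])
            if "check_ids" in lay:
                lay["check_ids"] = frozenset(lay["check_ids"])
            if "grid" in lay:
                lay["grid"] = tuple(lay["grid"])
            raw["layout"] = TrialLayout(**lay)
        return cls(**raw)


def _grid_shape(n_plots_per_block: int) -> tuple[int, int]:
    n_cols = max(2, math.ceil(math.sqrt(n_plots_per_block)))
    return math.ceil(n_plots_per_block / n_cols), n_cols


def simulate_met(config: SimulationConfig):
    """Simulate plot-level MET data.

    Returns ``(PlotTable, truth)`` where ``truth`` maps each effect
    component to its drawn true values (keyed by genotype / environment
    label where applicable).  Deterministic under ``config.seed``.

    With a selection funnel, the genotypes present in year ``t`` are the
    ``funnel[t]`` best survivors ranked on their observed trait mean over
    all previous years (truncation selection).
    """
    cfg = config
    genotypes = [f"g{i + 1:03d}" for i in range(cfg.n_genotypes)]
    locations = [f"L{j + 1}" for j in range(cfg.n_locations)]
    years = [cfg.start_year + k for k in range(cfg.n_years)]
    design = cfg.layout.design if cfg.layout is not None else "rcbd"
    check_ids = sorted(cfg.layout.check_ids) if cfg.layout is not None else []

    def draw(component, var, size):
        return _rng(cfg.seed, component).normal(0.0, math.sqrt(var), size)

    G = draw("genotype", cfg.sigma2_g, cfg.n_genotypes)
    L = draw("location", cfg.sigma2_l, cfg.n_locations)
    A = draw("year", cfg.sigma2_a, cfg.n_years)
    LA = draw("location_year", cfg.sigma2_la, (cfg.n_locations, cfg.n_years))
    GL = draw("gl", cfg.sigma2_gl, (cfg.n_genotypes, cfg.n_locations))
    GA = draw("ga", cfg.sigma2_ga, (cfg.n_genotypes, cfg.n_years))
    GLA = draw("gla", cfg.sigma2_gla, (cfg.n_genotypes, cfg.n_locations, cfg.n_years))
    rng_block = _rng(cfg.seed, "block")
    rng_row = _rng(cfg.seed, "row")
    rng_col = _rng(cfg.seed, "column")
    rng_eps = _rng(cfg.seed, "residual")
    rng_layout = _rng(cfg.seed, "layout")

    gi = {g: i for i, g in enumerate(genotypes)}
    truth = {
        "genotype": dict(zip(genotypes, G)),
        "location": dict(zip(locations, L)),
        "year": dict(zip(years, A)),
        "location_year": {(l, a): LA[j, k] for j, l in enumerate(locations)
                          for k, a in enumerate(years)},
        "gl": {(g, l): GL[i, j] for g, i in gi.items() for j, l in enumerate(locations)},
        "ga": {(g, a): GA[i, k] for g, i in gi.items() for k, a in enumerate(years)},
        "gla": {(g, l, a): GLA[i, j, k] for g, i in gi.items()
                for j, l in enumerate(locations) for k, a in enumerate(years)},
        "block": {}, "row": {}, "column": {},
        "retained": {},
    }

    rows_out = []
    alive = list(genotypes)
    observed_sum = {g: 0.0 for g in genotypes}
    observed_n = {g: 0 for g in genotypes}

    for k, year in enumerate(years):
        if cfg.funnel is not None and k > 0:
            target = cfg.funnel[k]
            ranked = sorted(
                alive,
                key=lambda g: (-(observed_sum[g] / observed_n[g]
                                 if observed_n[g] else -np.inf), g))
            alive = sorted(ranked[:target])
        truth["retained"][year] = list(alive)
        entries = [g for g in alive if g not in check_ids]

        for j, loc in enumerate(locations):
            env = (loc, year)
            if design == "rcbd":
                block_members = [list(alive) for _ in range(cfg.n_replicates)]
            else:  # augmented: entries split across blocks, checks in every block
                block_members = [[] for _ in range(cfg.n_replicates)]
                for idx, g in enumerate(entries):
                    block_members[idx % cfg.n_replicates].append(g)
                for b in block_members:
                    b.extend(check_ids)
            per_block = max(len(b) for b in block_members)
            rows_per_block, n_cols = _grid_shape(per_block)

            blocks = [f"b{b + 1}" for b in range(cfg.n_replicates)]
            beff = rng_block.normal(0.0, math.sqrt(cfg.sigma2_block), len(blocks))
            n_rows_total = rows_per_block * len(blocks)
            reff = rng_row.normal(0.0, math.sqrt(cfg.sigma2_row), n_rows_total)
            ceff = rng_col.normal(0.0, math.sqrt(cfg.sigma2_col), n_cols)
            truth["block"].update({(loc, year, b): beff[bi] for bi, b in enumerate(blocks)})
            truth["row"].update({(loc, year, r + 1): reff[r] for r in range(n_rows_total)})
            truth["column"].update({(loc, year, c + 1): ceff[c] for c in range(n_cols)})

            for bi, members in enumerate(block_members):
                order = list(rng_layout.permutation(members))
                for pos, g in enumerate(order):
                    row = bi * rows_per_block + pos // n_cols + 1
                    col = pos % n_cols + 1
                    i = gi[g]
                    value = (cfg.mu + G[i] + L[j] + A[k] + LA[j, k]
                             + beff[bi] + reff[row - 1] + ceff[col - 1]
                             + GL[i, j] + GA[i, k] + GLA[i, j, k]
                             + rng_eps.normal(0.0, math.sqrt(cfg.sigma2_e)))
                    rows_out.append((g, loc, year, blocks[bi], row, col, cfg.trait, value))
                    observed_sum[g] += value
                    observed_n[g] += 1

    df = pd.DataFrame(rows_out, columns=[
        "genotype", "location", "year", "block", "row", "column", "trait", "value"])
    return PlotTable(df), truth


def simulate_fw(
    n_genotypes: int,
    n_environments: int,
    slopes,
    noise_sd: float,
    seed: int = 0,
    mu: float = 0.0,
    genotype_sd: float = 1.0,
    env_sd: float = 1.0,
):
    """Simulate a BLUE table with joint-regression structure.

    ``y_ij = mu + G_i + beta_i * E_j + eps`` with the environment effects
    ``E_j`` drawn Gaussian and centered to mean zero.  Returns
    ``(BlueMatrix, truth)`` with the true genotype effects, slopes and
    environment effects.
    """
    slopes = np.asarray(slopes, dtype=float)
    if len(slopes) != n_genotypes:
        raise ValueError("need one slope per genotype")
    rng = _rng(seed, "fw")
    G = rng.normal(0.0, genotype_sd, n_genotypes)
    E = rng.normal(0.0, env_sd, n_environments)
    E = E - E.mean()
    eps = rng.normal(0.0, noise_sd, (n_genotypes, n_environments)) if noise_sd > 0 \
        else np.zeros((n_genotypes, n_environments))
    Y = mu + G[:, None] + slopes[:, None] * E[None, :] + eps
    genotypes = [f"g{i + 1:03d}" for i in range(n_genotypes)]
    envs = [EnvironmentKey("sim", j + 1) for j in range(n_environments)]
    blues = BlueMatrix(pd.DataFrame(Y, index=genotypes, columns=envs))
    truth = {"genotype_effects": dict(zip(genotypes, G)),
             "slopes": dict(zip(genotypes, slopes)),
             "env_effects": dict(zip(map(str, envs), E))}
    return blues, truth


def simulate_scores(
    n_evaluators: int,
    n_genotypes: int,
    stages: list[str] | None,
    genotype_effects,
    sigma2_evaluator: float,
    sigma2_stage: float,
    sigma2_e: float,
    scale: tuple[float, float] = (1.0, 10.0),
    mu: float | None = None,
    seed: int = 0,
):
    """Simulate an evaluator score panel.

    ``score = mu + G_i + evaluator_j (+ stage_k) + eps`` clipped to the
    scale bounds.  Returns ``(records, truth)``; ``truth['clip_fraction']``
    reports how much clipping distorted the Gaussian model.
    """
    lo, hi = scale
    if not lo < hi:
        raise ValueError("invalid scale bounds")
    genotype_effects = np.asarray(genotype_effects, dtype=float)
    if len(genotype_effects) != n_genotypes:
        raise ValueError("need one genotype effect per genotype")
    if mu is None:
        mu = 0.5 * (lo + hi)
    rng = _rng(seed, "scores")
    evals = rng.normal(0.0, math.sqrt(sigma2_evaluator), n_evaluators)
    stage_list = list(stages) if stages else [None]
    seff = rng.normal(0.0, math.sqrt(sigma2_stage), len(stage_list)) if stages \
        else np.zeros(1)
    genotypes = [f"g{i + 1:03d}" for i in range(n_genotypes)]
    evaluators = [f"e{j + 1:02d}" for j in range(n_evaluators)]

    records, n_clipped, n_total = [], 0, 0
    for i, g in enumerate(genotypes):
        for j, e in enumerate(evaluators):
            for k, st in enumerate(stage_list):
                raw = (mu + genotype_effects[i] + evals[j] + seff[k]
                       + rng.normal(0.0, math.sqrt(sigma2_e)))
                clipped = min(max(raw, lo), hi)
                n_total += 1
                n_clipped += int(clipped != raw)
                records.append(ScoreRecord(e, g, clipped, st, (lo, hi)))
    truth = {
        "mu": mu,
        "genotype_effects": dict(zip(genotypes, genotype_effects)),
        "evaluator_effects": dict(zip(evaluators, evals)),
        "stage_effects": dict(zip([s for s in stage_list if s is not None], seff)) if stages else {},
        "clip_fraction": n_clipped / n_total,
    }
    return records, truth
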