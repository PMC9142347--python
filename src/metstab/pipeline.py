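"""End-to-end analysis pipeline: one config in, a report bundle out.

Stages run in dependency order: simulate (or load) plot data, per-environment
BLUEs, variance components, heritability, stability (with and without the
dropped "extreme" environments), GGE, Dunnett comparison-to-check, and the
evaluator score models.  Every stage's outputs are CSV tables in the output
directory; a JSON manifest records the configuration, seeds, package
version, which stages ran, and a checksum per output file, so re-running
the same config is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import EnvironmentKey, PlotTable, read_plot_csv, write_plot_csv
from .mixed_models import (blues_all_environments, estimate_variance_components,
                           fit_score_model)
from .quantgen import heritability, incidence_counts, variance_proportions
from .stability import drop_environments, finlay_wilkinson, wricke_ecovalence
from .gge import gge_fit, biplot_coords, which_won_where, plot_biplot
from .comparisons import dunnett_test
from .synthetic import SimulationConfig, simulate_met, simulate_scores

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_ALL_STAGES = ("blues", "varcomp", "heritability", "stability", "gge",
               "dunnett", "scores")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    output_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    plots_path: str | None = None
    traits: list[str] | None = None
    check: str | None = None
    alpha: float = 0.05
    drop_envs: list[str] = field(default_factory=list)
    stages: dict[str, bool] = field(default_factory=dict)
    scores_sim: dict | None = None
    scores_path: str | None = None
    spatial: str = "auto"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.plots_path is None:
            raise ValueError("config needs either a simulation block or plots_path")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def stage_on(self, name: str) -> bool:
        return self.stages.get(name, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            if "funnel" in sim and sim["funnel"] is not None:
                sim["funnel"] = tuple(sim["funnel"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, log: list[str]) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    log.append(f"wrote {path.name} ({len(df)} rows)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest dictionary.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    outputs of completed stages are left on disk for inspection.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"metstab {__version__}", f"master seed {config.seed}"]
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "stages_run": [], "stages_skipped": [], "outputs": {},
    }

    # --- input data -------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        plots, truth = simulate_met(sim)
        write_plot_csv(plots, out / "plots.csv")
        log.append(f"simulated {len(plots)} plot records "
                   f"({sim.n_genotypes} genotypes, {sim.n_locations} locations, "
                   f"{sim.n_years} years)")
        manifest["simulation"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in dataclasses.asdict(sim).items()
                                  if not isinstance(v, frozenset)}
    else:
        plots = read_plot_csv(config.plots_path)
        log.append(f"loaded {len(plots)} plot records from {config.plots_path}")

    traits = config.traits or plots.traits
    drops = [EnvironmentKey.parse(d) for d in config.drop_envs]
    blue_matrices: dict[str, object] = {}

    def run_stage(name, fn):
        if not config.stage_on(name):
            manifest["stages_skipped"].append(name)
            log.append(f"stage {name}: skipped (toggled off)")
            return
        try:
            fn()
        except Exception as exc:  # persist partial outputs, then abort
            log.append(f"stage {name}: FAILED: {exc}")
            (out / "log.txt").write_text("\n".join(log) + "\n")
            raise PipelineError(name, exc) from exc
        manifest["stages_run"].append(name)

    # --- BLUEs ------------------------------------------------------------
    def stage_blues():
        for trait in traits:
            bm = blues_all_environments(plots, trait, spatial=config.spatial)
            blue_matrices[trait] = bm
            bm.write_csv(out / f"blues_{trait}.csv", out / f"blues_se_{trait}.csv")
            log.append(f"blues[{trait}]: {len(bm.genotypes)} genotypes x "
                       f"{len(bm.environments)} environments, completeness "
                       f"{bm.completeness()['overall']:.3f}")

    run_stage("blues", stage_blues)

    # --- variance components ---------------------------------------------
    vcs: dict[str, object] = {}

    def stage_varcomp():
        rows = []
        n_loc = len({e.location for e in plots.environments})
        n_yr = len({e.year for e in plots.environments})
        scope = "all" if (n_loc >= 2 and n_yr >= 2) else "per_location"
        for trait in traits:
            vc = estimate_variance_components(plots, trait, scope=scope)
            vcs[trait] = vc
            row = {"trait": trait, "scope": scope, "method": vc.method}
            row.update({k: v for k, v in vc.as_dict().items() if v is not None})
            shares = variance_proportions(vc)
            row.update({f"share_{k}": v for k, v in shares.items()})
            rows.append(row)
            for term in sorted(vc.clamped):
                log.append(f"varcomp[{trait}]: component {term} clamped at zero")
        _write(pd.DataFrame(rows), out / "varcomp.csv", log)

    run_stage("varcomp", stage_varcomp)

    # --- heritability -----------------------------------------------------
    def stage_heritability():
        if not vcs:
            raise RuntimeError("heritability requires the varcomp stage")
        rows = []
        for trait in traits:
            h = heritability(vcs[trait], incidence_counts(plots, trait))
            rows.append({"trait": trait, "H2": h.H2, "n_years_hm": h.n_years,
                         "n_locations_hm": h.n_locations, "n_envs_hm": h.n_envs,
                         "n_plots_hm": h.n_plots})
            for g in h.dropped_genotypes:
                log.append(f"heritability[{trait}]: dropped genotype {g} (no data)")
        _write(pd.DataFrame(rows), out / "heritability.csv", log)

    run_stage("heritability", stage_heritability)

    # --- stability --------------------------------------------------------
    def stage_stability():
        trait = traits[0]
        bm = blue_matrices.get(trait) or blues_all_environments(plots, trait,
                                                                spatial=config.spatial)
        fw = finlay_wilkinson(bm)
        wr = wricke_ecovalence(bm, on_missing="drop")
        tab = fw.table.merge(wr.table[["genotype", "W"]], on="genotype", how="left")
        for g in fw.excluded:
            log.append(f"stability[{trait}]: genotype {g} excluded (<3 environments)")
        if drops:
            bm2 = drop_environments(bm, drops)
            fw2 = finlay_wilkinson(bm2)
            wr2 = wricke_ecovalence(bm2, on_missing="drop")
            t2 = fw2.table[["genotype", "beta", "r2"]].merge(
                wr2.table[["genotype", "W"]], on="genotype", how="left")
            tab = tab.merge(t2, on="genotype", how="left",
                            suffixes=("", "_no_extremes"))
        _write(tab, out / "stability.csv", log)

        rows = []
        for t in traits:
            bmt = blue_matrices.get(t)
            if bmt is None:
                continue
            wt = wricke_ecovalence(bmt, on_missing="drop")
            for rec in wt.table.itertuples(index=False):
                rows.append({"trait": t, "genotype": rec.genotype,
                             "mean": rec.mean, "W": rec.W})
        _write(pd.DataFrame(rows), out / "stability_by_trait.csv", log)

    run_stage("stability", stage_stability)

    # --- GGE --------------------------------------------------------------
    def stage_gge():
        trait = traits[0]
        bm = blue_matrices.get(trait) or blues_all_environments(plots, trait,
                                                                spatial=config.spatial)
        complete = bm.values.dropna(axis=1)
        from .data import BlueMatrix
        model = gge_fit(BlueMatrix(complete))
        gen, env = biplot_coords(model, f=0.5)
        ve = model.variance_explained
        gen = gen.assign(kind="genotype", name=gen.index)
        env = env.assign(kind="environment", name=env.index)
        coords = pd.concat([gen, env], ignore_index=True)[
            ["kind", "name"] + [c for c in gen.columns if c.startswith("PC")]]
        _write(coords, out / "gge.csv", log)
        www = which_won_where(model)
        log.append(f"gge[{trait}]: PC1 {100 * ve[0]:.1f}%, PC2 "
                   f"{100 * ve[1]:.1f}% of G+GE; "
                   f"{www['n_mega_environments']} mega-environment(s)")
        manifest["gge"] = {"variance_explained": [float(v) for v in ve[:4]],
                           "mega_environments": www["mega_environments"]}
        if config.make_plots:
            plot_biplot(model, out / "gge.svg")

    run_stage("gge", stage_gge)

    # --- Dunnett ----------------------------------------------------------
    def stage_dunnett():
        if config.check is None:
            raise RuntimeError("dunnett stage requires a check genotype in the config")
        trait = traits[0]
        frames = []
        for env in plots.environments:
            sub = plots.subset(environment=env, trait=trait).df
            if config.check not in set(sub["genotype"]):
                log.append(f"dunnett[{env}]: check {config.check} absent, skipped")
                continue
            res = dunnett_test(plots, trait, config.check, alpha=config.alpha,
                               environment=env)
            t = res.table.assign(environment=str(env), df=res.df,
                                 critical_difference=res.critical_difference)
            frames.append(t)
        _write(pd.concat(frames, ignore_index=True), out / "dunnett.csv", log)

    run_stage("dunnett", stage_dunnett)

    # --- scores -----------------------------------------------------------
    def stage_scores():
        if config.scores_path is not None:
            from .data import read_scores_csv
            records = read_scores_csv(config.scores_path)
        elif config.scores_sim is not None:
            kw = dict(config.scores_sim)
            kw.setdefault("seed", config.seed)
            n_g = kw.pop("n_genotypes")
            rng = np.random.default_rng(kw["seed"] + 1)
            geno_eff = rng.normal(0.0, np.sqrt(kw.pop("sigma2_g", 1.0)), n_g)
            records, truth = simulate_scores(genotype_effects=geno_eff,
                                             n_genotypes=n_g, **kw)
            log.append(f"scores: simulated panel, clip fraction "
                       f"{truth['clip_fraction']:.3f}")
        else:
            raise RuntimeError("scores stage requires scores_path or scores_sim")
        res = fit_score_model(records)
        tab = res.table.assign(evaluator_variance=res.evaluator_variance,
                               residual_variance=res.sigma2_e)
        _write(tab, out / "scores_blues.csv", log)

    run_stage("scores", stage_scores)

    # --- manifest ---------------------------------------------------------
    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "log.txt").write_text("\n".join(log) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
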