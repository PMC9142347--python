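"""Quantitative-genetics summaries on top of fitted variance components.

Variance shares of the total genetic variance, broad-sense heritability on
an entry-mean basis with harmonic-mean divisors (the appropriate form for
unbalanced selection-funnel data), Fusarium head blight plot scoring, and
the percentile / threshold / top-n selection filters used to advance
families through a breeding program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PlotTable
from .mixed_models import VarianceComponents

__all__ = [
    "HeritabilityResult",
    "FHBPlotScore",
    "variance_proportions",
    "harmonic_mean",
    "incidence_counts",
    "heritability",
    "fhb_scores",
    "percentile_select",
    "DEFAULT_SEVERITY_MAP",
]


def variance_proportions(vc: VarianceComponents) -> dict[str, float]:
    """Shares of the total genetic variance (G + GL + GA + GLA).

    Non-genetic components (location, year, block, residual) are excluded
    from the denominator.  Shares sum to one.
    """
    parts = {
        "G": vc.sigma2_g or 0.0,
        "GL": vc.sigma2_gl or 0.0,
        "GA": vc.sigma2_ga or 0.0,
        "GLA": vc.sigma2_gla or 0.0,
    }
    total = sum(parts.values())
    if total <= 0:
        raise ValueError("total genetic variance is zero; shares undefined")
    return {k: v / total for k, v in parts.items()}


def harmonic_mean(counts) -> float:
    """Harmonic mean of positive counts: n / sum(1/c)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty count list")
    if (counts <= 0).any():
        raise ValueError("harmonic mean requires strictly positive counts; "
                         "drop genotypes with zero observations first")
    return float(counts.size / np.sum(1.0 / counts))


@dataclass
class HeritabilityResult:
    """Entry-mean broad-sense heritability with its harmonic-mean divisors."""

    H2: float
    n_years: float | None       # harmonic mean of years per genotype
    n_locations: float | None   # harmonic mean of locations per genotype
    n_envs: float | None        # harmonic mean of location-years per genotype
    n_plots: float              # harmonic mean of plots per genotype
    components: VarianceComponents | None = None
    dropped_genotypes: list[str] = field(default_factory=list)


def incidence_counts(plots: PlotTable, trait: str) -> pd.DataFrame:
    """Realized observation incidence per genotype.

    Returns one row per genotype with the number of distinct years,
    locations, location-years and plots in which the trait was measured.
    Selection funnels make these strongly unbalanced, which is why the
    heritability divisors are harmonic means of these realized counts
    rather than nominal design counts.
    """
    df = plots.subset(trait=trait).df
    df = df[np.isfinite(df["value"])]
    grp = df.groupby("genotype")
    out = pd.DataFrame({
        "n_years": grp["year"].nunique(),
        "n_locations": grp["location"].nunique(),
        "n_envs": grp.apply(
            lambda s: s[["location", "year"]].drop_duplicates().shape[0],
            include_groups=False),
        "n_plots": grp.size(),
    })
    out.index.name = "genotype"
    return out.reset_index()


def heritability(vc: VarianceComponents, incidence: pd.DataFrame) -> HeritabilityResult:
    """Broad-sense heritability on an entry-mean basis.

    H2 = s2_g / (s2_g + s2_ga/n_a + s2_gl/n_l + s2_gal/n_al + s2_e/n_alr)

    with harmonic-mean divisors computed from the realized observation
    incidence (``incidence_counts``).  Interaction terms absent from a
    reduced-scope component set drop out of the denominator, giving the
    per-location form (no location terms) and the per-environment form
    (genotype and residual only).  Genotypes with zero observations are
    dropped and reported.
    """
    inc = incidence.copy()
    dropped = inc.loc[inc["n_plots"] <= 0, "genotype"].tolist() if "genotype" in inc else []
    inc = inc[inc["n_plots"] > 0]
    if len(inc) == 0:
        raise ValueError("no genotypes with observations")

    n_a = harmonic_mean(inc["n_years"]) if "n_years" in inc else None
    n_l = harmonic_mean(inc["n_locations"]) if "n_locations" in inc else None
    n_al = harmonic_mean(inc["n_envs"]) if "n_envs" in inc else None
    n_alr = harmonic_mean(inc["n_plots"])

    denom = vc.sigma2_g
    if vc.sigma2_ga is not None:
        denom += vc.sigma2_ga / n_a
    if vc.sigma2_gl is not None:
        denom += vc.sigma2_gl / n_l
    if vc.sigma2_gla is not None:
        denom += vc.sigma2_gla / n_al
    denom += vc.sigma2_e / n_alr
    if denom <= 0:
        raise ValueError("zero denominator: all variance components vanish")
    return HeritabilityResult(
        H2=vc.sigma2_g / denom,
        n_years=n_a, n_locations=n_l, n_envs=n_al, n_plots=n_alr,
        components=vc, dropped_genotypes=dropped)


#: Percent of infected spikelets implied by each 0-5 visual spike score
#: (a 15-spikelet reading of the standard anchors).  Configurable because
#: scoring scales differ between programs.
DEFAULT_SEVERITY_MAP: dict[int, float] = {0: 0.0, 1: 6.7, 2: 13.3, 3: 50.0, 4: 75.0, 5: 100.0}


@dataclass(frozen=True)
class FHBPlotScore:
    """Fusarium head blight incidence, severity and index for one plot."""

    spike_scores: tuple[int, ...]
    incidence: float   # % of scored spikes with any symptoms
    severity: float    # mean % of infected spikelets over all scored spikes
    index: float       # incidence x severity / 100, in %


def fhb_scores(spike_scores, severity_map: dict[int, float] | None = None,
               n_spikes: int = 20) -> FHBPlotScore:
    """Summarise per-spike 0-5 visual scores into incidence/severity/index.

    Incidence is the percentage of nonzero scores among the ``n_spikes``
    scored spikes; severity is the mean mapped percentage of infected
    spikelets; the index is their product expressed as a percentage.
    """
    severity_map = DEFAULT_SEVERITY_MAP if severity_map is None else severity_map
    scores = tuple(int(s) for s in spike_scores)
    if len(scores) != n_spikes:
        raise ValueError(f"expected {n_spikes} spike scores, got {len(scores)}")
    if any(s < 0 or s > 5 for s in scores):
        raise ValueError("spike scores must be integers in 0-5")
    incidence = 100.0 * sum(s > 0 for s in scores) / len(scores)
    severity = float(np.mean([severity_map[s] for s in scores]))
    return FHBPlotScore(scores, incidence, severity, incidence * severity / 100.0)


def percentile_select(values: dict[str, float] | pd.Series, rule: str,
                      threshold: float | None = None, k: int | None = None,
                      percentile: float | None = None) -> list[str]:
    """Deterministic single-trait selection filter.

    * ``rule="above_percentile"`` keeps ids strictly above the (linearly
      interpolated, inclusive) percentile of the values;
    * ``rule="below_threshold"`` keeps ids strictly below ``threshold``;
    * ``rule="top_n"`` keeps the ``k`` highest means, retaining all ids
      tied with the k-th value (ties at the boundary are never broken
      arbitrarily).

    Returns the selected ids sorted alphabetically.
    """
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValueError("no values to select from")
    if rule == "above_percentile":
        if percentile is None:
            raise ValueError("above_percentile requires percentile=")
        cut = float(np.percentile(s.to_numpy(), percentile))
        keep = s[s > cut]
    elif rule == "below_threshold":
        if threshold is None:
            raise ValueError("below_threshold requires threshold=")
        keep = s[s < threshold]
    elif rule == "top_n":
        if k is None:
            raise ValueError("top_n requires k=")
        if k >= len(s):
            keep = s
        else:
            cut = s.sort_values(ascending=False).iloc[k - 1]
            keep = s[s >= cut]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return sorted(keep.index)
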