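"""Domain data model and CSV I/O for multi-environment trial (MET) data.

Three kinds of tables circulate in the package:

* **plot tables** — one row per field plot and trait, with full design
  coordinates (genotype, location, year, block, row, column).  On disk the
  format is wide (one column per trait); in memory it is tidy (one row per
  plot x trait) wrapped in :class:`PlotTable`.
* **BLUE matrices** — genotype x environment tables of best linear unbiased
  estimates (:class:`BlueMatrix`), the input to all stability and GGE
  analyses.  An *environment* is a (location, year) pair.
* **score tables** — one row per evaluator x genotype (x baking stage)
  score from participatory baking / sensory panels.

Missing values are empty cells (or ``NA``) in CSV and ``NaN`` in memory;
they are never silently zero-filled.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentKey",
    "PlotObservation",
    "PlotTable",
    "TrialLayout",
    "BlueMatrix",
    "ScoreRecord",
    "TRAIT_REGISTRY",
    "MetDataError",
    "read_plot_csv",
    "write_plot_csv",
    "two_way_table",
    "read_blue_csv",
    "read_scores_csv",
    "write_scores_csv",
]


class MetDataError(ValueError):
    """Raised for malformed or invariant-violating trial data."""


#: Registered traits and their validation class.
#: ``percent`` traits must lie in [0, 100]; ``positive`` traits must be > 0.
TRAIT_REGISTRY: dict[str, str] = {
    "yield_kg_ha": "unbounded",
    "protein_pct": "percent",
    "falling_number_s": "positive",
    "ash_pct": "percent",
    "test_weight_kg_hl": "positive",
    "winter_survival_pct": "percent",
    "plant_height_cm": "positive",
    "fhb_score": "nonnegative",
    "score": "nonnegative",
}

_DESIGN_COLUMNS = ["genotype", "location", "year", "block", "row", "column"]


@dataclass(frozen=True)
class EnvironmentKey:
    """A trial environment: one location in one harvest year."""

    location: str
    year: int

    def __post_init__(self) -> None:
        if not self.location:
            raise MetDataError("environment location must be non-empty")
        object.__setattr__(self, "year", int(self.year))

    @property
    def sort_key(self) -> tuple[int, str]:
        # deterministic total ordering: year first, then location
        return (self.year, self.location)

    def __lt__(self, other: "EnvironmentKey") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.location}:{self.year}"

    @classmethod
    def parse(cls, text: str) -> "EnvironmentKey":
        """Parse ``"Madison:2019"`` into an :class:`EnvironmentKey`."""
        loc, _, year = text.rpartition(":")
        if not loc or not year:
            raise MetDataError(f"cannot parse environment key {text!r}")
        return cls(loc, int(year))


@dataclass(frozen=True)
class PlotObservation:
    """A single plot-level trait measurement with its design coordinates."""

    genotype_id: str
    location: str
    year: int
    block: str
    row: int
    column: int
    trait: str
    value: float  # NaN encodes a missing measurement

    @property
    def environment(self) -> EnvironmentKey:
        return EnvironmentKey(self.location, self.year)


@dataclass(frozen=True)
class TrialLayout:
    """Experimental design metadata for one trial."""

    design: str  # "rcbd" or "augmented_alpha"
    n_replicates: int
    check_ids: frozenset[str] = frozenset()
    grid: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.design not in ("rcbd", "augmented_alpha"):
            raise MetDataError(f"unknown design {self.design!r}")
        if self.n_replicates < 1:
            raise MetDataError("n_replicates must be >= 1")
        if self.design == "augmented_alpha" and not self.check_ids:
            raise MetDataError("augmented_alpha design requires check_ids")


def _validate_value(trait: str, value: float, where: str) -> None:
    if np.isnan(value):
        return
    if not np.isfinite(value):
        raise MetDataError(f"non-finite value for {trait} at {where}")
    kind = TRAIT_REGISTRY.get(trait, "unbounded")
    if kind == "percent" and not (0.0 <= value <= 100.0):
        raise MetDataError(f"{trait}={value} outside [0, 100] at {where}")
    if kind == "positive" and value <= 0:
        raise MetDataError(f"{trait}={value} must be > 0 at {where}")
    if kind == "nonnegative" and value < 0:
        raise MetDataError(f"{trait}={value} must be >= 0 at {where}")


class PlotTable:
    """Validated collection of :class:`PlotObservation` rows.

    Wraps a tidy DataFrame with columns
    ``genotype, location, year, block, row, column, trait, value``.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        required = _DESIGN_COLUMNS + ["trait", "value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise MetDataError(f"plot table missing columns {missing}")
        df = df[required].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["location"] = df["location"].astype(str)
        df["block"] = df["block"].astype(str)
        df["year"] = df["year"].astype(int)
        df["row"] = df["row"].astype(int)
        df["column"] = df["column"].astype(int)
        df["value"] = df["value"].astype(float)
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if (df["location"] == "").any():
            raise MetDataError("empty location in plot table")
        if (df["row"] < 1).any() or (df["column"] < 1).any():
            raise MetDataError("row/column indices must be >= 1")
        for t, sub in df.groupby("trait"):
            vals = sub["value"].to_numpy()
            present = ~np.isnan(vals)
            bad = present & ~np.isfinite(vals)
            kind = TRAIT_REGISTRY.get(t, "unbounded")
            if kind == "percent":
                bad |= present & ((vals < 0) | (vals > 100))
            elif kind == "positive":
                bad |= present & (vals <= 0)
            elif kind == "nonnegative":
                bad |= present & (vals < 0)
            if bad.any():
                i = int(sub.index[np.flatnonzero(bad)[0]])
                _validate_value(t, float(vals[np.flatnonzero(bad)[0]]), f"record {i}")
                raise MetDataError(f"invalid value for trait {t} at record {i}")
        dup = df.duplicated(subset=["location", "year", "row", "column", "trait"], keep=False)
        if dup.any():
            lines = df.index[dup].tolist()
            raise MetDataError(
                "duplicate (environment, row, column, trait) coordinates at "
                f"records {lines}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def observations(self) -> Iterator[PlotObservation]:
        for rec in self.df.itertuples(index=False):
            yield PlotObservation(
                rec.genotype, rec.location, rec.year, rec.block,
                rec.row, rec.column, rec.trait, rec.value,
            )

    @property
    def environments(self) -> list[EnvironmentKey]:
        keys = {EnvironmentKey(l, y) for l, y in
                self.df[["location", "year"]].drop_duplicates().itertuples(index=False)}
        return sorted(keys)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def subset(self, environment: EnvironmentKey | None = None,
               trait: str | None = None) -> "PlotTable":
        df = self.df
        if environment is not None:
            df = df[(df["location"] == environment.location) & (df["year"] == environment.year)]
        if trait is not None:
            df = df[df["trait"] == trait]
        return PlotTable(df, validate=False)


def read_plot_csv(path, registry: dict[str, str] | None = None) -> PlotTable:
    """Read a wide plot CSV (one column per trait) into a :class:`PlotTable`.

    Empty cells and ``NA`` become missing values.  A malformed numeric cell
    raises :class:`MetDataError` naming its row and column.
    """
    registry = TRAIT_REGISTRY if registry is None else registry
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise MetDataError(f"plot CSV missing required columns {missing}")
    trait_cols = [c for c in raw.columns if c not in _DESIGN_COLUMNS]
    if not trait_cols:
        raise MetDataError("plot CSV has no trait columns")
    unknown = [c for c in trait_cols if c not in registry]
    if unknown:
        raise MetDataError(f"unregistered trait columns {unknown}")

    for col in ["year", "row", "column"]:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            i = int(raw.index[bad][0])
            raise MetDataError(
                f"malformed numeric cell in column {col!r}, CSV line {i + 2}"
            )
        raw[col] = parsed.astype(int)

    frames = []
    for col in trait_cols:
        s = raw[col].str.strip()
        empty = (s == "") | (s.str.upper() == "NA")
        parsed = pd.to_numeric(s.where(~empty, np.nan), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            i = int(raw.index[bad][0])
            raise MetDataError(
                f"malformed numeric cell in column {col!r}, CSV line {i + 2}"
            )
        sub = raw[_DESIGN_COLUMNS].copy()
        sub["trait"] = col
        sub["value"] = parsed.astype(float)
        frames.append(sub)
    return PlotTable(pd.concat(frames, ignore_index=True))


def write_plot_csv(table: PlotTable, path) -> None:
    """Write a :class:`PlotTable` back to the wide CSV layout."""
    wide = table.df.pivot(
        index=_DESIGN_COLUMNS, columns="trait", values="value",
    ).reset_index()
    wide.columns.name = None
    wide.to_csv(path, index=False, float_format="%.12g")


@dataclass
class BlueMatrix:
    """Genotype x environment table of BLUEs, optionally with SEs.

    ``values`` is indexed by genotype with one column per environment
    (columns hold :class:`EnvironmentKey` objects); cells may be NaN.
    """

    values: pd.DataFrame
    se: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.se is not None:
            if self.se.shape != self.values.shape:
                raise MetDataError("se matrix shape differs from values")
            self.se = self.se.set_axis(self.values.index, axis=0).set_axis(
                self.values.columns, axis=1)

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[EnvironmentKey]:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def completeness(self) -> dict:
        """Fraction of non-missing cells overall, per genotype and per environment."""
        present = self.values.notna()
        return {
            "overall": float(present.to_numpy().mean()),
            "by_genotype": present.mean(axis=1).to_dict(),
            "by_environment": {str(e): float(v) for e, v in present.mean(axis=0).items()},
        }

    def drop_environments(self, drop: Sequence[EnvironmentKey]) -> "BlueMatrix":
        drop = list(drop)
        for env in drop:
            if env not in self.values.columns:
                raise MetDataError(f"environment {env} not in matrix")
        keep = [e for e in self.values.columns if e not in drop]
        se = self.se[keep] if self.se is not None else None
        return BlueMatrix(self.values[keep].copy(), se.copy() if se is not None else None)

    def write_csv(self, path, se_path=None) -> None:
        out = self.values.copy()
        out.columns = [str(e) for e in out.columns]
        out.index.name = "genotype"
        out.to_csv(path, float_format="%.12g")
        if se_path is not None and self.se is not None:
            se = self.se.copy()
            se.columns = [str(e) for e in se.columns]
            se.index.name = "genotype"
            se.to_csv(se_path, float_format="%.12g")


def read_blue_csv(path, se_path=None) -> BlueMatrix:
    """Read a wide BLUE CSV (``genotype,<Location:Year>...``)."""
    df = pd.read_csv(path, index_col="genotype")
    df.index = df.index.astype(str)
    df.columns = [EnvironmentKey.parse(c) for c in df.columns]
    se = None
    if se_path is not None:
        se = pd.read_csv(se_path, index_col="genotype")
        se.index = se.index.astype(str)
        se.columns = [EnvironmentKey.parse(c) for c in se.columns]
    return BlueMatrix(df.astype(float), se.astype(float) if se is not None else None)


def two_way_table(records) -> BlueMatrix:
    """Assemble per-environment BLUE records into a :class:`BlueMatrix`.

    ``records`` is an iterable of ``(EnvironmentKey, genotype, value[, se])``
    tuples or a DataFrame with columns ``environment, genotype, value[, se]``.
    Ordering of the result is deterministic (genotypes alphabetically,
    environments by (year, location)) and independent of input order.
    Conflicting duplicate values for the same cell raise an error.
    """
    if isinstance(records, pd.DataFrame):
        rows = [tuple(r) for r in records[
            ["environment", "genotype", "value"] +
            (["se"] if "se" in records.columns else [])
        ].itertuples(index=False)]
    else:
        rows = [tuple(r) for r in records]

    cells: dict[tuple[str, EnvironmentKey], float] = {}
    ses: dict[tuple[str, EnvironmentKey], float] = {}
    for rec in rows:
        env, gen, value = rec[0], str(rec[1]), float(rec[2])
        se = float(rec[3]) if len(rec) > 3 and rec[3] is not None else np.nan
        key = (gen, env)
        if key in cells and not np.isclose(cells[key], value, rtol=1e-12, atol=1e-12, equal_nan=True):
            raise MetDataError(
                f"conflicting duplicate values for genotype {gen!r} in {env}: "
                f"{cells[key]} vs {value}"
            )
        cells[key] = value
        ses[key] = se

    genotypes = sorted({g for g, _ in cells})
    environments = sorted({e for _, e in cells})
    values = pd.DataFrame(np.nan, index=genotypes, columns=environments)
    se_df = pd.DataFrame(np.nan, index=genotypes, columns=environments)
    for (g, e), v in cells.items():
        values.loc[g, e] = v
        se_df.loc[g, e] = ses[(g, e)]
    has_se = np.isfinite(se_df.to_numpy()).any()
    return BlueMatrix(values, se_df if has_se else None)


@dataclass(frozen=True)
class ScoreRecord:
    """One evaluator's score for one genotype, optionally at one baking stage."""

    evaluator_id: str
    genotype_id: str
    score: float
    stage: str | None = None
    scale: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not (lo <= self.score <= hi):
            raise MetDataError(
                f"score {self.score} outside scale [{lo}, {hi}] "
                f"(evaluator {self.evaluator_id}, genotype {self.genotype_id})"
            )


def read_scores_csv(path) -> list[ScoreRecord]:
    """Read ``evaluator,genotype,stage,score,scale_min,scale_max`` records."""
    df = pd.read_csv(path, dtype={"evaluator": str, "genotype": str, "stage": str})
    records = []
    for rec in df.itertuples(index=False):
        stage = None if pd.isna(rec.stage) or rec.stage == "" else str(rec.stage)
        records.append(ScoreRecord(
            evaluator_id=str(rec.evaluator), genotype_id=str(rec.genotype),
            score=float(rec.score), stage=stage,
            scale=(float(rec.scale_min), float(rec.scale_max)),
        ))
    return records


def write_scores_csv(records: Iterable[ScoreRecord], path) -> None:
    rows = [{
        "evaluator": r.evaluator_id, "genotype": r.genotype_id,
        "stage": "" if r.stage is None else r.stage, "score": r.score,
        "scale_min": r.scale[0], "scale_max": r.scale[1],
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def scores_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of score records (one row per score)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
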