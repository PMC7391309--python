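"""Domain types and CSV I/O for island and plot abundance data.

The pipeline works on long-format ("tidy") abundance tables: one row per
(island, species) or (island, plot, species) with an integer count, plus a
metadata table giving each island's area in km².  Species identifiers are
opaque strings; no taxonomy handling is attempted.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: default column names for the long-format CSVs; override via the
#: ``columns`` argument of the readers to match differently-named deposits.
DEFAULT_COLUMNS = {
    "island_id": "island_id",
    "plot_id": "plot_id",
    "species_id": "species_id",
    "abundance": "abundance",
    "area_km2": "area_km2",
}


@dataclass(frozen=True)
class AbundanceVector:
    """Species counts for one community sample (an island or a plot).

    Zero-count species are dropped on construction; counts must be
    non-negative integers.  The empty vector represents a surveyed island
    on which no individuals of the taxon were found; all diversity metrics
    reject it with a :class:`~isar.errors.DomainError`.
    """

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for sp, count in self.entries.items():
            if isinstance(count, bool) or not float(count).is_integer():
                raise ValidationError(
                    f"abundance of species {sp!r} must be an integer, got {count!r}"
                )
            count = int(count)
            if count < 0:
                raise ValidationError(
                    f"abundance of species {sp!r} must be >= 0, got {count}"
                )
            if count > 0:
                cleaned[str(sp)] = count
        object.__setattr__(self, "entries", cleaned)

    @property
    def n_individuals(self) -> int:
        return sum(self.entries.values())

    @property
    def s_obs(self) -> int:
        return len(self.entries)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    @property
    def counts(self) -> np.ndarray:
        """Counts as an integer array, in sorted-species order."""
        return np.array([self.entries[s] for s in self.species], dtype=np.int64)

    def __len__(self) -> int:
        return self.s_obs

    def __bool__(self) -> bool:
        return self.s_obs > 0

    def __add__(self, other: "AbundanceVector") -> "AbundanceVector":
        merged = Counter(self.entries)
        merged.update(other.entries)
        return AbundanceVector(dict(merged))


@dataclass(frozen=True)
class IslandSample:
    """One island's pooled community together with its area (km²)."""

    island_id: str
    area_km2: float
    community: AbundanceVector
    taxon: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.area_km2) or self.area_km2 <= 0:
            raise ValidationError(
                f"island {self.island_id!r}: area must be > 0, got {self.area_km2}"
            )


@dataclass(frozen=True)
class PlotSample:
    """One bounded quadrat on an island."""

    island_id: str
    plot_id: str
    community: AbundanceVector


@dataclass
class ArchipelagoDataset:
    """A validated per-taxon dataset: islands, and optionally plots."""

    taxon: str
    islands: list[IslandSample]
    plots: list[PlotSample] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [isl.island_id for isl in self.islands]
        dupes = {i for i, c in Counter(ids).items() if c > 1}
        if dupes:
            raise ValidationError(f"duplicate island ids: {sorted(dupes)}")
        if self.plots:
            known = set(ids)
            orphans = {p.island_id for p in self.plots} - known
            if orphans:
                raise ValidationError(
                    f"plots reference unknown islands: {sorted(orphans)}"
                )
            keys = [(p.island_id, p.plot_id) for p in self.plots]
            dupk = {k for k, c in Counter(keys).items() if c > 1}
            if dupk:
                raise ValidationError(f"duplicate (island, plot) ids: {sorted(dupk)}")

    @property
    def island_ids(self) -> list[str]:
        return [isl.island_id for isl in self.islands]

    def island(self, island_id: str) -> IslandSample:
        for isl in self.islands:
            if isl.island_id == island_id:
                return isl
        raise KeyError(island_id)

    def nonempty_islands(self) -> list[IslandSample]:
        """Islands with at least one individual; empty ones are logged."""
        empty = [i.island_id for i in self.islands if not i.community]
        if empty:
            logger.info(
                "excluding %d empty island(s) from metric computation: %s",
                len(empty), empty,
            )
        return [i for i in self.islands if i.community]


def _require_columns(df: pd.DataFrame, needed: Iterable[str], path: str | Path) -> None:
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _columns(columns: Mapping[str, str] | None) -> dict[str, str]:
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    return mapping


def _check_abundances(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals < 0) | (vals != vals.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row}: abundance must be a non-negative integer, "
            f"got {df[col].iloc[row]!r}"
        )
    return vals.astype(int)


def read_island_table(
    abundance_path: str | Path,
    metadata_path: str | Path,
    taxon: str,
    columns: Mapping[str, str] | None = None,
) -> ArchipelagoDataset:
    """Read island-level abundances plus island metadata into a dataset.

    Duplicate (island, species) rows are summed.  Islands present in the
    metadata but absent from the abundance table are retained with empty
    communities and logged, mirroring surveys where a taxon was absent.
    """
    cols = _columns(columns)
    ab = pd.read_csv(abundance_path)
    meta = pd.read_csv(metadata_path)
    _require_columns(ab, [cols["island_id"], cols["species_id"], cols["abundance"]],
                     abundance_path)
    _require_columns(meta, [cols["island_id"], cols["area_km2"]], metadata_path)

    ab = ab.rename(columns={cols["island_id"]: "island_id",
                            cols["species_id"]: "species_id",
                            cols["abundance"]: "abundance"})
    meta = meta.rename(columns={cols["island_id"]: "island_id",
                                cols["area_km2"]: "area_km2"})
    ab["abundance"] = _check_abundances(ab, "abundance", abundance_path)

    areas = pd.to_numeric(meta["area_km2"], errors="coerce")
    bad = areas.isna() | (areas <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{metadata_path}: row {row}: area_km2 must be positive, "
            f"got {meta['area_km2'].iloc[row]!r}"
        )

    known = set(meta["island_id"].astype(str))
    missing_meta = set(ab["island_id"].astype(str)) - known
    if missing_meta:
        raise ValidationError(
            f"{abundance_path}: islands without metadata: {sorted(missing_meta)}"
        )

    pooled = (
        ab.groupby(["island_id", "species_id"], sort=True)["abundance"].sum()
    )
    islands = []
    for island_id, area in zip(meta["island_id"].astype(str), areas):
        if island_id in pooled.index.get_level_values(0):
            vec = AbundanceVector(pooled.loc[island_id].to_dict())
        else:
            logger.warning("island %r has no abundance records; kept empty", island_id)
            vec = AbundanceVector({})
        islands.append(IslandSample(island_id, float(area), vec, taxon=taxon))
    return ArchipelagoDataset(taxon=taxon, islands=islands)


def read_plot_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[PlotSample]:
    """Read plot-level abundances; one PlotSample per (island, plot).

    Islands with fewer than two plots are logged as flagged for exclusion
    from the β analysis (single-quadrat islands cannot partition diversity).
    """
    cols = _columns(columns)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty plot table", path)
        return []
    if df.empty:
        logger.warning("%s: empty plot table", path)
        return []
    _require_columns(
        df, [cols["island_id"], cols["plot_id"], cols["species_id"], cols["abundance"]],
        path,
    )
    df = df.rename(columns={cols["island_id"]: "island_id",
                            cols["plot_id"]: "plot_id",
                            cols["species_id"]: "species_id",
                            cols["abundance"]: "abundance"})
    df["abundance"] = _check_abundances(df, "abundance", path)
    pooled = df.groupby(["island_id", "plot_id", "species_id"], sort=True)[
        "abundance"
    ].sum()
    plots = [
        PlotSample(str(isl), str(plot), AbundanceVector(grp.droplevel([0, 1]).to_dict()))
        for (isl, plot), grp in pooled.groupby(level=[0, 1], sort=True)
    ]
    per_island = Counter(p.island_id for p in plots)
    single = sorted(i for i, c in per_island.items() if c < 2)
    if single:
        logger.warning(
            "islands with a single plot, flagged for exclusion from the "
            "beta analysis: %s", single,
        )
    return plots


def pool_plots(plots: Sequence[PlotSample], island_id: str) -> AbundanceVector:
    """Species-wise sum of counts over one island's plots."""
    mine = [p for p in plots if p.island_id == island_id]
    if not mine:
        raise KeyError(f"no plots for island {island_id!r}")
    pooled = AbundanceVector({})
    for p in mine:
        pooled = pooled + p.community
    return pooled


def multi_plot_islands(plots: Sequence[PlotSample]) -> list[str]:
    """Island ids with >= 2 plots (the ones usable for β-diversity)."""
    per_island = Counter(p.island_id for p in plots)
    return sorted(i for i, c in per_island.items() if c >= 2)


def write_island_table(
    dataset: ArchipelagoDataset,
    abundance_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the dataset back out in the same long CSV layout the readers accept."""
    rows = [
        {"island_id": isl.island_id, "species_id": sp, "abundance": count}
        for isl in dataset.islands
        for sp, count in sorted(isl.community.entries.items())
    ]
    pd.DataFrame(rows, columns=["island_id", "species_id", "abundance"]).to_csv(
        abundance_path, index=False
    )
    meta = pd.DataFrame(
        {
            "island_id": [i.island_id for i in dataset.islands],
            "area_km2": [i.area_km2 for i in dataset.islands],
        }
    )
    meta.to_csv(metadata_path, index=False)


def write_plot_table(plots: Sequence[PlotSample], path: str | Path) -> None:
    rows = [
        {"island_id": p.island_id, "plot_id": p.plot_id, "species_id": sp,
         "abundance": count}
        for p in plots
        for sp, count in sorted(p.community.entries.items())
    ]
    pd.DataFrame(
        rows, columns=["island_id", "plot_id", "species_id", "abundance"]
    ).to_csv(path, index=False)
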