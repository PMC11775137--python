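"""Domain tables and their CSV/TSV readers and writers.

Three tables drive the pipeline:

* :class:`OccurrenceTable` — long-format community observations, one row
  per (lake, time-slice, taxon) with a read count.  Time-slice ``k``
  covers the half-open age interval ``((k-1)*W, k*W]`` calendar years BP
  (slice 1 is the most recent) with slice width ``W`` = 1000 y by default.
* :class:`LakeRegistry` — lake ids with lon/lat coordinates; the source
  of all geometry downstream.
* :class:`TraitTable` — taxon or family keys mapped to a growth-form
  group (``cushion``, ``tree`` or ``other``) used as interaction proxies.

Delimiters are inferred from the file extension (``.tsv`` → tab,
anything else → comma); files are UTF-8 with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("cushion", "tree", "other")

OCC_COLUMNS = ("lake_id", "slice_index", "taxon_id", "family", "reads")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Row-level contract violation (duplicates, ranges, unknown labels)."""


def _delimiter(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


@dataclass(frozen=True)
class LakeRegistry:
    """Lake ids with geographic coordinates (degrees, WGS-style lon/lat)."""

    frame: pd.DataFrame  # columns: lake_id, lon, lat

    def __post_init__(self) -> None:
        df = self.frame
        missing = {"lake_id", "lon", "lat"} - set(df.columns)
        if missing:
            raise SchemaError(f"lake registry missing columns: {sorted(missing)}")
        dupes = df["lake_id"][df["lake_id"].duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate lake_id(s): {sorted(set(dupes))}")
        lon, lat = df["lon"].to_numpy(float), df["lat"].to_numpy(float)
        if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
            raise ValidationError("non-finite lake coordinates")
        if (np.abs(lon) > 180).any():
            raise ValidationError("longitude out of range [-180, 180]")
        if (np.abs(lat) > 90).any():
            raise ValidationError("latitude out of range [-90, 90]")

    @property
    def lake_ids(self) -> list[str]:
        return self.frame["lake_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def coords(self) -> np.ndarray:
        """(n, 2) array of lon, lat."""
        return self.frame[["lon", "lat"]].to_numpy(float)


@dataclass(frozen=True)
class OccurrenceTable:
    """Validated long-format (lake, slice, taxon, family, reads) table.

    Invariants enforced at construction: unique (lake, slice, taxon)
    keys, strictly positive integer read counts, and (when a registry is
    supplied) every lake known to the registry.
    """

    frame: pd.DataFrame
    slice_width_years: int = 1000

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(OCC_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"occurrence table missing columns: {sorted(missing)}")
        if df.duplicated(["lake_id", "slice_index", "taxon_id"]).any():
            raise ValidationError(
                "duplicate (lake_id, slice_index, taxon_id) rows; "
                "use validate_occurrences() to merge them"
            )
        if (df["reads"] <= 0).any():
            raise ValidationError("reads must be positive after load")
        if (df["slice_index"] < 1).any():
            raise ValidationError("slice_index must be >= 1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.frame["taxon_id"].unique())

    @property
    def slices(self) -> list[int]:
        return sorted(self.frame["slice_index"].unique())

    def slice_age_bounds(self, slice_index: int) -> tuple[int, int]:
        """(young, old) age bounds in years BP of a slice, half-open (young, old]."""
        w = self.slice_width_years
        return ((slice_index - 1) * w, slice_index * w)

    def check_lakes(self, registry: LakeRegistry) -> None:
        unknown = set(self.frame["lake_id"]) - set(registry.lake_ids)
        if unknown:
            raise ValidationError(f"lakes absent from registry: {sorted(unknown)}")


def validate_occurrences(
    df: pd.DataFrame,
    registry: LakeRegistry | None = None,
    slice_width_years: int = 1000,
) -> OccurrenceTable:
    """Validate a raw occurrence frame into an :class:`OccurrenceTable`.

    Duplicate (lake, slice, taxon) rows are summed with a logged
    warning; zero-read rows are dropped.  Re-validating an already valid
    table is a no-op (idempotent).
    """
    missing = set(OCC_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"occurrence table missing columns: {sorted(missing)}")
    df = df.loc[:, list(OCC_COLUMNS)].copy()

    reads = pd.to_numeric(df["reads"], errors="coerce")
    bad = reads.isna() | (reads != np.floor(reads))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"non-integer reads value {df['reads'].iloc[row]!r} at row {row}"
        )
    if (reads < 0).any():
        raise ValidationError("negative read counts")
    df["reads"] = reads.astype(np.int64)
    df["slice_index"] = pd.to_numeric(df["slice_index"]).astype(np.int64)

    n_zero = int((df["reads"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-read rows", n_zero)
        df = df[df["reads"] > 0]

    keys = ["lake_id", "slice_index", "taxon_id"]
    n_dupes = int(df.duplicated(keys).sum())
    if n_dupes:
        logger.warning("summing %d duplicate (lake, slice, taxon) rows", n_dupes)
        df = (
            df.groupby(keys, as_index=False, sort=False)
            .agg(family=("family", "first"), reads=("reads", "sum"))
            .loc[:, list(OCC_COLUMNS)]
        )
    table = OccurrenceTable(df.reset_index(drop=True), slice_width_years)
    if registry is not None:
        table.check_lakes(registry)
    logger.info("occurrence table loaded: %d rows (%d duplicates merged, %d zero-read dropped)",
                len(table), n_dupes, n_zero)
    return table


def read_occurrence_table(
    path: str | Path,
    registry: LakeRegistry | None = None,
    columns: Mapping[str, str] | None = None,
    slice_width_years: int = 1000,
) -> OccurrenceTable:
    """Read and validate a long-format occurrence CSV/TSV.

    ``columns`` optionally maps canonical names (``lake_id`` ...) to the
    names used in the file.
    """
    df = pd.read_csv(path, sep=_delimiter(path), dtype={"reads": str})
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return validate_occurrences(df, registry, slice_width_years)


def write_occurrence_table(table: OccurrenceTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep=_delimiter(path), index=False)


def read_lake_registry(path: str | Path) -> LakeRegistry:
    df = pd.read_csv(path, sep=_delimiter(path))
    return LakeRegistry(df.reset_index(drop=True))


def write_lake_registry(registry: LakeRegistry, path: str | Path) -> None:
    registry.frame.to_csv(path, sep=_delimiter(path), index=False)


@dataclass(frozen=True)
class TraitTable:
    """Taxon/family keys mapped to growth-form groups.

    Groups are restricted to ``cushion`` (mat-forming facilitators such
    as Saxifragaceae or Caryophyllaceae), ``tree`` (e.g. Betulaceae,
    Pinaceae) and ``other``.  Lookups for unknown keys default to
    ``other`` and are counted.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: g for k, g in self.mapping.items() if g not in GROUPS}
        if bad:
            raise ValidationError(
                f"unknown group label(s) {sorted(set(bad.values()))}; "
                f"allowed labels: {list(GROUPS)}"
            )

    def group_of(self, *keys: str) -> str:
        """Group for the first matching key (taxon first, then family)."""
        for key in keys:
            if key in self.mapping:
                return self.mapping[key]
        return "other"

    def groups_for(self, taxa: list[str], families: list[str]) -> np.ndarray:
        """Vector of groups, taxon key taking precedence over family key."""
        out, n_unknown = [], 0
        for t, f in zip(taxa, families):
            if t in self.mapping:
                out.append(self.mapping[t])
            elif f in self.mapping:
                out.append(self.mapping[f])
            else:
                out.append("other")
                n_unknown += 1
        if n_unknown:
            logger.info("%d taxa without trait entry defaulted to 'other'", n_unknown)
        return np.asarray(out)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep=_delimiter(path))
    missing = {"key", "group"} - set(df.columns)
    if missing:
        raise SchemaError(f"trait table missing columns: {sorted(missing)}")
    if df["key"].duplicated().any():
        dupes = sorted(set(df["key"][df["key"].duplicated()]))
        raise ValidationError(f"duplicate trait keys: {dupes}")
    return TraitTable(dict(zip(df["key"].astype(str), df["group"].astype(str))))


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    pd.DataFrame(
        {"key": list(traits.mapping), "group": list(traits.mapping.values())}
    ).to_csv(path, sep=_delimiter(path), index=False)
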