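"""Per-slice richness and range-size metrics (AOO and EOO).

Richness of a time-slice is the number of distinct taxa with at least
one read in any lake of the slice.  Range size per taxon is measured
two ways: area of occupancy (AOO) as the number of occupied lakes, and
extent of occurrence (EOO) as the summed area (km²) of equal-area grid
cells overlapping the convex hull of the occupied lakes.  The per-slice
mean range size averages over exactly the taxa present in the slice.

The grid-cell validation path (:func:`grid_cell_stats`) applies the
same AOO logic to arbitrary point occurrences binned into grid cells,
supporting spatial-domain richness/range regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import (Grid, ProjectedLakes, eoo_area_by_lakeset, laea_project,
                       make_grid, project_lakes)
from .io import LakeRegistry, OccurrenceTable
from .rarefy import ResampleSet


def _iteration_presence(rs: ResampleSet, iteration: int) -> pd.DataFrame:
    if not 1 <= iteration <= rs.n_iterations:
        raise IndexError(f"iteration {iteration} out of range")
    it = rs.counts[iteration - 1]
    df = rs.samples.copy()
    return df, it


def richness_per_slice(
    source: OccurrenceTable | ResampleSet,
    slice_index: int,
    iteration: int | None = None,
) -> int:
    """Distinct taxa with a positive count in any lake of the slice."""
    if isinstance(source, OccurrenceTable):
        sub = source.frame[source.frame["slice_index"] == slice_index]
        return int(sub["taxon_id"].nunique())
    samples, counts = _iteration_presence(source, iteration or 1)
    rows = samples["slice_index"].to_numpy() == slice_index
    if not rows.any():
        return 0
    return int(((counts[rows] > 0).any(axis=0)).sum())


def aoo_range(
    source: OccurrenceTable | ResampleSet,
    slice_index: int,
    iteration: int | None = None,
) -> pd.Series:
    """Occupied-lake count per taxon present in a slice (AOO, in lakes)."""
    if isinstance(source, OccurrenceTable):
        sub = source.frame[source.frame["slice_index"] == slice_index]
        return sub.groupby("taxon_id")["lake_id"].nunique().rename("aoo")
    samples, counts = _iteration_presence(source, iteration or 1)
    rows = samples["slice_index"].to_numpy() == slice_index
    occ = (counts[rows] > 0).sum(axis=0)
    present = occ > 0
    return pd.Series(occ[present], index=np.asarray(source.taxon_ids)[present],
                     name="aoo").sort_index()


@dataclass(frozen=True)
class RangeContext:
    """Projected lakes, grid and the per-lakeset EOO lookup table."""

    projected: ProjectedLakes
    grid: Grid
    eoo_table: np.ndarray    # EOO km² indexed by occupancy bitmask

    @classmethod
    def from_registry(cls, registry: LakeRegistry,
                      cell_side_m: float = 200_000.0) -> "RangeContext":
        projected = project_lakes(registry)
        grid = make_grid(projected, cell_side_m)
        return cls(projected, grid, eoo_area_by_lakeset(projected, grid))


def slice_range_summaries(
    rs: ResampleSet,
    registry: LakeRegistry,
    cfg: RunConfig,
    context: RangeContext | None = None,
) -> pd.DataFrame:
    """Richness and mean AOO/EOO range per (iteration, slice).

    Returns a tidy frame with one row per (iteration, slice_index) and
    columns ``richness``, ``mean_range_aoo`` (lakes) and
    ``mean_range_eoo`` (km²).  Slices empty in an iteration get richness
    0 and missing means.  EOO is evaluated through a bitmask lookup over
    the ``2**n_lakes - 1`` possible occupied-lake sets, which makes the
    per-taxon hull computation a vectorised table lookup.
    """
    context = context or RangeContext.from_registry(registry, cfg.grid_cell_m)
    lake_order = {l: i for i, l in enumerate(registry.lake_ids)}
    n_lakes, n_slices = len(registry), cfg.n_slices
    n_iter, _, n_taxa = rs.counts.shape

    lake_idx = rs.samples["lake_id"].map(lake_order).to_numpy()
    slice_idx = rs.samples["slice_index"].to_numpy() - 1

    # scatter presence into (iteration, lake, slice, taxon)
    presence = np.zeros((n_iter, n_lakes, n_slices, n_taxa), dtype=bool)
    presence[:, lake_idx, slice_idx, :] = rs.counts > 0

    occupancy = presence.sum(axis=1)                     # (iter, slice, taxon)
    present = occupancy > 0
    richness = present.sum(axis=2)                       # (iter, slice)

    with np.errstate(invalid="ignore"):
        mean_aoo = np.where(richness > 0,
                            occupancy.sum(axis=2) / richness, np.nan)

    weights = (1 << np.arange(n_lakes)).astype(np.int64)
    bitmask = np.tensordot(presence.astype(np.int64), weights, axes=([1], [0]))
    eoo = context.eoo_table[bitmask]                     # NaN where absent
    with np.errstate(invalid="ignore"):
        mean_eoo = np.where(richness > 0,
                            np.nansum(np.where(present, eoo, 0.0), axis=2)
                            / richness, np.nan)

    it, sl = np.meshgrid(np.arange(1, n_iter + 1), np.arange(1, n_slices + 1),
                         indexing="ij")
    return pd.DataFrame({
        "iteration": it.ravel(),
        "slice_index": sl.ravel(),
        "richness": richness.ravel(),
        "mean_range_aoo": mean_aoo.ravel(),
        "mean_range_eoo": mean_eoo.ravel(),
    })


def grid_cell_stats(
    occurrences: pd.DataFrame,
    cell_side_m: float = 200_000.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Grid-cell richness and mean AOO range from point occurrences.

    ``occurrences`` needs columns ``taxon_id``, ``lon``, ``lat``.  The
    points are projected into an LAEA frame centred on their mean
    position and binned into square cells; a taxon's range is its count
    of occupied cells (AOO in cells), a cell's richness is the number of
    taxa present, and a cell's mean range averages the ranges of the
    taxa present in it.

    Returns ``(per_cell, per_taxon_range)``.
    """
    need = {"taxon_id", "lon", "lat"} - set(occurrences.columns)
    if need:
        raise ValueError(f"occurrences missing columns: {sorted(need)}")
    lon = occurrences["lon"].to_numpy(float)
    lat = occurrences["lat"].to_numpy(float)
    xy = laea_project(lon, lat, float(lon.mean()), float(lat.mean()))
    origin = (xy[:, 0].min() - cell_side_m / 2, xy[:, 1].min() - cell_side_m / 2)
    grid = Grid(origin, cell_side_m)
    cells = [grid.cell_of(x, y) for x, y in xy]
    df = pd.DataFrame({"taxon_id": occurrences["taxon_id"].to_numpy(),
                       "cell": cells}).drop_duplicates()
    taxon_range = df.groupby("taxon_id")["cell"].nunique().rename("range_cells")
    per_cell = (
        df.assign(rng=lambda d: d["taxon_id"].map(taxon_range))
        .groupby("cell")
        .agg(richness=("taxon_id", "nunique"), mean_range=("rng", "mean"))
        .reset_index()
    )
    return per_cell, taxon_range
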