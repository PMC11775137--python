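"""Synthetic multi-lake sedaDNA community generator.

Generates lake × time-slice × taxon read-count tables with the
statistical structure the downstream analysis assumes, plus a truth
record, so the whole pipeline is testable without sequencing data.

The generative model mimics a stress-gradient scenario in a 30,000-year
record split at ~11 ka into a "glacial" regime (older slices) and a
"Holocene" regime (younger slices):

1. Per-slice richness ``S_t ~ Poisson(lambda)`` truncated at >= 5.
2. Present taxa are drawn without replacement from a fixed pool.
3. Each present taxon occupies ``L = 1 + Binomial(n_lakes - 1, p_t)``
   lakes, with ``logit(p_t) = a + b * (S_t - lambda) / sqrt(lambda)``;
   the coupling ``b`` is positive in the glacial regime (richer slices
   have more widespread taxa — facilitation expands ranges) and
   negative in the Holocene (richer slices have more restricted taxa —
   competition contracts ranges).  Occupied lakes are chosen uniformly.
4. Within a slice, relative abundances are a single Dirichlet(alpha)
   draw over the present taxa, multiplicatively boosted for the
   regime-favoured growth-form group (cushion plants under the glacial
   regime, trees under the Holocene), renormalised per lake over the
   taxa present there, and converted to reads by a multinomial with a
   fixed per-lake-slice total.

Draw order per dataset (one shared RNG stream, seeded from
``SimParams.rng_seed``): taxon→family assignment; per-slice richness;
per-slice taxon subsets; per-taxon occupancy counts then lake choices;
per-slice Dirichlet abundances; per-lake multinomial reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LakeRegistry, OccurrenceTable, TraitTable, validate_occurrences

#: Family pool with growth-form groups.  Cushion and tree memberships
#: follow the classic arctic/boreal assignments (mat-forming cushion
#: families vs. tree genera families); the rest are common tundra/taiga
#: families treated as "other".
FAMILY_GROUPS: dict[str, str] = {
    "Saxifragaceae": "cushion",
    "Caryophyllaceae": "cushion",
    "Boraginaceae": "cushion",
    "Brassicaceae": "cushion",
    "Betulaceae": "tree",
    "Pinaceae": "tree",
    "Poaceae": "other",
    "Cyperaceae": "other",
    "Asteraceae": "other",
    "Rosaceae": "other",
    "Ranunculaceae": "other",
    "Ericaceae": "other",
    "Salicaceae": "other",
    "Fabaceae": "other",
    "Polygonaceae": "other",
    "Apiaceae": "other",
    "Juncaceae": "other",
    "Onagraceae": "other",
    "Papaveraceae": "other",
    "Plumbaginaceae": "other",
}

#: Continuous-frame study box (lon east, lat north) standing in for the
#: northeast Siberia / Alaska lake region.
DEFAULT_BBOX = (110.0, 60.0, 170.0, 72.0)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults define the reference study conditions."""

    n_lakes: int = 7
    n_slices: int = 30
    regime_boundary_slice: int = 11   # slices > 11 (older than ~11 ka) are glacial
    taxon_pool_size: int = 150
    mean_richness_per_slice: float = 60.0
    occupancy_coupling_glacial: float = 0.6
    occupancy_coupling_holocene: float = -0.6
    baseline_occupancy_logit: float = 0.0
    reads_per_lake_slice: int = 20_000
    abundance_concentration: float = 1.0
    group_weight: float = 5.0         # boost of the regime-favoured group
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lakes", "n_slices", "taxon_pool_size",
                     "reads_per_lake_slice"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        if not self.regime_boundary_slice < self.n_slices:
            raise SimulationError("regime_boundary_slice must be < n_slices")

    def regime_of(self, slice_index: int) -> str:
        return "glacial" if slice_index > self.regime_boundary_slice else "holocene"


@dataclass
class SimTruth:
    """Generator-side record, recountable from the emitted table."""

    richness: pd.Series               # slice_index -> realized richness
    occupancy: pd.DataFrame           # (slice_index, taxon_id, n_lakes)
    regime: pd.Series                 # slice_index -> "glacial" | "holocene"
    group_fractions: pd.DataFrame     # (slice_index, cushion, tree, other) read shares
    params: SimParams = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "richness": {int(k): int(v) for k, v in self.richness.items()},
            "regime": {int(k): v for k, v in self.regime.items()},
            "occupancy": self.occupancy.to_dict(orient="records"),
            "group_fractions": self.group_fractions.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_lakes(
    n: int,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
    seed: int = 0,
) -> LakeRegistry:
    """``n`` distinct lake positions uniform in a lon/lat box (deterministic)."""
    if n < 1:
        raise SimulationError("need at least one lake")
    lon0, lat0, lon1, lat1 = bbox
    if not (lon1 > lon0 and lat1 > lat0):
        raise SimulationError("degenerate bounding box")
    rng = np.random.default_rng(seed)
    while True:
        lon = rng.uniform(lon0, lon1, n)
        lat = rng.uniform(lat0, lat1, n)
        if len({(a, b) for a, b in zip(lon, lat)}) == n:
            break
    ids = [f"lake_{i + 1:02d}" for i in range(n)]
    return LakeRegistry(pd.DataFrame({"lake_id": ids, "lon": lon, "lat": lat}))


def default_traits() -> TraitTable:
    """Family-level trait table matching the generator's family pool."""
    return TraitTable(dict(FAMILY_GROUPS))


def _taxon_pool(params: SimParams, rng: np.random.Generator):
    families = list(FAMILY_GROUPS)
    fam_idx = rng.integers(0, len(families), params.taxon_pool_size)
    taxon_ids = [f"t{i + 1:03d}" for i in range(params.taxon_pool_size)]
    taxon_family = [families[i] for i in fam_idx]
    taxon_group = np.array([FAMILY_GROUPS[f] for f in taxon_family])
    return taxon_ids, taxon_family, taxon_group


def generate_community(
    params: SimParams, lakes: LakeRegistry
) -> tuple[OccurrenceTable, SimTruth]:
    """Simulate one dataset under ``params`` for the given lake registry."""
    if len(lakes) != params.n_lakes:
        raise SimulationError(
            f"registry has {len(lakes)} lakes, params expect {params.n_lakes}"
        )
    rng = np.random.default_rng(params.rng_seed)
    taxon_ids, taxon_family, taxon_group = _taxon_pool(params, rng)
    lam = params.mean_richness_per_slice
    sd = np.sqrt(lam)
    lake_ids = lakes.lake_ids

    rows: list[tuple] = []
    regimes = {}
    for t in range(1, params.n_slices + 1):
        regime = params.regime_of(t)
        regimes[t] = regime
        s_t = 0
        while s_t < 5:
            s_t = int(rng.poisson(lam))
        if s_t > params.taxon_pool_size:
            raise SimulationError("taxon pool smaller than realized richness")
        present = rng.choice(params.taxon_pool_size, size=s_t, replace=False)

        b = (params.occupancy_coupling_glacial if regime == "glacial"
             else params.occupancy_coupling_holocene)
        eta = params.baseline_occupancy_logit + b * (s_t - lam) / sd
        p_t = 1.0 / (1.0 + np.exp(-eta))

        lakes_of: dict[int, np.ndarray] = {}
        for tx in present:
            n_occ = 1 + int(rng.binomial(params.n_lakes - 1, p_t))
            lakes_of[tx] = rng.choice(params.n_lakes, size=n_occ, replace=False)

        base = rng.dirichlet(np.full(s_t, params.abundance_concentration))
        favoured = "cushion" if regime == "glacial" else "tree"
        weights = np.where(taxon_group[present] == favoured, params.group_weight, 1.0)
        abundance = base * weights

        # lake membership matrix for this slice
        member = np.zeros((params.n_lakes, s_t), dtype=bool)
        for col, tx in enumerate(present):
            member[lakes_of[tx], col] = True
        for li in range(params.n_lakes):
            cols = np.flatnonzero(member[li])
            if cols.size == 0:
                continue
            p = abundance[cols] / abundance[cols].sum()
            counts = rng.multinomial(params.reads_per_lake_slice, p)
            for col, c in zip(cols, counts):
                if c > 0:
                    tx = present[col]
                    rows.append((lake_ids[li], t, taxon_ids[tx], taxon_family[tx], c))

    frame = pd.DataFrame(rows, columns=["lake_id", "slice_index", "taxon_id",
                                        "family", "reads"])
    table = validate_occurrences(frame, lakes)

    # truth records the *realized* state, recountable from the table
    # (a drawn taxon that received zero reads everywhere does not count)
    richness, occupancy = recount_truth(table)
    group_frac = group_read_fractions(table, taxon_group, taxon_ids)
    truth = SimTruth(
        richness=richness.rename("richness"),
        occupancy=occupancy,
        regime=pd.Series(regimes, name="regime"),
        group_fractions=group_frac,
        params=params,
    )
    return table, truth


def group_read_fractions(
    table: OccurrenceTable, taxon_group: np.ndarray, taxon_ids: list[str]
) -> pd.DataFrame:
    """Per-slice read share of each growth-form group in a table."""
    gmap = dict(zip(taxon_ids, taxon_group))
    df = table.frame.assign(group=lambda d: d["taxon_id"].map(gmap))
    tot = df.groupby("slice_index")["reads"].sum()
    out = (
        df.groupby(["slice_index", "group"])["reads"].sum().unstack(fill_value=0)
        .reindex(columns=["cushion", "tree", "other"], fill_value=0)
    )
    return (out.div(tot, axis=0)).reset_index()


def recount_truth(table: OccurrenceTable) -> tuple[pd.Series, pd.DataFrame]:
    """Recount per-slice richness and per-(slice, taxon) lake occupancy.

    Used to check that a :class:`SimTruth` is consistent with its table.
    Note the recount sees only taxa that received >= 1 read in >= 1 lake,
    which the multinomial guarantees only for occupied lakes with large
    read totals; at default read depths truth and recount coincide.
    """
    df = table.frame
    richness = df.groupby("slice_index")["taxon_id"].nunique()
    occ = (
        df.groupby(["slice_index", "taxon_id"])["lake_id"].nunique()
        .rename("n_lakes").reset_index()
    )
    return richness, occ


def generate_dataset(
    params: SimParams | None = None,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
) -> tuple[OccurrenceTable, LakeRegistry, TraitTable, SimTruth]:
    """Convenience wrapper: lakes + community + traits in one call."""
    params = params or SimParams()
    lakes = generate_lakes(params.n_lakes, bbox, seed=params.rng_seed)
    table, truth = generate_community(params, lakes)
    return table, lakes, default_traits(), truth
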