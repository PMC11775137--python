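"""Rarefaction: depth-standardise lake-slice samples by resampling reads.

Each (lake, time-slice) sample is subsampled without replacement
(multivariate hypergeometric) to a common base count — 5000 reads by
default — and the whole procedure is repeated for a configurable number
of iterations (100 by default).  Samples shallower than the base count
are excluded identically in every iteration and logged.  Iteration
``i`` uses an RNG substream seeded from ``(rng_seed, i)``, so iterations
are individually reproducible and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import OccurrenceTable

logger = logging.getLogger(__name__)


class InsufficientDepthError(ValueError):
    """Sample total below the rarefaction base count."""


class EmptyInputError(ValueError):
    """No sample deep enough to rarefy."""


@dataclass(frozen=True)
class ResampleSet:
    """Rarefied counts for all iterations.

    ``counts`` has shape (n_iterations, n_samples, n_taxa); ``samples``
    holds the retained (lake_id, slice_index) pairs in row order;
    ``excluded`` lists samples below the base count with their original
    totals.
    """

    counts: np.ndarray
    samples: pd.DataFrame              # columns lake_id, slice_index
    taxon_ids: tuple[str, ...]
    families: tuple[str, ...]
    base_count: int
    excluded: pd.DataFrame             # columns lake_id, slice_index, total_reads

    @property
    def n_iterations(self) -> int:
        return self.counts.shape[0]

    def presence(self) -> np.ndarray:
        """Boolean (iteration, sample, taxon) incidence array."""
        return self.counts > 0

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long frame of non-zero rarefied counts (can be large)."""
        it, smp, tx = np.nonzero(self.counts)
        return pd.DataFrame({
            "iteration": it + 1,
            "lake_id": self.samples["lake_id"].to_numpy()[smp],
            "slice_index": self.samples["slice_index"].to_numpy()[smp],
            "taxon_id": np.asarray(self.taxon_ids)[tx],
            "family": np.asarray(self.families)[tx],
            "reads": self.counts[it, smp, tx],
        })

    def write(self, counts_path: str | Path, exclusions_path: str | Path) -> None:
        self.to_long_frame().to_csv(counts_path, index=False)
        self.excluded.to_csv(exclusions_path, index=False)


def rarefy_sample(
    counts: np.ndarray,
    base_count: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> np.ndarray:
    """Subsample one count vector to exactly ``base_count`` reads.

    Without replacement (the default) this draws a multivariate
    hypergeometric sample, so every returned element is bounded by its
    input and a total exactly equal to the base count returns the input
    unchanged.  The with-replacement variant (multinomial) exists for
    sensitivity runs only.
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < base_count:
        raise InsufficientDepthError(
            f"sample total {total} below base count {base_count}"
        )
    if with_replacement:
        return rng.multinomial(base_count, counts / total)
    if total == base_count:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), base_count)


def _sample_matrix(table: OccurrenceTable):
    """Pivot a long table into a dense (sample × taxon) count matrix."""
    pivot = table.frame.pivot_table(
        index=["lake_id", "slice_index"], columns="taxon_id",
        values="reads", aggfunc="sum", fill_value=0,
    ).sort_index()
    fam = (
        table.frame.drop_duplicates("taxon_id").set_index("taxon_id")["family"]
        .reindex(pivot.columns)
    )
    samples = pivot.index.to_frame(index=False)
    return pivot.to_numpy(np.int64), samples, tuple(pivot.columns), tuple(fam)


def rarefy_dataset(
    table: OccurrenceTable,
    cfg: RunConfig,
    with_replacement: bool = False,
) -> ResampleSet:
    """Rarefy every (lake, slice) sample ``cfg.n_iterations`` times.

    Deterministic for a fixed ``cfg.rng_seed``; shallow samples are
    excluded before any random draw so the exclusion set is identical
    across iterations.
    """
    matrix, samples, taxon_ids, families = _sample_matrix(table)
    totals = matrix.sum(axis=1)
    keep = totals >= cfg.base_count
    excluded = samples.loc[~keep].assign(total_reads=totals[~keep]).reset_index(drop=True)
    if not keep.any():
        raise EmptyInputError("no sample reaches the rarefaction base count")
    if len(excluded):
        logger.warning("excluding %d samples below base count %d",
                       len(excluded), cfg.base_count)
    matrix = matrix[keep]
    samples = samples.loc[keep].reset_index(drop=True)

    out = np.empty((cfg.n_iterations, matrix.shape[0], matrix.shape[1]),
                   dtype=np.int32)
    for i in range(cfg.n_iterations):
        rng = np.random.default_rng([cfg.rng_seed, i + 1])
        for s in range(matrix.shape[0]):
            out[i, s] = rarefy_sample(matrix[s], cfg.base_count, rng,
                                      with_replacement)
    return ResampleSet(out, samples, taxon_ids, families,
                       cfg.base_count, excluded)
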