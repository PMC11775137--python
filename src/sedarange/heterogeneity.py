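"""Biotic heterogeneity as multiple-site Jaccard turnover across lakes.

Beta diversity between the lakes of a time-slice is used as a proxy for
environmental heterogeneity.  Only the turnover (species-replacement)
component is used, so the measure is independent of richness
differences between lakes: with ``a`` shared taxa and ``b_ij``/``b_ji``
the taxa exclusive to each site of a pair,

    β_JTU = 2·Σ_{i<j} min(b_ij, b_ji)
            ─────────────────────────────────────────────
            (Σ_i S_i − S_T) + 2·Σ_{i<j} min(b_ij, b_ji)

the multiple-site Jaccard-family turnover component (Baselga's
partition), which for two sites reduces to the pairwise closed form
``2·min(b₁₂, b₂₁) / (a + 2·min(b₁₂, b₂₁))``.  Identical sites score 0
by convention.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import RunConfig
from .rarefy import ResampleSet
from .windows import Window, make_windows


class InsufficientSitesError(ValueError):
    """Fewer than two non-empty sites."""


def pairwise_components(presence: np.ndarray) -> pd.DataFrame:
    """Shared/exclusive taxon counts for every site pair.

    ``presence`` is a sites × taxa 0/1 matrix.  Returns one row per
    unordered pair (i, j) with ``a`` (shared), ``b_ij`` (in i only) and
    ``b_ji`` (in j only); ``a + b_ij`` equals site i's richness.
    """
    P = np.asarray(presence, bool)
    non_empty = (P.sum(axis=1) > 0).sum()
    if P.shape[0] < 2 or non_empty < 2:
        raise InsufficientSitesError("need at least 2 non-empty sites")
    rows = []
    for i, j in itertools.combinations(range(P.shape[0]), 2):
        a = int((P[i] & P[j]).sum())
        rows.append((i, j, a, int(P[i].sum()) - a, int(P[j].sum()) - a))
    return pd.DataFrame(rows, columns=["site_i", "site_j", "a", "b_ij", "b_ji"])


def multisite_jaccard_turnover(presence: np.ndarray) -> float:
    """Multiple-site Jaccard turnover β_JTU ∈ [0, 1] of an incidence matrix."""
    P = np.asarray(presence, bool)
    comp = pairwise_components(P)
    sum_min = int(np.minimum(comp["b_ij"], comp["b_ji"]).sum())
    s_i = P.sum(axis=1).sum()
    s_t = int((P.any(axis=0)).sum())
    denom = (s_i - s_t) + 2 * sum_min
    if denom == 0:
        return 0.0  # all sites identical: no turnover
    return 2.0 * sum_min / denom


def heterogeneity_series(
    rs: ResampleSet,
    cfg: RunConfig,
) -> pd.DataFrame:
    """β_JTU per (iteration, slice) from rarefied incidences.

    Slices with fewer than two occupied lakes in an iteration get a
    missing value.  Computed from pairwise shared-taxon counts via
    matrix products, vectorised over iterations and slices.
    """
    slice_values = sorted(rs.samples["slice_index"].unique())
    lakes = sorted(rs.samples["lake_id"].unique())
    lake_pos = {l: i for i, l in enumerate(lakes)}
    n_lakes = len(lakes)
    n_iter = rs.n_iterations

    rows = []
    presence = rs.counts > 0
    sample_lake = rs.samples["lake_id"].map(lake_pos).to_numpy()
    sample_slice = rs.samples["slice_index"].to_numpy()
    for t in slice_values:
        sel = sample_slice == t
        lk = sample_lake[sel]
        P = np.zeros((n_iter, n_lakes, presence.shape[2]), dtype=bool)
        P[:, lk, :] = presence[:, sel, :]
        Pi = P.astype(np.int32)
        shared = Pi @ Pi.transpose(0, 2, 1)          # (iter, lake, lake)
        s_site = Pi.sum(axis=2)                      # (iter, lake)
        b_ij = s_site[:, :, None] - shared
        b_ji = s_site[:, None, :] - shared
        mins = np.minimum(b_ij, b_ji)
        iu = np.triu_indices(n_lakes, k=1)
        sum_min = mins[:, iu[0], iu[1]].sum(axis=1)
        s_t = P.any(axis=1).sum(axis=1)
        denom = (s_site.sum(axis=1) - s_t) + 2 * sum_min
        occupied = (s_site > 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(denom > 0, 2.0 * sum_min / denom, 0.0)
        beta = np.where(occupied >= 2, beta, np.nan)
        for i in range(n_iter):
            rows.append((i + 1, t, beta[i]))
    return pd.DataFrame(rows, columns=["iteration", "slice_index", "beta_jtu"])


def window_heterogeneity(
    series: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Mean β_JTU per (iteration, window), the running-window smoothing."""
    windows = make_windows(cfg.n_slices, cfg.window_width_slices,
                           cfg.window_step_slices)
    rows = []
    for w in windows:
        sub = series[series["slice_index"].isin(w.slices)]
        agg = sub.groupby("iteration")["beta_jtu"].mean()
        for iteration, val in agg.items():
            rows.append((w.label, int(iteration), val))
    return pd.DataFrame(rows, columns=["window", "iteration", "beta_jtu"])
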