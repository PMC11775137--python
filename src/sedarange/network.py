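"""Family-level positive co-occurrence network and community structure.

Terrestrial plant taxa are grouped to the family level and families are
filtered to those with at least 10 reads summed over all time-slices
and presence in at least 5 slices.  Pairwise Spearman rank correlations
of the family abundance series (reads per slice, pooled over lakes)
are computed over slices; p-values are Benjamini–Hochberg adjusted over
all tested pairs.  An undirected edge joins two families when r > 0.6
and adjusted p < 0.05 (positive associations only).  Communities are
the modularity-maximising partition — found exactly by enumerating set
partitions per connected component for small components, or by greedy
agglomeration otherwise (the method used is recorded).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OccurrenceTable

#: components larger than this fall back to greedy agglomeration
EXACT_COMPONENT_CAP = 12


class EmptyMatrixError(ValueError):
    """No family survives the read/slice filters."""


@dataclass(frozen=True)
class FamilyAbundanceMatrix:
    """Families × slices read-count matrix after the retention filters."""

    frame: pd.DataFrame           # index: family, columns: slice_index
    dropped: tuple[str, ...]      # families removed by the filters

    @property
    def families(self) -> list[str]:
        return list(self.frame.index)


def aggregate_families(
    table: OccurrenceTable,
    min_reads: int = 10,
    min_slices: int = 5,
    n_slices: int | None = None,
) -> FamilyAbundanceMatrix:
    """Sum reads to family × slice and apply the retention filters."""
    mat = (
        table.frame.groupby(["family", "slice_index"])["reads"].sum()
        .unstack(fill_value=0)
    )
    if n_slices is not None:
        mat = mat.reindex(columns=range(1, n_slices + 1), fill_value=0)
    keep = (mat.sum(axis=1) >= min_reads) & ((mat > 0).sum(axis=1) >= min_slices)
    dropped = tuple(mat.index[~keep])
    mat = mat.loc[keep]
    if mat.empty:
        raise EmptyMatrixError("no family passes the read/slice filters")
    return FamilyAbundanceMatrix(mat, dropped)


@dataclass(frozen=True)
class SpearmanStats:
    families: tuple[str, ...]
    r: np.ndarray        # symmetric, NaN diagonal/undefined pairs
    p: np.ndarray
    p_adj: np.ndarray    # BH over the tested upper triangle


def spearman_matrix(matrix: FamilyAbundanceMatrix) -> SpearmanStats:
    """All-pairs Spearman correlation of family series across slices.

    Ties get average ranks; p-values use the t approximation
    ``t = r·√((n−2)/(1−r²))`` on n−2 df.  Pairs involving a constant
    series are flagged undefined (NaN) and excluded from the BH
    adjustment.
    """
    data = matrix.frame.to_numpy(float)
    m, n = data.shape
    if m < 2:
        raise ValueError("need at least 2 retained families")
    if n < 4:
        raise ValueError("need at least 4 slices")
    constant = np.ptp(data, axis=1) == 0
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0

    iu = np.triu_indices(m, k=1)
    flat_p = p[iu]
    tested = np.isfinite(flat_p)
    p_adj = np.full_like(flat_p, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(flat_p[tested], method="fdr_bh")[1]
    p_adj_mat = np.full((m, m), np.nan)
    p_adj_mat[iu] = p_adj
    p_adj_mat[(iu[1], iu[0])] = p_adj
    return SpearmanStats(tuple(matrix.families), r, p, p_adj_mat)


def build_network(
    statistics: SpearmanStats,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
) -> nx.Graph:
    """Positive co-occurrence graph: edge iff r > threshold and p_adj < alpha.

    All retained families appear as nodes; families with no qualifying
    correlation stay isolated with degree 0.
    """
    g = nx.Graph()
    g.add_nodes_from(statistics.families)
    m = len(statistics.families)
    for i, j in itertools.combinations(range(m), 2):
        r, q = statistics.r[i, j], statistics.p_adj[i, j]
        if np.isfinite(r) and np.isfinite(q) and r > r_threshold and q < alpha:
            g.add_edge(statistics.families[i], statistics.families[j],
                       r=float(r), p_adj=float(q))
    return g


def _exact_component_partition(
    nodes: list, adj: dict, degree: dict, m_edges: float
) -> list[set]:
    """Modularity-optimal partition of one connected component.

    Enumerates set partitions in restricted-growth order, tracking each
    block's internal edge count and degree sum incrementally; the
    objective uses the whole graph's edge count, so the per-component
    optima compose into the global optimum (communities never span
    disconnected components).
    """
    best_q = -np.inf
    best: list[set] | None = None
    n = len(nodes)

    def recurse(i: int, blocks: list[list], internal: list[int], degsum: list[float]):
        nonlocal best_q, best
        if i == n:
            q = sum(e / m_edges - (d / (2 * m_edges)) ** 2
                    for e, d in zip(internal, degsum))
            if q > best_q:
                best_q = q
                best = [set(b) for b in blocks]
            return
        v = nodes[i]
        for b in range(len(blocks)):
            links = sum(1 for u in blocks[b] if u in adj[v])
            blocks[b].append(v)
            internal[b] += links
            degsum[b] += degree[v]
            recurse(i + 1, blocks, internal, degsum)
            blocks[b].pop()
            internal[b] -= links
            degsum[b] -= degree[v]
        blocks.append([v])
        internal.append(0)
        degsum.append(degree[v])
        recurse(i + 1, blocks, internal, degsum)
        blocks.pop()
        internal.pop()
        degsum.pop()

    recurse(0, [], [], [])
    return best


def detect_communities(g: nx.Graph) -> tuple[list[set], str]:
    """Modularity-maximising partition of a co-occurrence graph.

    Components with at most :data:`EXACT_COMPONENT_CAP` nodes are solved
    exactly by partition enumeration; larger components use greedy
    modularity agglomeration.  Isolated (degree-0) nodes each form their
    own community.  Returns ``(partition, method)`` where method is
    ``"exact"`` or ``"greedy"`` (greedy if any component needed it).
    """
    m_edges = g.number_of_edges()
    if m_edges == 0:
        return [{v} for v in g.nodes], "trivial"
    degree = dict(g.degree)
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    partition: list[set] = [{v} for v, d in degree.items() if d == 0]
    method = "exact"
    for comp in nx.connected_components(g):
        comp = [v for v in comp if degree[v] > 0]
        if not comp:
            continue
        if len(comp) <= EXACT_COMPONENT_CAP:
            partition.extend(_exact_component_partition(comp, adj, degree,
                                                        float(m_edges)))
        else:
            sub = g.subgraph(comp)
            partition.extend(
                set(c) for c in
                nx.community.greedy_modularity_communities(sub, weight=None)
            )
            method = "greedy"
    return partition, method


def modularity(g: nx.Graph, partition: list[set]) -> float:
    return nx.community.modularity(g, partition, weight=None)


def community_metrics(g: nx.Graph, partition: list[set]) -> pd.DataFrame:
    """Node/edge bookkeeping per community.

    ``positive_link_pct`` expresses a community's internal edges as a
    percentage of all network edges; internal and total counts are both
    reported so alternative denominators can be formed.
    """
    total = g.number_of_edges()
    rows = []
    for ci, comm in enumerate(partition):
        internal = g.subgraph(comm).number_of_edges()
        rows.append({
            "community": ci,
            "n_nodes": len(comm),
            "internal_edges": internal,
            "total_edges": total,
            "positive_link_pct": 100.0 * internal / total if total else np.nan,
            "members": ";".join(sorted(map(str, comm))),
        })
    return pd.DataFrame(rows)


def label_communities(
    partition: list[set],
    matrix: FamilyAbundanceMatrix,
    regime_boundary_slice: int = 11,
) -> dict[int, str]:
    """Label each community glacial/holocene by where its reads concentrate.

    A community is "glacial" when its member families hold more summed
    reads in slices older than the boundary than in younger slices.
    Reporting convenience only.
    """
    cols = matrix.frame.columns.to_numpy()
    glacial_cols = cols > regime_boundary_slice
    labels = {}
    for ci, comm in enumerate(partition):
        members = [f for f in comm if f in matrix.frame.index]
        if not members:
            labels[ci] = "unknown"
            continue
        sub = matrix.frame.loc[members].to_numpy(float)
        g_reads = sub[:, glacial_cols].sum()
        h_reads = sub[:, ~glacial_cols].sum()
        labels[ci] = "glacial" if g_reads > h_reads else "holocene"
    return labels


def node_table(g: nx.Graph, partition: list[set]) -> pd.DataFrame:
    comm_of = {v: ci for ci, comm in enumerate(partition) for v in comm}
    return pd.DataFrame(
        [{"family": v, "degree": d, "community": comm_of.get(v, -1)}
         for v, d in g.degree]
    ).sort_values("family").reset_index(drop=True)


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [{"family_a": a, "family_b": b, "r": d["r"], "p_adj": d["p_adj"]}
            for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["family_a", "family_b", "r", "p_adj"])
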