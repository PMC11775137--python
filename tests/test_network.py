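"""Family filtering, correlation thresholds, modularity communities."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import sedarange as sr
from sedarange.network import (EmptyMatrixError, FamilyAbundanceMatrix,
                               SpearmanStats, aggregate_families,
                               build_network, community_metrics,
                               detect_communities, label_communities,
                               modularity, spearman_matrix)

from conftest import make_occurrence


def family_table(series: dict, reads_scale=1):
    rows = []
    for fam, vals in series.items():
        for t, v in enumerate(vals, start=1):
            if v > 0:
                rows.append(("L1", t, f"{fam}_sp", fam, v * reads_scale))
    return make_occurrence(rows)


class TestAggregateFamilies:
    def test_retention_filters(self):
        table = family_table({
            "LowReads": [1, 1, 1, 1, 1, 1, 1, 1, 1],        # 9 reads, 9 slices
            "FewSlices": [250, 250, 250, 250, 0, 0, 0, 0, 0],  # 4 slices
            "Keeps": [2, 2, 2, 2, 2, 0, 0, 0, 0],           # 10 reads, 5 slices
        })
        fam = aggregate_families(table, min_reads=10, min_slices=5)
        assert fam.families == ["Keeps"]
        assert set(fam.dropped) == {"LowReads", "FewSlices"}

    def test_empty_after_filter_raises(self):
        table = family_table({"OnlyOne": [1, 1, 0, 0, 0, 0]})
        with pytest.raises(EmptyMatrixError):
            aggregate_families(table, min_reads=10, min_slices=5)

    def test_reads_summed_over_lakes_and_taxa(self):
        rows = [("L1", 1, "a1", "Fam", 5), ("L2", 1, "a2", "Fam", 7)]
        table = make_occurrence(rows)
        fam = aggregate_families(table, min_reads=1, min_slices=1)
        assert fam.frame.loc["Fam", 1] == 12


def _stats_matrix(series: dict):
    frame = pd.DataFrame(series).T
    frame.columns = range(1, frame.shape[1] + 1)
    return FamilyAbundanceMatrix(frame, ())


class TestSpearmanMatrix:
    def test_identical_and_reversed_series(self):
        st = spearman_matrix(_stats_matrix({
            "A": [1, 2, 3, 4, 5, 6],
            "B": [2, 4, 6, 8, 10, 12],
            "C": [6, 5, 4, 3, 2, 1],
        }))
        i, j, k = (st.families.index(x) for x in ("A", "B", "C"))
        assert st.r[i, j] == pytest.approx(1.0)
        assert st.r[i, k] == pytest.approx(-1.0)

    def test_constant_series_flagged_undefined(self):
        st = spearman_matrix(_stats_matrix({
            "A": [1, 2, 3, 4], "B": [5, 5, 5, 5], "C": [4, 3, 2, 1]}))
        b = st.families.index("B")
        assert np.isnan(st.r[b]).all()

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        series = {f"F{i}": rng.integers(0, 100, 12) for i in range(6)}
        st = spearman_matrix(_stats_matrix(series))
        iu = np.triu_indices(6, 1)
        p = st.p[iu]
        q = st.p_adj[iu]
        assert (q >= p - 1e-15).all()
        # direct step-up rule
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        assert np.allclose(q[order], expected, atol=1e-12)


class TestBuildNetwork:
    def _stats(self, r, q):
        arr_r = np.array([[np.nan, r], [r, np.nan]])
        arr_q = np.array([[np.nan, q], [q, np.nan]])
        return SpearmanStats(("A", "B"), arr_r, arr_q.copy(), arr_q)

    def test_edge_requires_both_thresholds(self):
        assert build_network(self._stats(0.61, 0.01)).number_of_edges() == 1
        assert build_network(self._stats(0.9, 0.2)).number_of_edges() == 0
        assert build_network(self._stats(-0.9, 1e-6)).number_of_edges() == 0

    def test_isolated_nodes_kept_with_zero_degree(self):
        g = build_network(self._stats(0.1, 0.9))
        assert g.number_of_nodes() == 2
        assert dict(g.degree) == {"A": 0, "B": 0}


def partitions_oracle(nodes):
    """Every set partition, generated by recursive placement."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in partitions_oracle(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


def best_modularity_oracle(g):
    return max(modularity(g, p) for p in partitions_oracle(list(g.nodes)))


class TestDetectCommunities:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        part, method = detect_communities(g)
        assert method == "exact"
        assert sorted(map(sorted, part)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_triangle_one_community(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0)])
        part, _ = detect_communities(g)
        assert part == [{0, 1, 2}]

    def test_edgeless_network_trivial_partition(self):
        g = nx.empty_graph(4)
        part, method = detect_communities(g)
        assert method == "trivial"
        assert len(part) == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_optimum_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        if g.number_of_edges() == 0:
            return
        part, method = detect_communities(g)
        assert modularity(g, part) == pytest.approx(
            best_modularity_oracle(g), abs=1e-12)

    def test_beats_random_partitions(self):
        g = nx.gnp_random_graph(10, 0.4, seed=7)
        part, _ = detect_communities(g)
        q = modularity(g, part)
        rng = np.random.default_rng(7)
        for _ in range(1000):
            labels = rng.integers(0, 3, 10)
            rand = [set(np.flatnonzero(labels == k)) for k in range(3)
                    if (labels == k).any()]
            assert q >= modularity(g, rand) - 1e-12


class TestCommunityMetrics:
    def test_triangle_full_share(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0)])
        m = community_metrics(g, [{0, 1, 2}])
        assert m.internal_edges.iloc[0] == 3
        assert m.positive_link_pct.iloc[0] == 100.0

    def test_two_triangles_split_half(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        m = community_metrics(g, [{0, 1, 2}, {3, 4, 5}])
        assert m.internal_edges.tolist() == [3, 3]
        assert m.positive_link_pct.tolist() == [50.0, 50.0]

    def test_block_structured_families_label_and_order(self):
        # two family blocks: one concentrated in old (glacial) slices,
        # one in young slices; block sizes 4 vs 2 → more glacial edges
        rng = np.random.default_rng(3)
        slices = np.arange(1, 31)
        step_old = np.where(slices > 11, 300.0, 20.0)
        step_new = np.where(slices <= 11, 300.0, 20.0)
        series = {}
        for i in range(4):
            series[f"G{i}"] = step_old * rng.lognormal(0, 0.15, 30)
        for i in range(2):
            series[f"H{i}"] = step_new * rng.lognormal(0, 0.15, 30)
        frame = pd.DataFrame(series).T
        frame.columns = slices
        fam = FamilyAbundanceMatrix(frame, ())
        g = build_network(spearman_matrix(fam))
        part, _ = detect_communities(g)
        labels = label_communities(part, fam)
        m = community_metrics(g, part)
        m["label"] = m.community.map(labels)
        by_label = m.groupby("label").internal_edges.sum()
        assert by_label["glacial"] > by_label["holocene"]
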