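"""Correlation clustering: threshold partitions, Dunn index, partition
selection, and the minimum spanning tree, cross-checked against
independent brute-force constructions."""

import numpy as np
import pandas as pd
import pytest

from milkcog.clustering import (
    DunnUndefinedError,
    dunn_index,
    minimum_spanning_tree,
    optimal_partition,
    pairwise_correlations,
    partition_table,
    single_linkage_clusters,
)
from milkcog.cohort import CorrelationTarget, default_correlation_target

from conftest import random_correlation


def components_oracle(matrix: np.ndarray, tc: float) -> list[set[int]]:
    """Brute-force connected components of the graph {r_ij > tc}."""
    p = len(matrix)
    seen = set()
    comps = []
    for start in range(p):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for j in range(p):
                if j != i and matrix[i, j] > tc and j not in comp:
                    stack.append(j)
        seen |= comp
        comps.append(comp)
    return comps


def as_sets(labels: dict[str, int], names: list[str]) -> set[frozenset]:
    by_cluster: dict[int, set] = {}
    for idx, name in enumerate(names):
        by_cluster.setdefault(labels[name], set()).add(idx)
    return {frozenset(s) for s in by_cluster.values()}


class TestPairwiseCorrelations:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(30)})
        out = pairwise_correlations(df)
        assert out.matrix[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": -x})
        out = pairwise_correlations(df)
        assert out.matrix[0, 1] == pytest.approx(-1.0)

    def test_constructed_exact_correlation(self):
        """Two vectors built from orthonormal components with r = 0.8."""
        n = 20
        u = np.zeros(n)
        u[0], u[1] = 1.0, -1.0
        v = np.zeros(n)
        v[2], v[3] = 1.0, -1.0
        y = 0.8 * u + 0.6 * v
        df = pd.DataFrame({"x": u, "y": y, "z": v})
        out = pairwise_correlations(df)
        assert out.matrix[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_pvalue_matrices_align_with_statsmodels(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        df = random_correlation(5, rng)
        out = pairwise_correlations(df)
        r, p = stats.pearsonr(df.iloc[:, 0], df.iloc[:, 1])
        assert out.matrix[0, 1] == pytest.approx(r, abs=1e-12)
        assert out.p_raw[0, 1] == pytest.approx(p, abs=1e-10)
        assert (out.p_adj >= out.p_raw - 1e-12).all()

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pairwise_correlations(df)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        df = random_correlation(4, rng)
        scaled = df * [10.0, 0.01, 3.0, 7.0]
        a = pairwise_correlations(df)
        b = pairwise_correlations(scaled)
        assert np.allclose(a.matrix, b.matrix, atol=1e-12)


class TestThresholdClusters:
    def test_single_edge_above_threshold(self):
        m = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.3], [0.2, 0.3, 1.0]])
        corr = CorrelationTarget(["a", "b", "c"], m)
        sol = single_linkage_clusters(corr, tc=0.5)
        assert as_sets(sol.labels, ["a", "b", "c"]) == {frozenset({0, 1}), frozenset({2})}

    def test_threshold_above_all_gives_singletons(self):
        m = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
        corr = CorrelationTarget(["a", "b", "c"], m)
        sol = single_linkage_clusters(corr, tc=0.9)
        assert sol.k == 3

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_component_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        df = random_correlation(8, rng)
        corr = pairwise_correlations(df)
        off = corr.matrix[~np.eye(8, dtype=bool)]
        for tc in rng.uniform(off.min(), off.max(), 4):
            sol = single_linkage_clusters(corr, float(tc))
            oracle = {frozenset(c) for c in components_oracle(corr.matrix, tc)}
            assert as_sets(sol.labels, corr.labels) == oracle


class TestDunnIndex:
    def test_hand_computed_ratio(self):
        """Two tight pairs at diameter 0.1, separation 0.9: Dunn = 9."""
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        assert dunn_index(d, np.array([0, 0, 1, 1])) == pytest.approx(9.0)

    def test_single_cluster_undefined(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(DunnUndefinedError):
            dunn_index(d, np.zeros(3))

    def test_all_singletons_undefined(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(DunnUndefinedError):
            dunn_index(d, np.arange(3))

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert dunn_index(3.7 * d, labels) == pytest.approx(dunn_index(d, labels))


def brute_force_best_cut(matrix: np.ndarray):
    """Exhaustive evaluation of every threshold partition by scanning all
    midpoints between consecutive distinct off-diagonal correlations."""
    p = len(matrix)
    off = np.unique(matrix[~np.eye(p, dtype=bool)])
    cuts = [(off[i] + off[i + 1]) / 2 for i in range(len(off) - 1)]
    d = 1.0 - matrix
    np.fill_diagonal(d, 0.0)
    best = None
    for tc in cuts:
        comps = components_oracle(matrix, tc)
        if len(comps) < 2 or all(len(c) == 1 for c in comps):
            continue
        labels = np.empty(p, dtype=int)
        for cid, comp in enumerate(comps):
            for i in comp:
                labels[i] = cid
        val = dunn_index(d, labels)
        key = (val, -len(comps))
        if best is None or key > best[0]:
            best = (key, {frozenset(c) for c in comps})
    return best[1]


class TestOptimalPartition:
    def test_two_separated_blocks_select_k2(self):
        names = [f"v{i}" for i in range(6)]
        m = np.full((6, 6), 0.05)
        m[:3, :3] = 0.9
        m[3:, 3:] = 0.9
        np.fill_diagonal(m, 1.0)
        scan = optimal_partition(CorrelationTarget(names, m))
        assert scan.selected.k == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_cut_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        df = random_correlation(10, rng)
        corr = pairwise_correlations(df)
        scan = optimal_partition(corr)
        assert as_sets(scan.selected.labels, corr.labels) == brute_force_best_cut(corr.matrix)

    def test_intervals_tile_offdiagonal_range(self):
        rng = np.random.default_rng(5)
        df = random_correlation(9, rng)
        corr = pairwise_correlations(df)
        scan = optimal_partition(corr)
        sols = sorted(scan.solutions, key=lambda s: -s.tc_interval[1])
        off = corr.matrix[~np.eye(9, dtype=bool)]
        assert sols[0].tc_interval[1] == pytest.approx(off.max())
        assert sols[-1].tc_interval[0] == pytest.approx(off.min())
        for a, b in zip(sols, sols[1:]):
            assert a.tc_interval[0] == pytest.approx(b.tc_interval[1])

    def test_selected_dunn_dominates_all_cuts(self):
        rng = np.random.default_rng(6)
        df = random_correlation(8, rng)
        scan = optimal_partition(pairwise_correlations(df))
        for s in scan.solutions:
            if s.dunn is not None:
                assert scan.selected.dunn >= s.dunn - 1e-12

    def test_partition_table_shape_and_interval_format(self):
        scan = optimal_partition(default_correlation_target())
        table = partition_table(scan)
        assert "Dunn index" in table.index
        assert all(" < Tc <= " in c for c in table.columns)
        # the default block target yields the 7-cluster reference partition
        assert scan.selected.k == 7


class TestMinimumSpanningTree:
    def test_two_nodes_single_edge(self):
        m = np.array([[1.0, 0.6], [0.6, 1.0]])
        mst = minimum_spanning_tree(CorrelationTarget(["a", "b"], m))
        assert mst.edges == [("a", "b", pytest.approx(0.6))]

    def test_hand_run_kruskal_on_toy(self):
        """Greedy edge selection by hand: ab (0.9), cd (0.8), bc (0.5)."""
        names = ["a", "b", "c", "d"]
        m = np.array([
            [1.0, 0.9, 0.5, 0.1],
            [0.9, 1.0, 0.4, 0.2],
            [0.5, 0.4, 1.0, 0.8],
            [0.1, 0.2, 0.8, 1.0],
        ])
        mst = minimum_spanning_tree(CorrelationTarget(names, m))
        got = {frozenset((e[0], e[1])) for e in mst.edges}
        assert got == {frozenset("ab"), frozenset("cd"), frozenset({"a", "c"})}

    @pytest.mark.parametrize("seed", range(8))
    def test_tree_properties_and_cut_equivalence(self, seed):
        rng = np.random.default_rng(200 + seed)
        df = random_correlation(9, rng)
        corr = pairwise_correlations(df)
        mst = minimum_spanning_tree(corr)
        assert len(mst.edges) == 8
        # cutting MST edges at tc reproduces the threshold partition
        off = corr.matrix[~np.eye(9, dtype=bool)]
        for tc in rng.uniform(off.min(), off.max(), 3):
            kept = mst.cut(float(tc))
            parent = {l: l for l in corr.labels}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b, _ in kept:
                parent[find(a)] = find(b)
            mst_part = {}
            for name in corr.labels:
                mst_part.setdefault(find(name), set()).add(name)
            sol = single_linkage_clusters(corr, float(tc))
            want = {frozenset(v) for v in sol.members().values()}
            assert {frozenset(v) for v in mst_part.values()} == want
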