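"""Nutrient correlation structure: single-linkage clustering, Dunn-index
partition choice, and the minimum spanning tree.

Collinear nutrients are grouped by thresholding their Pearson correlations:
at threshold Tc, two nutrients join one cluster when r > Tc, which is
exactly (i) the connected components of the graph with edges {r_ij > Tc}
and (ii) a cut of the single-linkage merge tree under the distance
d = 1 - r.  Every distinct partition produced between consecutive merge
heights is scored with the Dunn index (minimum single-linkage inter-cluster
separation over maximum intra-cluster diameter, singletons contributing
diameter zero) and the maximizer is selected.  The MST under d = 1 - r
gives the interpretable backbone: removing its edges with r <= Tc
reproduces the threshold partition.

Thresholds are compared strictly (r > Tc); reported stability intervals are
printed as "(low < Tc <= high]", whose upper endpoint is the merge
correlation that dissolves the partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree as _csgraph_mst
from scipy.spatial.distance import squareform
from scipy.special import betainc

from .cohort import CorrelationTarget
from .marginal import bh_adjust

__all__ = [
    "NutrientCorrelations",
    "ClusterSolution",
    "SpanningTree",
    "DunnUndefinedError",
    "pairwise_correlations",
    "correlation_distance",
    "single_linkage_clusters",
    "dunn_index",
    "optimal_partition",
    "minimum_spanning_tree",
    "partition_table",
]


class DunnUndefinedError(ValueError):
    """The Dunn index is undefined (fewer than 2 clusters, or no cluster
    with at least 2 members)."""


@dataclass
class NutrientCorrelations:
    """Pairwise Pearson correlations with raw and FDR-adjusted p-values."""

    labels: list[str]
    matrix: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray

    def as_target(self) -> CorrelationTarget:
        return CorrelationTarget(labels=list(self.labels), matrix=self.matrix.copy())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class ClusterSolution:
    """A partition of the nutrients with its threshold-stability interval."""

    k: int
    labels: dict[str, int]
    tc_interval: tuple[float, float]  # (low, high]
    dunn: float | None

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.labels.items():
            out.setdefault(cid, []).append(name)
        return out

    @property
    def interval_label(self) -> str:
        lo, hi = self.tc_interval
        return f"{lo:.2f} < Tc <= {hi:.2f}"


@dataclass
class SpanningTree:
    """MST edge list (nutrient, nutrient, correlation)."""

    edges: list[tuple[str, str, float]]

    def cut(self, tc: float) -> list[tuple[str, str, float]]:
        """Edges retained after removing those with r <= tc."""
        return [e for e in self.edges if e[2] > tc]


def pairwise_correlations(df: pd.DataFrame, columns: list[str] | None = None) -> NutrientCorrelations:
    """Pearson correlation matrix of the named columns, with two-sided
    p-values and BH adjustment over the distinct pairs."""
    columns = columns if columns is not None else list(df.columns)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for correlations")
    x = df[columns].to_numpy(dtype=float)
    sds = x.std(axis=0, ddof=1)
    bad = [c for c, s in zip(columns, sds) if s == 0]
    if bad:
        raise ValueError(f"constant columns: {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0  # exact symmetry (corrcoef carries ~1e-17 asymmetry)
    np.fill_diagonal(r, 1.0)
    n = len(df)
    # two-sided p for Pearson r via the incomplete beta function
    rc = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    p = betainc((n - 2) / 2.0, 0.5, 1.0 - rc**2)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices_from(p, k=1)
    adj_flat = bh_adjust(p[iu])
    p_adj = np.zeros_like(p)
    p_adj[iu] = adj_flat
    p_adj = p_adj + p_adj.T
    return NutrientCorrelations(list(columns), r, p, p_adj)


def correlation_distance(matrix: np.ndarray, absolute: bool = False) -> np.ndarray:
    """Distance matrix 1 - r (or 1 - |r| when ``absolute``)."""
    r = np.abs(matrix) if absolute else matrix
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _canonical_labels(labels: list[str], comp: np.ndarray) -> dict[str, int]:
    """Renumber components by first appearance so labellings compare equal."""
    remap: dict[int, int] = {}
    out = {}
    for name, c in zip(labels, comp):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[name] = remap[c]
    return out


def _merge_heights(dist: np.ndarray) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method="single")
    return z


def _partition_after(z: np.ndarray, n: int, m: int) -> np.ndarray:
    """Component index per leaf after applying the first m merges of a
    linkage matrix (union-find over the merge rows)."""
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rep = list(range(n))  # representative leaf per linkage cluster id
    for row in range(m):
        a, b = int(z[row, 0]), int(z[row, 1])
        ra, rb = find(rep[a]), find(rep[b])
        parent[rb] = ra
        rep.append(ra)
    return np.array([find(i) for i in range(n)])


def single_linkage_clusters(
    corr: CorrelationTarget | NutrientCorrelations, tc: float, absolute: bool = False
) -> ClusterSolution:
    """Partition at threshold ``tc``: connected components of {r > tc}.

    The equivalent merge-tree cut (at distance 1 - tc) is used to report the
    stability interval; both constructions coincide for single linkage.
    """
    if not -1 < tc < 1:
        raise ValueError("tc must lie in (-1, 1)")
    labels, mat = list(corr.labels), np.asarray(corr.matrix, dtype=float)
    sim = np.abs(mat) if absolute else mat
    adjacency = csr_matrix((sim > tc).astype(np.int8))
    _, comp = connected_components(adjacency, directed=False)
    lab = _canonical_labels(labels, comp)
    scan = optimal_partition(corr, absolute=absolute)
    for sol in scan.solutions:
        if sol.labels == lab:
            return ClusterSolution(
                k=sol.k, labels=lab, tc_interval=sol.tc_interval, dunn=sol.dunn,
            )
    # tc outside the merge range: all singletons (above) or irrelevant (below)
    d = correlation_distance(mat, absolute)
    dunn = None
    k = len(set(lab.values()))
    if 2 <= k <= len(labels):
        try:
            dunn = dunn_index(d, np.array([lab[l] for l in labels]))
        except DunnUndefinedError:
            dunn = None
    offdiag = mat[~np.eye(len(labels), dtype=bool)]
    hi = float(offdiag.max())
    interval = (hi, 1.0) if tc > hi else (-1.0, float(offdiag.min()))
    return ClusterSolution(k=k, labels=lab, tc_interval=interval, dunn=dunn)


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min single-linkage inter-cluster separation over max cluster diameter.

    Singleton clusters contribute diameter 0.  Raises
    :class:`DunnUndefinedError` when fewer than 2 clusters exist or every
    cluster is a singleton (zero maximum diameter).
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise DunnUndefinedError("need at least 2 clusters")
    groups = [np.flatnonzero(labels == c) for c in ids]
    max_diam = 0.0
    for g in groups:
        if len(g) > 1:
            block = dist[np.ix_(g, g)]
            max_diam = max(max_diam, float(block.max()))
    if max_diam == 0.0:
        raise DunnUndefinedError("all clusters are singletons (zero diameter)")
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            sep = float(dist[np.ix_(groups[i], groups[j])].min())
            min_sep = min(min_sep, sep)
    return min_sep / max_diam


@dataclass
class PartitionScan:
    """All merge-tree partitions with their Dunn indices, and the selected one."""

    solutions: list[ClusterSolution]
    selected: ClusterSolution


def optimal_partition(
    corr: CorrelationTarget | NutrientCorrelations, absolute: bool = False
) -> PartitionScan:
    """Evaluate every partition produced by cutting the single-linkage tree
    between consecutive merge heights and select the Dunn maximizer.

    Ties break toward fewer clusters, then the lower threshold interval.
    """
    labels = list(corr.labels)
    mat = np.asarray(corr.matrix, dtype=float)
    n = len(labels)
    d = correlation_distance(mat, absolute)
    z = _merge_heights(d)
    merge_corr = 1.0 - z[:, 2]  # descending
    offdiag = mat[~np.eye(n, dtype=bool)]
    floor = float(np.min(np.abs(offdiag)) if absolute else offdiag.min())
    solutions = []
    for m in range(1, n):
        hi = float(merge_corr[m - 1])
        lo = float(merge_corr[m]) if m < n - 1 else floor
        if hi - lo <= 1e-12 and m < n - 1:
            continue  # tied merge heights: not a distinct stable partition
        comp = _partition_after(z, n, m)
        lab = _canonical_labels(labels, comp)
        k = len(set(lab.values()))
        try:
            dunn = dunn_index(d, comp)
        except DunnUndefinedError:
            dunn = None
        solutions.append(ClusterSolution(k=k, labels=lab, tc_interval=(lo, hi), dunn=dunn))
    scored = [s for s in solutions if s.dunn is not None]
    if not scored:
        raise ValueError("no partition with a defined Dunn index")
    selected = max(scored, key=lambda s: (s.dunn, -s.k, -s.tc_interval[1]))
    return PartitionScan(solutions=solutions, selected=selected)


def minimum_spanning_tree(
    corr: CorrelationTarget | NutrientCorrelations, absolute: bool = False
) -> SpanningTree:
    """MST under distance 1 - r, edges annotated with r."""
    labels = list(corr.labels)
    mat = np.asarray(corr.matrix, dtype=float)
    d = correlation_distance(mat, absolute)
    d = np.where(d <= 0, 1e-12, d)  # csgraph drops explicit zeros
    np.fill_diagonal(d, 0.0)
    mst = _csgraph_mst(csr_matrix(d)).tocoo()
    edges = [
        (labels[i], labels[j], float(mat[i, j]))
        for i, j in zip(mst.row, mst.col)
    ]
    edges.sort(key=lambda e: -e[2])
    return SpanningTree(edges=edges)


def partition_table(scan: PartitionScan, max_solutions: int | None = None) -> pd.DataFrame:
    """Render the partition scan as a groups-by-threshold-interval table:
    one column per partition (header is its Tc interval), group memberships
    as rows and the Dunn index as the final row."""
    sols = sorted(
        (s for s in scan.solutions), key=lambda s: -s.tc_interval[1]
    )
    if max_solutions is not None:
        sols = sols[:max_solutions]
    kmax = max(s.k for s in sols)
    data = {}
    for s in sols:
        members = s.members()
        col = []
        for cid in range(1, kmax + 1):
            col.append(", ".join(members[cid]) if cid in members else "-")
        col.append("" if s.dunn is None else f"{s.dunn:.2f}")
        data[s.interval_label] = col
    index = [f"Group {i}" for i in range(1, kmax + 1)] + ["Dunn index"]
    return pd.DataFrame(data, index=index)
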