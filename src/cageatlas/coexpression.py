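"""Correlation graphs, Markov clustering and the stage-ordered variant.

Correlations are computed on log2(TPM + 1).  The Markov cluster algorithm is
implemented here in full (expansion by matrix squaring, entry-wise inflation,
column renormalisation, pruning) because the clustering itself is the
analytical core of the pipeline; it is deterministic for a given graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import atlas as catlas
from . import io as cio


@dataclass
class CorrelationGraph:
    """Undirected graph with Pearson-r edge weights at or above ``cutoff``."""

    graph: nx.Graph
    cutoff: float
    zero_variance: set = field(default_factory=set)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass
class ClusterPartition:
    """Disjoint clusters plus the below-cutoff isolates."""

    clusters: dict[int, set]
    unassigned: set = field(default_factory=set)
    converged: bool = True

    def labels(self) -> dict:
        out = {}
        for cid, members in self.clusters.items():
            for m in members:
                out[m] = cid
        return out

    def all_nodes(self) -> set:
        nodes = set(self.unassigned)
        for members in self.clusters.values():
            nodes |= members
        return nodes


def log_transform(matrix: cio.ExpressionMatrix) -> cio.ExpressionMatrix:
    """log2(TPM + 1)."""
    if matrix.units != "tpm":
        raise ValueError(f"expected a tpm matrix, got units={matrix.units!r}")
    if (matrix.values.values < 0).any():
        raise ValueError("negative TPM values")
    return cio.ExpressionMatrix(values=np.log2(matrix.values + 1.0), units="log2tpm")


def pearson_graph(matrix: cio.ExpressionMatrix, cutoff: float) -> CorrelationGraph:
    """Thresholded all-pairs Pearson correlation over matrix rows.

    Rows with zero variance get no edges and are reported in
    ``zero_variance``.  All rows appear as nodes regardless of degree.
    """
    values = matrix.values
    if values.shape[1] < 3:
        raise ValueError("need >= 3 observations per row for correlation")
    X = values.to_numpy(dtype=float)
    ids = list(values.index)
    sd = X.std(axis=1)
    zero_var = {ids[i] for i in np.flatnonzero(sd == 0)}
    g = nx.Graph()
    g.add_nodes_from(ids)
    ok = np.flatnonzero(sd > 0)
    if len(ok) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(X[ok])
        iu, ju = np.triu_indices(len(ok), k=1)
        mask = r[iu, ju] >= cutoff
        for i, j, w in zip(iu[mask], ju[mask], r[iu[mask], ju[mask]]):
            g.add_edge(ids[ok[i]], ids[ok[j]], weight=float(min(w, 1.0)))
    return CorrelationGraph(graph=g, cutoff=cutoff, zero_variance=zero_var)


def mcl(
    graph: CorrelationGraph | nx.Graph,
    inflation: float = 2.2,
    expansion: int = 2,
    max_iter: int = 200,
    prune_threshold: float = 1e-5,
    tol: float = 1e-8,
) -> ClusterPartition:
    """Markov cluster algorithm on the weighted adjacency matrix.

    Self-loops of weight 1 are added, columns are normalised to stochastic,
    then expansion (matrix power) alternates with inflation (entry-wise
    power + renormalisation) and pruning until the matrix stops changing.
    Clusters are read off as connected components of the non-zero structure
    of the limit matrix.  Nodes with no edges at all are reported as
    ``unassigned`` rather than as singleton clusters.
    """
    g = graph.graph if isinstance(graph, CorrelationGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes, key=str)
    unassigned = {n for n in nodes if g.degree(n) == 0}
    active = [n for n in nodes if n not in unassigned]
    if not active:
        return ClusterPartition(clusters={}, unassigned=unassigned)
    index = {n: i for i, n in enumerate(active)}
    n = len(active)
    M = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        if u in index and v in index:
            w = float(data.get("weight", 1.0))
            M[index[u], index[v]] = w
            M[index[v], index[u]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if prev.shape == M.shape and np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; interpreting current matrix")

    structure = (M > prune_threshold) | (M > prune_threshold).T
    comp_graph = nx.from_numpy_array(structure.astype(float))
    clusters: dict[int, set] = {}
    comps = sorted(
        (sorted((active[i] for i in comp), key=str) for comp in nx.connected_components(comp_graph)),
        key=lambda members: str(members[0]),
    )
    for cid, members in enumerate(comps):
        clusters[cid] = set(members)
    return ClusterPartition(clusters=clusters, unassigned=unassigned, converged=converged)


def filter_clusters(
    partition: ClusterPartition,
    atlas: catlas.Atlas,
    min_members: int = 20,
    min_genes: int = 5,
) -> ClusterPartition:
    """Keep clusters with >= min_members TSSs and >= min_genes distinct genes.

    Intergenic members count toward membership but contribute no gene.
    """
    gene_of = atlas.clusters["gene_id"]
    kept = {}
    for cid, members in partition.clusters.items():
        if len(members) < min_members:
            continue
        genes = {gene_of.get(m) for m in members} - {None}
        genes = {g for g in genes if isinstance(g, str)}
        if len(genes) < min_genes:
            continue
        kept[cid] = set(members)
    return ClusterPartition(
        clusters=kept, unassigned=set(partition.unassigned), converged=partition.converged
    )


def cluster_profile(
    partition: ClusterPartition, matrix: cio.ExpressionMatrix
) -> pd.DataFrame:
    """Per-cluster arithmetic mean expression vector over samples."""
    rows = {}
    for cid, members in partition.clusters.items():
        missing = [m for m in members if m not in matrix.values.index]
        if missing:
            raise KeyError(f"cluster {cid} members absent from matrix: {missing[:3]}")
        rows[cid] = matrix.values.loc[sorted(members, key=str)].mean(axis=0)
    return pd.DataFrame(rows).T


def stage_means(
    matrix: cio.ExpressionMatrix, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Gene x stage means (columns ordered by stage_order)."""
    stages = sorted(sample_sheet["stage_order"].unique())
    cols = {}
    for st in stages:
        samples = sample_sheet.loc[sample_sheet["stage_order"] == st, "sample_id"]
        cols[st] = matrix.values[list(samples)].mean(axis=1)
    return pd.DataFrame(cols)


def trajectory_clusters(
    matrix: cio.ExpressionMatrix,
    sample_sheet: pd.DataFrame,
    min_log2_fc: float = 1.0,
    cutoff: float = 0.9,
    inflation: float = 2.2,
) -> tuple[ClusterPartition, pd.DataFrame]:
    """Cluster dynamically expressed genes over ordered stages.

    A gene is dynamic iff max stage mean - min stage mean >= min_log2_fc on
    the log2(TPM+1) scale; dynamic genes are clustered by thresholded
    correlation of their stage-mean profiles followed by MCL.  Returns the
    partition and the stage-mean profile frame of the dynamic genes.
    """
    n_stages = sample_sheet["stage_order"].nunique()
    if n_stages < 3:
        raise ValueError(f"need >= 3 ordered stages, got {n_stages}")
    if matrix.units == "tpm":
        matrix = log_transform(matrix)
    elif matrix.units != "log2tpm":
        raise ValueError("matrix must be tpm or log2tpm")
    means = stage_means(matrix, sample_sheet)
    dynamic = means.max(axis=1) - means.min(axis=1) >= min_log2_fc
    profiles = means[dynamic]
    if len(profiles) == 0:
        return ClusterPartition(clusters={}, unassigned=set()), profiles
    graph = pearson_graph(
        cio.ExpressionMatrix(values=profiles, units="log2tpm"), cutoff=cutoff
    )
    partition = mcl(graph, inflation=inflation)
    return partition, profiles


def partition_to_frame(partition: ClusterPartition) -> pd.DataFrame:
    rows = [
        {"node": str(m), "cluster": cid}
        for cid, members in sorted(partition.clusters.items())
        for m in sorted(members, key=str)
    ]
    rows += [{"node": str(m), "cluster": -1} for m in sorted(partition.unassigned, key=str)]
    return pd.DataFrame(rows, columns=["node", "cluster"])


def frame_to_partition(df: pd.DataFrame) -> ClusterPartition:
    clusters: dict[int, set] = {}
    unassigned = set()
    for row in df.itertuples():
        if row.cluster == -1:
            unassigned.add(row.node)
        else:
            clusters.setdefault(int(row.cluster), set()).add(row.node)
    return ClusterPartition(clusters=clusters, unassigned=unassigned)
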