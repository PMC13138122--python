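"""Jaccard-weighted kNN graph construction, Leiden partitioning, cluster
marker profiles, and a UMAP embedding for figures.

Events (rows of a scaled matrix) become graph nodes. Each node is linked to
its k nearest neighbors under squared Euclidean distance; the undirected,
deduplicated edges are re-weighted by the Jaccard similarity of the two
endpoints' neighbor sets, and the weighted graph is partitioned by Leiden
modularity optimization at a given resolution. The embedding is used only
for visualization, never for gating decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .events import EventMatrix

#: above this event count, approximate (NN-descent) search replaces exact kNN
APPROX_KNN_THRESHOLD = 50_000


@dataclass
class KnnGraph:
    n_nodes: int
    edges: np.ndarray  # (m, 2) int array with i < j per row
    weights: np.ndarray  # (m,) floats in (0, 1]
    k: int
    metric: str = "sqeuclidean"

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValueError("edges must satisfy i < j")
        if ((self.weights <= 0) | (self.weights > 1)).any():
            raise ValueError("Jaccard weights must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.edges[:, 0], "j": self.edges[:, 1], "weight": self.weights}
        )


@dataclass
class ClusterLabels:
    labels: np.ndarray
    resolution: float
    seed: int
    modularity: float
    k: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.size and set(np.unique(labels)) != set(range(labels.max() + 1)):
            raise ValueError("labels must be contiguous integers from 0")
        self.labels = labels

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ClusterProfile:
    """Per-cluster median asinh expression and sizes."""

    medians: pd.DataFrame  # clusters × markers
    sizes: np.ndarray


def knn_search(
    m: EventMatrix, k: int, seed: int = 0, method: str = "auto"
) -> np.ndarray:
    """k nearest neighbors per event under squared Euclidean distance.

    Returns an (n, k) int array of neighbor indices, self excluded. Exact
    search (scikit-learn) is used up to :data:`APPROX_KNN_THRESHOLD` events;
    beyond that a seeded NN-descent approximate index takes over (ranking by
    squared Euclidean distance equals ranking by Euclidean).
    """
    n = m.n_events
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of events ({n})")
    if method == "auto":
        method = "exact" if n <= APPROX_KNN_THRESHOLD else "approximate"
    if method == "exact":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(m.values)
        idx = nn.kneighbors(m.values, return_distance=False)
    elif method == "approximate":
        from pynndescent import NNDescent

        index = NNDescent(
            m.values, n_neighbors=k + 1, metric="euclidean", random_state=seed
        )
        idx = index.neighbor_graph[0]
    else:
        raise ValueError(f"unknown knn method {method!r}")
    # drop self wherever it appears; fall back to dropping the last column
    out = np.empty((n, k), dtype=np.int64)
    rows = np.arange(n)
    self_pos = idx == rows[:, None]
    for i in range(n):
        row = idx[i][~self_pos[i]][:k]
        if len(row) < k:  # self not returned (approximate search)
            row = idx[i][:k]
        out[i] = row
    return out


def jaccard_edge_weights(neighbors: np.ndarray) -> KnnGraph:
    """Build the undirected Jaccard-weighted graph from kNN lists.

    For every kNN pair (i, j) the edge weight is
    ``|N(i) ∩ N(j)| / |N(i) ∪ N(j)|`` over the two k-sized neighbor sets;
    duplicated directions are merged and zero-weight pairs omitted.
    """
    n, k = neighbors.shape
    rows = np.repeat(np.arange(n), k)
    membership = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, neighbors.ravel())), shape=(n, n)
    )
    # candidate pairs: the kNN relation, symmetrized, deduplicated to i < j
    cand = membership.maximum(membership.T).tocoo()
    mask = cand.row < cand.col
    ci, cj = cand.row[mask], cand.col[mask]
    shared = membership @ membership.T  # shared[i, j] = |N(i) ∩ N(j)|
    inter = np.asarray(shared[ci, cj]).ravel()
    union = 2 * k - inter
    weights = inter / union
    keep = weights > 0
    edges = np.column_stack([ci[keep], cj[keep]]).astype(np.int64)
    return KnnGraph(n_nodes=n, edges=edges, weights=weights[keep], k=k)


def leiden_partition(g: KnnGraph, resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """Partition the weighted graph with Leiden modularity optimization.

    Deterministic given the seed; runs a fixed 10-iteration budget and
    records the achieved weighted modularity of the partition.
    """
    import igraph as ig
    import leidenalg

    if g.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    graph = ig.Graph(
        n=g.n_nodes, edges=[tuple(e) for e in g.edges], edge_attrs={"weight": list(g.weights)}
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=10,
    )
    labels = np.asarray(part.membership, dtype=np.int64)
    modularity = graph.modularity(part.membership, weights="weight")
    return ClusterLabels(
        labels=labels, resolution=resolution, seed=int(seed),
        modularity=float(modularity), k=g.k,
    )


def cluster_events(
    m: EventMatrix, k: int, resolution: float, seed: int, method: str = "auto"
) -> ClusterLabels:
    """Convenience composition: kNN → Jaccard weights → Leiden."""
    neighbors = knn_search(m, k=k, seed=seed, method=method)
    graph = jaccard_edge_weights(neighbors)
    return leiden_partition(graph, resolution=resolution, seed=seed)


def cluster_marker_profile(m: EventMatrix, labels: ClusterLabels) -> ClusterProfile:
    """Per-cluster per-marker median on the asinh scale, plus cluster sizes."""
    if len(labels.labels) != m.n_events:
        raise ValueError("labels must align with events")
    df = m.to_dataframe()
    df["_cluster"] = labels.labels
    medians = df.groupby("_cluster").median()
    medians.index.name = "cluster"
    sizes = np.bincount(labels.labels, minlength=labels.n_clusters)
    return ClusterProfile(medians=medians, sizes=sizes)


def umap_embed(m: EventMatrix, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding of the scaled matrix, deterministic given seed.

    Figures only — gating decisions never consume these coordinates.
    """
    if m.n_events < 10:
        raise ValueError("need at least 10 events to embed")
    import umap

    reducer = umap.UMAP(
        n_components=2, random_state=int(seed), n_neighbors=n_neighbors
    )
    return reducer.fit_transform(m.values)
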