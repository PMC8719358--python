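"""Embedding, neighborhood graph, community clustering, dendrograms.

Transgene features must never influence clustering — a cell's projection
label is the thing being read out afterwards, so letting it shape the
transcriptomic neighborhoods would be circular. Every entry point here
asserts transgene features are absent from its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import anndata as ad


@dataclass
class Embedding:
    """PCA coordinates (cells x n_pcs) plus explained-variance fractions."""

    coords: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class ClusterLabels:
    labels: np.ndarray  # contiguous ints from 0
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _assert_no_transgenes(adata: ad.AnnData, mask: np.ndarray | None = None) -> None:
    cls = adata.var["feature_class"].values
    used = cls if mask is None else cls[mask]
    if np.any(used == "transgene"):
        raise ValueError(
            "transgene features must be excluded before embedding/clustering"
        )


def pca_embed(
    scaled: np.ndarray, n_pcs: int = 50, seed: int = 0,
    adata: ad.AnnData | None = None, feature_mask: np.ndarray | None = None,
) -> Embedding:
    """PCA with the arpack solver (deterministic under a fixed seed).

    If ``adata``/``feature_mask`` describe the input columns, the
    no-transgenes rule is enforced rather than trusted.
    """
    if adata is not None:
        _assert_no_transgenes(adata, feature_mask)
    n_cells, n_genes = scaled.shape
    if n_pcs >= min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(cells, genes) = {min(n_cells, n_genes)}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=seed)
    coords = pca.fit_transform(scaled)
    # fix component signs so output is reproducible across BLAS builds
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            coords[:, j] *= -1
    return Embedding(coords=coords, explained_variance_ratio=pca.explained_variance_ratio_)


def knn_graph(embedding: Embedding, k: int = 15) -> sp.csr_matrix:
    """k-nearest-neighbor graph in PC space, symmetrized by edge union.

    Returns an unweighted symmetric adjacency (CSR, no self loops).
    """
    coords = embedding.coords
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, have {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    adj = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    return adj


def community_cluster(
    graph: sp.csr_matrix, resolution: float = 0.6, seed: int = 0
) -> ClusterLabels:
    """Leiden community detection on the kNN graph (RBConfiguration
    modularity with a resolution parameter); deterministic for a fixed seed.

    Labels are relabeled contiguously from 0 in order of first appearance.
    """
    n = graph.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.array(part.membership)
    _, labels = np.unique(raw, return_inverse=True)
    # reorder so label 0 is the first-seen community
    order = {}
    relabeled = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        relabeled[i] = order[lab]
    return ClusterLabels(labels=relabeled, resolution=resolution, seed=seed)


def subset_by_marker(
    adata: ad.AnnData,
    genes: list[str],
    rule: str = "any",
    layer: str | None = None,
) -> np.ndarray:
    """Boolean cell mask: cells expressing the gene set per ``rule``.

    A gene counts as expressed when its value is > 0 (raw counts or the
    given layer). ``rule="any"``: at least one gene expressed; ``"all"``:
    every gene expressed. Unknown genes are an error.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"unknown genes: {missing}")
    X = sp.csr_matrix(adata.X if layer is None else adata.layers[layer])
    cols = [adata.var_names.get_loc(g) for g in genes]
    expressed = np.asarray((X[:, cols] > 0).todense())
    return expressed.any(axis=1) if rule == "any" else expressed.all(axis=1)


def cluster_dendrogram(
    embedding: Embedding, labels: ClusterLabels, n_pcs: int = 50
) -> str:
    """Complete-linkage dendrogram over cluster centroids in PC space.

    Distance between clusters = 1 - Pearson r between their mean PC
    vectors (range [0, 2]). Returned as a Newick string with cluster labels
    as leaf names and merge heights as branch lengths; SciPy's agglomeration
    order (lowest index first on ties) makes the output deterministic.
    """
    labs = labels.labels
    k = labels.n_clusters
    if k < 2:
        raise ValueError("dendrogram needs at least 2 clusters")
    coords = embedding.coords[:, :n_pcs]
    centroids = np.vstack([coords[labs == c].mean(axis=0) for c in range(k)])
    corr = np.corrcoef(centroids)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    condensed = dist[np.triu_indices(k, 1)]
    Z = sch.linkage(condensed, method="complete")
    return _linkage_to_newick(Z, [str(c) for c in range(k)])


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    n = len(leaf_names)

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{leaf_names[node]}:{bl:.6g}"
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

    root = n + len(Z) - 1
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    h = height(root)
    return f"({render(a, h)},{render(b, h)});"
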