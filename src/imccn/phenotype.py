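"""Phenotype clustering: kNN graph with shared-neighbor weights + Leiden.

This mirrors the PhenoGraph recipe — a k-nearest-neighbor graph over
normalized expression (k = 100 by default), symmetrized by union, with
Jaccard shared-neighbor edge weights, partitioned by modularity community
detection. The number of clusters is emergent, never forced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError
from .quantify import norm_column

# below this size exact, stably tie-broken kNN via a full distance matrix is
# cheap; above it fall back to sklearn's tree-based search
_BRUTE_FORCE_LIMIT = 8192


@dataclass
class PhenotypeResult:
    """Per-cell cluster labels plus cluster summaries."""

    labels: np.ndarray
    n_clusters: int
    cluster_means: pd.DataFrame | None = None
    batches: np.ndarray | None = None


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of each row's k nearest other rows (Euclidean).

    Distance ties are broken by index order, so duplicate points yield a
    deterministic graph.
    """
    n = len(X)
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= n:
        warnings.warn(f"k={k} >= n_cells={n}; reduced to {n - 1}")
        k = n - 1
    if n <= _BRUTE_FORCE_LIMIT:
        from scipy.spatial.distance import cdist

        d = cdist(X, X)
        order = np.argsort(d, axis=1, kind="stable")
        out = np.empty((n, k), dtype=int)
        for i in range(n):
            row = order[i]
            out[i] = row[row != i][:k]
        return out
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(return_distance=False)
    return idx[:, :k] if idx.shape[1] == k else idx


def build_knn_graph(features: np.ndarray, k: int = 100,
                    weighting: str = "jaccard") -> ig.Graph:
    """Symmetrized kNN graph over expression space.

    Directed kNN edges are symmetrized by union. With ``weighting='jaccard'``
    each edge (i, j) is weighted by the Jaccard overlap of the two cells'
    neighbor sets (PhenoGraph-style); edges with zero overlap are dropped.
    ``weighting='uniform'`` keeps the plain union with unit weights.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValidationError("features must be a non-empty 2-D matrix")
    idx = _knn_indices(X, k)
    n, k_eff = idx.shape
    rows = np.repeat(np.arange(n), k_eff)
    A = sparse.csr_matrix((np.ones(n * k_eff, dtype=np.int32),
                           (rows, idx.ravel())), shape=(n, n))
    union = ((A + A.T) > 0).tocoo()
    mask = union.row < union.col
    ei, ej = union.row[mask], union.col[mask]
    if weighting == "jaccard":
        inter = (A @ A.T).tocsr()
        overlap = np.asarray(inter[ei, ej]).ravel()
        weights = overlap / (2 * k_eff - overlap)
        keep = weights > 0
        ei, ej, weights = ei[keep], ej[keep], weights[keep]
    elif weighting == "uniform":
        weights = np.ones(len(ei))
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    g = ig.Graph(n=n, edges=list(zip(ei.tolist(), ej.tolist())))
    g.es["weight"] = weights.tolist()
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 1.0,
                  seed: int = 0) -> PhenotypeResult:
    """Leiden modularity communities; deterministic for a fixed seed."""
    if graph.vcount() == 0:
        raise ValidationError("cannot cluster an empty graph")
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership, dtype=int)
    return PhenotypeResult(labels=labels, n_clusters=int(labels.max()) + 1)


def cluster_means(table: pd.DataFrame, labels: np.ndarray,
                  channels: list[str]) -> pd.DataFrame:
    """Cluster x channel matrix of mean normalized expression."""
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValidationError("labels not aligned to table rows")
    cols = [norm_column(c) for c in channels]
    df = table[cols].copy()
    df.columns = channels
    df["__cluster"] = labels
    return df.groupby("__cluster").mean().rename_axis("cluster")


def center_batches(table: pd.DataFrame, batches: np.ndarray,
                   channels: list[str]) -> pd.DataFrame:
    """Per-batch location adjustment of normalized expression.

    For each batch and channel, subtract the batch mean and add the global
    mean. This is a deliberately simple alignment hook (off by default in
    :func:`phenotype_cells`), not a mutual-nearest-neighbor or mixture-model
    batch correction.
    """
    batches = np.asarray(batches)
    if len(batches) != len(table):
        raise ValidationError("batch labels not aligned to table rows")
    out = table.copy()
    for ch in channels:
        col = norm_column(ch)
        vals = out[col].to_numpy(dtype=float)
        global_mean = vals.mean()
        for b in np.unique(batches):
            sel = batches == b
            vals[sel] = vals[sel] - vals[sel].mean() + global_mean
        out[col] = vals
    return out


def phenotype_cells(table: pd.DataFrame, channels: list[str], *, k: int = 100,
                    resolution: float = 1.0, seed: int = 0,
                    batches: np.ndarray | None = None,
                    weighting: str = "jaccard") -> PhenotypeResult:
    """Cluster a cell table into phenotypes.

    Rows are sorted by (image_id, cell_id) before graph construction so the
    result is invariant to the table's row order; labels are returned in the
    original row order.
    """
    work = table.reset_index(drop=True)
    order = np.lexsort((work["cell_id"].to_numpy(),
                        work["image_id"].to_numpy()))
    sorted_tab = work.iloc[order]
    if batches is not None:
        sorted_tab = center_batches(sorted_tab, np.asarray(batches)[order], channels)
    X = sorted_tab[[norm_column(c) for c in channels]].to_numpy(dtype=float)
    res = cluster_graph(build_knn_graph(X, k=k, weighting=weighting),
                        resolution=resolution, seed=seed)
    labels = np.empty(len(work), dtype=int)
    labels[order] = res.labels
    means = cluster_means(work, labels, channels)
    return PhenotypeResult(labels=labels, n_clusters=res.n_clusters,
                           cluster_means=means,
                           batches=None if batches is None else np.asarray(batches))
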