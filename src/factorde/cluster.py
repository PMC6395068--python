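"""K-means clustering of response genes, elbow diagnostics, and
hierarchical ordering of genes and samples for heatmap export.

K-means treats genes as observations and samples as dimensions: Lloyd's
algorithm from `restarts` random initializations keeps the run with minimal
within-cluster sum of squares. The heatmap layout orders samples by a
Pearson-distance (1 - r) dendrogram and genes by cluster index, then
hierarchically (Euclidean) within each cluster.

The k-means primitive operates on the values it is given; the pipeline
centers each gene (mean subtraction) before clustering by default so
clusters capture pattern rather than baseline — see `center_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from factorde.types import ExpressionMatrix, ValidationError


def center_genes(expr: ExpressionMatrix, scale: bool = False) -> ExpressionMatrix:
    """Per-gene mean subtraction (optionally unit-variance scaling)."""
    v = expr.values - expr.values.mean(axis=1, keepdims=True)
    if scale:
        sd = v.std(axis=1, ddof=0, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise ValidationError(
                f"cannot scale zero-variance gene(s): "
                f"{[expr.gene_ids[i] for i in zero[:5]]}"
            )
        v = v / sd
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), v)


@dataclass
class ClusterModel:
    k: int
    gene_ids: list[str]
    assignments: np.ndarray  # cluster index per gene, 0..k-1
    centroids: np.ndarray  # k x n_samples
    wss: float
    restarts_used: int
    seed: int

    def genes_in_cluster(self, c: int) -> list[str]:
        return [g for g, a in zip(self.gene_ids, self.assignments) if a == c]


def kmeans_cluster(
    expr_subset: ExpressionMatrix, k: int, restarts: int = 50, seed: int = 0
) -> ClusterModel:
    """Best-of-`restarts` Lloyd's k-means over genes; deterministic for a
    fixed seed. Empty clusters are repaired by the solver's relocation of
    the farthest points."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > expr_subset.n_genes:
        raise ValueError(
            f"k={k} exceeds the number of genes ({expr_subset.n_genes})"
        )
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(expr_subset.values)
    wss = float(
        np.sum(
            (expr_subset.values - km.cluster_centers_[km.labels_]) ** 2
        )
    )
    return ClusterModel(
        k=k,
        gene_ids=list(expr_subset.gene_ids),
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        wss=wss,
        restarts_used=restarts,
        seed=seed,
    )


def elbow_curve(
    expr_subset: ExpressionMatrix,
    k_range: Sequence[int] = range(2, 21),
    restarts: int = 50,
    seed: int = 0,
) -> dict[int, float]:
    """Best-of-restarts within-cluster sum of squares per candidate k."""
    ks = sorted(set(int(k) for k in k_range))
    if max(ks) > expr_subset.n_genes:
        raise ValueError(
            f"max k ({max(ks)}) exceeds the number of genes "
            f"({expr_subset.n_genes})"
        )
    return {k: kmeans_cluster(expr_subset, k, restarts, seed).wss for k in ks}


def _pearson_distance(matrix: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    sd = matrix.std(axis=1, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance item(s) under pearson metric: "
            f"{[labels[i] for i in zero[:5]]}"
        )
    d = 1.0 - np.corrcoef(matrix)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise
    return squareform(d, checks=False)


def hierarchical_order(
    matrix: np.ndarray,
    labels: Sequence[str],
    metric: str = "euclidean",
    linkage: str = "complete",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative ordering of the rows of `matrix`.

    Returns (leaf-order labels, scipy linkage matrix). Rows are pre-sorted
    by label so ties break deterministically by identifier regardless of
    input order. Pearson distance is 1 - r.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels length must match the number of rows")
    order0 = np.argsort(np.asarray(labels, dtype=object), kind="mergesort")
    labels_sorted = [labels[i] for i in order0]
    m = matrix[order0]
    if metric == "pearson":
        dist = _pearson_distance(m, labels_sorted)
    elif metric == "euclidean":
        dist = pdist(m, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'pearson' or 'euclidean'")
    Z = sch.linkage(dist, method=linkage)
    leaves = sch.leaves_list(Z)
    return [labels_sorted[i] for i in leaves], Z


@dataclass
class HeatmapLayout:
    gene_order: list[str]
    sample_order: list[str]
    cluster_boundaries: list[int]  # row index where each cluster starts
    cluster_of_gene: dict[str, int]


def build_heatmap_layout(
    expr_subset: ExpressionMatrix,
    model: ClusterModel,
    linkage: str = "complete",
) -> HeatmapLayout:
    """Heatmap row/column permutations: samples by Pearson dendrogram,
    genes contiguous by cluster and Euclidean-ordered within cluster."""
    if list(model.gene_ids) != list(expr_subset.gene_ids):
        raise ValidationError("cluster model was fitted on a different gene set")
    sample_order, _ = hierarchical_order(
        expr_subset.values.T, expr_subset.sample_ids, metric="pearson", linkage=linkage
    )
    gene_index = expr_subset.gene_index()
    gene_order: list[str] = []
    boundaries: list[int] = []
    for c in range(model.k):
        members = model.genes_in_cluster(c)
        boundaries.append(len(gene_order))
        if len(members) == 0:
            continue
        if len(members) == 1:
            gene_order.extend(members)
            continue
        sub = expr_subset.values[[gene_index[g] for g in members]]
        ordered, _ = hierarchical_order(sub, members, metric="euclidean", linkage=linkage)
        gene_order.extend(ordered)
    return HeatmapLayout(
        gene_order=gene_order,
        sample_order=sample_order,
        cluster_boundaries=boundaries,
        cluster_of_gene={
            g: int(a) for g, a in zip(model.gene_ids, model.assignments)
        },
    )
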