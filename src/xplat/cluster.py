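"""Clustering and projection of MOA-varying genes.

Presentation conventions for the benchmark comparison: genes standardized to
mean 0 / sd 1, pairwise distance 1 - cosine similarity (uncentered
correlation; centered Pearson available by flag), Ward linkage (the squared
distance update, i.e. the Ward.D2 convention, applied to the given
distances), a 3-component PCA projection of the samples, and a
cluster-vs-MOA agreement report that names chemicals whose replicates land
outside their MOA's majority cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import ExpressionMatrix, StudyDesign

__all__ = [
    "HclusterResult",
    "MoaAgreement",
    "standardize_genes",
    "hcluster",
    "pca_projection",
    "moa_agreement",
]


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (population sd). Zero-variance genes are dropped with
    a warning; an all-constant matrix raises."""
    sds = matrix.values.std(axis=1)  # population denominator
    keep = sds > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance genes dropped")
    vals = matrix.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(matrix.sample_ids), vals, matrix.scale,
                            matrix.platform_label)


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


@dataclass
class HclusterResult:
    item_ids: list[str]
    linkage: np.ndarray
    newick: str
    labels: dict[str, int] | None      # item -> flat cluster label at the requested k


def hcluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    k: int | None = None,
    centered: bool = False,
) -> HclusterResult:
    """Hierarchical clustering of samples or genes.

    Distance is 1 - cosine similarity (uncentered correlation) by default, or
    1 - Pearson r with ``centered=True``; linkage is Ward. ``k`` requests a
    flat cut into k clusters.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    if axis == "samples":
        items, x = list(matrix.sample_ids), matrix.values.T
    else:
        items, x = list(matrix.gene_ids), matrix.values
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    norms = np.linalg.norm(x - x.mean(axis=1, keepdims=True) if centered else x, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm vector for item {items[bad[0]]!r}")
    dist = pdist(x, metric="correlation" if centered else "cosine")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    linkage = hierarchy.linkage(dist, method="ward")
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        labels = dict(zip(items, (int(v) for v in flat)))
    return HclusterResult(items, linkage, _to_newick(linkage, items), labels)


def pca_projection(matrix: ExpressionMatrix, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top principal components of the gene space.

    Samples are observations, genes features. Returns (scores indexed by
    sample, explained-variance fractions). ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = matrix.values.T  # samples x genes
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if n_components > rank:
        warnings.warn(f"n_components {n_components} exceeds rank {rank}; truncated")
        n_components = max(rank, 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    frame = pd.DataFrame(scores, index=matrix.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, pca.explained_variance_ratio_


@dataclass
class MoaAgreement:
    cluster_purity: dict[int, float]       # majority-MOA fraction per cluster
    moa_majority_cluster: dict[str, int]   # MOA -> cluster holding most of its samples
    outlier_chemicals: list[str]           # chemicals mostly outside their MOA's cluster
    overall_purity: float


def moa_agreement(labels: dict[str, int], design: StudyDesign) -> MoaAgreement:
    """Score a flat sample clustering against the MOA labels.

    A chemical is an outlier when the majority of its replicates fall outside
    the cluster that holds the plurality of its MOA's samples.
    """
    treated = design.treated[design.treated["sample_id"].isin(labels)]
    frame = treated.assign(cluster=[labels[s] for s in treated["sample_id"]])

    purity: dict[int, float] = {}
    agree = 0
    for cl, sub in frame.groupby("cluster"):
        counts = sub["moa"].value_counts()
        purity[int(cl)] = float(counts.iloc[0] / len(sub))
        agree += int(counts.iloc[0])
    majority = {str(m): int(sub["cluster"].value_counts().index[0])
                for m, sub in frame.groupby("moa")}
    outliers = []
    for chem, sub in frame.groupby("chemical"):
        home = majority[str(sub["moa"].iloc[0])]
        if (sub["cluster"] == home).sum() <= len(sub) / 2:
            outliers.append(str(chem))
    return MoaAgreement(purity, majority, sorted(outliers), agree / len(frame))
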