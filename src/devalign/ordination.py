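"""PCA ordination, group centroids in a selected component subspace, and
hierarchical sample clustering.

Samples are observations and genes features; each gene is centred before the
decomposition. Centroid distances are plain Euclidean (geometric vector
length) on an explicitly chosen list of components — the discriminative
components are a configuration choice, not an automatic inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

VALID_LINKAGES = ("average", "complete", "single", "ward")
DEFAULT_COMPONENTS = (1, 2, 4)


@dataclass
class OrdinationResult:
    """Scores, loadings and the full variance spectrum of a PCA."""

    scores: pd.DataFrame        # samples x kept components ("PC1", ...)
    loadings: pd.DataFrame      # genes x kept components
    variance_fraction: np.ndarray  # full spectrum, sums to 1
    n_components: int

    def component_columns(self, components) -> list[str]:
        cols = [f"PC{c}" for c in components]
        unknown = [c for c in cols if c not in self.scores.columns]
        if unknown:
            raise ValueError(f"components not computed: {unknown}")
        return cols


def pca(matrix, n_components: int = 5) -> OrdinationResult:
    """Principal components of the centred genes x samples matrix.

    Scores are sample coordinates (U * S of the economy SVD of the centred
    samples x genes array); variance fractions are computed over the full
    spectrum and sum to one.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.values.to_numpy(float).T  # samples x genes
    centred = x - x.mean(axis=0, keepdims=True)
    if not np.any(centred):
        raise ValueError("matrix is constant across samples; no variance to decompose")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # drop numerically null trailing dimensions (rank <= n_samples - 1)
    rank = max(1, int((s > s[0] * 1e-12).sum()))
    keep = min(n_components, rank)
    variance = s**2
    variance_fraction = variance / variance.sum()
    cols = [f"PC{i + 1}" for i in range(keep)]
    scores = pd.DataFrame((u[:, :keep] * s[:keep]), index=matrix.sample_ids, columns=cols)
    loadings = pd.DataFrame(vt[:keep].T, index=matrix.gene_ids, columns=cols)
    return OrdinationResult(
        scores=scores, loadings=loadings,
        variance_fraction=variance_fraction[:rank], n_components=keep,
    )


@dataclass
class CentroidDistanceTable:
    """Group centroids, their pairwise geometric distances, and the
    per-tumour-subgroup ranking of control groups by distance."""

    centroids: pd.DataFrame     # group x components
    distances: pd.DataFrame     # group x group Euclidean
    control_ranking: dict[str, list[str]]  # subgroup -> controls, ascending distance
    components: tuple[int, ...]

    def nearest_control(self, subgroup: str) -> str:
        return self.control_ranking[subgroup][0]


def _assert_metric(d: np.ndarray) -> None:
    # metric axioms, asserted on every run: symmetry, zero diagonal,
    # non-negativity, triangle inequality
    assert np.allclose(d, d.T, atol=1e-9)
    assert np.allclose(np.diag(d), 0.0, atol=1e-9)
    assert (d >= -1e-12).all()
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            assert (d[i, j] <= d[i, :] + d[:, j] + 1e-9).all()


def group_centroids(ordination: OrdinationResult, metadata: pd.DataFrame,
                    components=DEFAULT_COMPONENTS) -> CentroidDistanceTable:
    """Mean score vector per group on the chosen (1-based) components, all
    pairwise Euclidean distances, and ascending control rankings."""
    components = tuple(components)
    cols = ordination.component_columns(components)
    scores = ordination.scores[cols]
    groups = list(dict.fromkeys(metadata["group"]))
    centroids = pd.DataFrame(
        [scores.loc[metadata.index[metadata["group"] == g]].mean(axis=0) for g in groups],
        index=pd.Index(groups, name="group"),
    )
    d = squareform(pdist(centroids.to_numpy(), metric="euclidean"))
    _assert_metric(d)
    distances = pd.DataFrame(d, index=centroids.index, columns=centroids.index)
    controls = [g for g in groups if (metadata.loc[metadata["group"] == g, "kind"] == "control").all()]
    tumors = [g for g in groups if g not in controls]
    ranking = {
        s: sorted(controls, key=lambda c: (distances.loc[s, c], c)) for s in tumors
    }
    return CentroidDistanceTable(
        centroids=centroids, distances=distances, control_ranking=ranking, components=components
    )


@dataclass
class SampleDendrogram:
    """Hierarchical clustering of samples with Newick export."""

    linkage: np.ndarray
    labels: list[str]
    method: str
    metric: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def hierarchical_cluster(matrix, linkage: str = "average",
                         metric: str = "correlation") -> SampleDendrogram:
    """Full sample dendrogram on correlation distance (1 - Pearson) by default."""
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    if linkage not in VALID_LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {VALID_LINKAGES}")
    x = matrix.values.to_numpy(float).T
    dist = pdist(x, metric=metric)
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding in correlation distance
    z = hierarchy.linkage(dist, method=linkage)
    return SampleDendrogram(linkage=z, labels=matrix.sample_ids, method=linkage, metric=metric)
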