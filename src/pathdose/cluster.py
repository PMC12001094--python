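"""Divergent-subgroup detection within a gene set.

Genes are clustered by k-means in the space of their empirical-Bayes
random-effect coefficients (baseline b0 plus dose-effect terms),
standardized per dimension. k is chosen by mean silhouette over
k = 2..k_max; when the best silhouette falls below a floor the set is
declared homogeneous (k = 1). Each cluster can be emitted as a derived
gene set and refit separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datasets import GeneSet

__all__ = ["ClusterAssignment", "cluster_genes", "split_geneset"]

SILHOUETTE_FLOOR = 0.25


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k) with the silhouette trace."""

    labels: dict[str, int]
    k: int
    silhouette_by_k: dict[int, float]
    dominant_cluster: int

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]


def cluster_genes(
    features: pd.DataFrame,
    k_max: int = 6,
    seed: int = 0,
    silhouette_floor: float = SILHOUETTE_FLOOR,
) -> ClusterAssignment:
    """Cluster genes on their random-effect coordinates.

    Parameters
    ----------
    features
        Genes x coefficient dimensions (e.g. the b0/b1 or spline random
        effects of the fitted model).
    k_max
        Largest k tried; capped at n_genes - 1.
    """
    if features.shape[0] < 3:
        raise ValueError("clustering needs >= 3 genes")
    genes = list(features.index)
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():  # all genes identical in this space
        return ClusterAssignment(
            labels={g: 1 for g in genes}, k=1, silhouette_by_k={}, dominant_cluster=1
        )
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    k_max = min(k_max, len(genes) - 1)
    sil: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        labels = km.fit_predict(X)
        if np.unique(labels).size < 2:
            continue
        sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
        best_labels[k] = labels
    if not sil or max(sil.values()) < silhouette_floor:
        return ClusterAssignment(
            labels={g: 1 for g in genes}, k=1, silhouette_by_k=sil, dominant_cluster=1
        )
    k_best = max(sil, key=lambda k: (sil[k], -k))
    raw = best_labels[k_best]
    # Relabel 1..k by decreasing cluster size so labels are deterministic
    # and the dominant cluster is always 1.
    sizes = [(int((raw == c).sum()), c) for c in np.unique(raw)]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    remap = {old: new + 1 for new, (_, old) in enumerate(sizes)}
    labels = {g: remap[c] for g, c in zip(genes, raw)}
    return ClusterAssignment(
        labels=labels, k=k_best, silhouette_by_k=sil, dominant_cluster=1
    )


def split_geneset(geneset: GeneSet, assignment: ClusterAssignment) -> list[GeneSet]:
    """One derived gene set per cluster, partitioning the parent members.

    Derived sets are named ``<parent>__cluster<i>`` and can be refit
    independently downstream.
    """
    missing = set(g for g in assignment.labels) - set(geneset.members)
    if missing:
        raise ValueError(f"assignment covers genes outside the set: {sorted(missing)}")
    out = []
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        if not members:
            continue
        out.append(
            GeneSet(
                name=f"{geneset.name}__cluster{c}",
                members=frozenset(members),
                description=f"cluster {c} of {assignment.k} from {geneset.name}",
                id=geneset.id,
            )
        )
    return out
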