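"""Clustering and classification metrics for integration benchmarks.

Clustering quality is assessed by running Louvain community detection on a
k-nearest-neighbour graph of the latent matrix over a resolution grid
(0.1, 0.2, ..., 2.0 by default) and keeping the resolution with the best
adjusted mutual information against the reference labelling.  Agreement
measures are the chance-adjusted AMI and ARI plus clustering purity (the
cluster-size-weighted fraction of each cluster occupied by its dominant
reference class).  Separation is measured by the silhouette coefficient,
optionally stratified (e.g. batch silhouette within each subpopulation), and
by the out-of-fold AUC of a linear one-vs-rest max-margin classifier.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusteringResult",
    "louvain_scan",
    "adjusted_mutual_information",
    "adjusted_rand_index",
    "clustering_purity",
    "silhouette",
    "population_auc",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))


@dataclass
class ClusteringResult:
    labels: np.ndarray
    resolution: float
    n_clusters: int
    metrics: dict[str, float] = field(default_factory=dict)


def _check_lengths(u, v):
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"label vectors differ in length: {u.shape} vs {v.shape}")
    return u, v


def adjusted_mutual_information(u, v) -> float:
    """AMI = (MI - E[MI]) / (mean(H(U), H(V)) - E[MI]); 1 iff identical
    partitions, ~0 for independent labellings regardless of cluster counts."""
    u, v = _check_lengths(u, v)
    return float(_skm.adjusted_mutual_info_score(u, v, average_method="arithmetic"))


def adjusted_rand_index(u, v) -> float:
    """Pair-counting Rand index corrected for chance."""
    u, v = _check_lengths(u, v)
    return float(_skm.adjusted_rand_score(u, v))


def clustering_purity(reference, clusters) -> float:
    """(sum over clusters of the dominant reference-class count) / n_cells."""
    reference, clusters = _check_lengths(reference, clusters)
    total = 0
    for c in np.unique(clusters):
        members = reference[clusters == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / len(reference)


def _knn_graph(embedding: np.ndarray, k: int):
    import igraph

    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    return g


def louvain_scan(embedding: np.ndarray, reference,
                 resolutions=DEFAULT_RESOLUTIONS, k: int = 15,
                 seed: int = 0) -> ClusteringResult:
    """Louvain over a resolution grid; returns the best-AMI clustering.

    Ties favour the lowest resolution.  The community detection runs on a
    k-NN graph (Euclidean, k=15 by default) with a seeded RNG, so results
    are reproducible.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    reference = np.asarray(reference)
    if embedding.shape[0] != len(reference):
        raise ValueError("reference labels do not match the embedding's cell count")
    if embedding.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    if len(resolutions) == 0:
        raise ValueError("resolutions must be non-empty")
    g = _knn_graph(embedding, k)
    best: ClusteringResult | None = None
    for res in resolutions:
        _pyrandom.seed(seed)  # igraph delegates to Python's random module
        membership = np.array(g.community_multilevel(resolution=float(res)).membership)
        ami = adjusted_mutual_information(reference, membership)
        if best is None or ami > best.metrics["ami"] + 1e-12:
            best = ClusteringResult(
                labels=membership,
                resolution=float(res),
                n_clusters=int(membership.max()) + 1,
                metrics={
                    "ami": ami,
                    "ari": adjusted_rand_index(reference, membership),
                    "purity": clustering_purity(reference, membership),
                },
            )
    return best


def silhouette(embedding: np.ndarray, labels, within=None):
    """Mean silhouette coefficient (Euclidean) and per-cell scores.

    Without `within`: returns ``(mean, per_cell_scores)``.  With `within`, a
    stratifying labelling (e.g. subpopulations when scoring batch mixing),
    scores are computed independently inside each stratum and a dict
    ``stratum -> mean`` is returned together with the grand mean over scored
    strata; strata with fewer than 2 label levels or only singleton labels
    are skipped with a warning.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    if within is None:
        if len(np.unique(labels)) < 2:
            raise ValueError("silhouette needs at least 2 distinct labels")
        scores = _skm.silhouette_samples(embedding, labels)
        return float(scores.mean()), scores
    within = np.asarray(within)
    per_stratum: dict[str, float] = {}
    for s in np.unique(within):
        sel = within == s
        sub_labels = labels[sel]
        uniq, counts = np.unique(sub_labels, return_counts=True)
        if len(uniq) < 2 or np.all(counts < 2):
            warnings.warn(f"stratum {s!r} skipped: not enough label variation")
            continue
        per_stratum[str(s)] = float(_skm.silhouette_score(embedding[sel], sub_labels))
    if not per_stratum:
        raise ValueError("no stratum had enough label variation to score")
    grand = float(np.mean(list(per_stratum.values())))
    return grand, per_stratum


def population_auc(embedding: np.ndarray, labels, folds: int = 10,
                   seed: int = 0) -> tuple[dict[str, float], float]:
    """One-vs-rest linear SVM AUC with stratified cross-validation.

    Returns (per-class AUC dict, unweighted macro mean).  Out-of-fold
    decision scores are pooled before computing each class's ROC AUC.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import LinearSVC

    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < folds:
            raise ValueError(f"class {cls!r} has {cnt} members, fewer than {folds} folds")
    scores = np.zeros((len(labels), len(classes)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(embedding, labels):
        clf = LinearSVC()
        clf.fit(embedding[train_idx], labels[train_idx])
        dec = clf.decision_function(embedding[test_idx])
        if dec.ndim == 1:  # binary: score for classes[1]
            dec = np.column_stack([-dec, dec])
        scores[test_idx] = dec
    per_class = {}
    for i, cls in enumerate(classes):
        per_class[str(cls)] = float(_skm.roc_auc_score((labels == cls).astype(int), scores[:, i]))
    return per_class, float(np.mean(list(per_class.values())))
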