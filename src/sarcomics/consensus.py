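"""Resampling-based consensus clustering with centroid assignment.

The grouping procedure shared by the handcrafted-radiomics, deep-
radiomics and transcriptomics branches: center-scale the feature
matrix, repeatedly subsample 60% of subjects (i.e. leave out 40%),
cluster each subsample by average-linkage hierarchical clustering on
the Pearson distance, and accumulate co-clustering proportions into a
consensus matrix. The final partition cuts the tree built on
1 - consensus; the number of clusters is chosen by maximizing the mean
silhouette width of the consensus partition under the full-data Pearson
distance unless fixed. Clusters are renamed A, B, C... by decreasing size, and held-out
observations are assigned to the cluster whose centroid is nearest in
Pearson distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusModel",
    "center_scale",
    "pearson_distance",
    "hierarchical_cluster",
    "consensus_cluster",
    "label_clusters_by_size",
    "assign_by_centroid",
]


@dataclass
class ConsensusModel:
    consensus: np.ndarray
    k: int
    labels: pd.Series              # cluster name per subject ("A", "B", ...)
    centroids: pd.DataFrame        # cluster x feature, on scaled features
    scaling: pd.DataFrame          # per-feature mean / sd used for scaling
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "settings": self.settings,
            "scaling": self.scaling.to_dict(orient="index"),
            "centroids": self.centroids.to_dict(orient="index"),
            "labels": self.labels.to_dict(),
        }, indent=1)


def center_scale(matrix: pd.DataFrame, ddof: int = 0):
    """Column-standardize to mean 0, sd 1 (population sd by default).

    Zero-variance columns carry no clustering information and are
    dropped with a warning. Returns (scaled matrix, scaling frame).
    """
    X = matrix.astype(float)
    if len(X) < 2:
        raise ValueError("need at least 2 subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are degenerate (zero variance)")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    scaled = (X.loc[:, keep] - mean[keep]) / sd[keep]
    scaling = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return scaled, scaling


def pearson_distance(x, y) -> float:
    """1 - Pearson correlation, in [0, 2]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        raise ValueError("Pearson distance undefined for constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def _pearson_distance_matrix(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("Pearson distance undefined for constant rows")
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hierarchical_cluster(dist: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    """Cut an agglomerative tree on a distance matrix into k groups.

    Returns integer labels 1..k. SciPy breaks merge ties by the lowest
    pair index, which this package documents as its tie rule.
    """
    dist = np.asarray(dist, float)
    n = dist.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of observations")
    if n == 1:
        return np.array([1])
    Z = linkage(squareform(dist, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(matrix: pd.DataFrame,
                      k_range=(2, 3, 4, 5),
                      B: int = 10000,
                      holdout: float = 0.40,
                      seed: int = 0,
                      k_fixed: int | None = None,
                      linkage_method: str = "average",
                      min_cluster_frac: float = 0.05) -> ConsensusModel:
    """Consensus clustering by repeated 60% subsampling.

    For each of ``B`` resamples a random ``1 - holdout`` fraction of
    subjects is clustered (average linkage, Pearson distance) at each
    candidate k; consensus(i, j) = co-clustered count / co-sampled
    count. Pairs never co-sampled (possible at tiny B) are imputed at
    0.5 with a warning. k is chosen over ``k_range`` by maximal mean
    silhouette width (ties to the smaller k, clusters below
    ``min_cluster_frac`` of the cohort disqualify a candidate) unless
    ``k_fixed`` is given. Deterministic per seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    scaled, scaling = center_scale(matrix)
    X = scaled.to_numpy()
    n = len(scaled)
    if n < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    ks = [k_fixed] if k_fixed is not None else sorted(k_range)
    m_sub = max(2, int(round(n * (1.0 - holdout))))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(B):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        dist = _pearson_distance_matrix(X[idx])
        co_sampled[np.ix_(idx, idx)] += 1
        for k in ks:
            lab = hierarchical_cluster(dist, min(k, m_sub), method=linkage_method)
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} pair(s) never co-sampled; "
                      "consensus imputed at 0.5")
    consensus_by_k = {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_clustered[k] /
                            np.maximum(co_sampled, 1), 0.5)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus_by_k[k] = cons

    if k_fixed is not None:
        k_best = k_fixed
    else:
        # Candidate k is valid if its consensus partition has no
        # spuriously small cluster (outlier singletons make any k look
        # stable). Among valid candidates, maximize the mean silhouette
        # width of the partition under the full-data Pearson distance:
        # merging distinct groups inflates within-cluster distances and
        # splitting a tight group deflates between-cluster distances,
        # so both are penalized. Ties go to the smaller k.
        from sklearn.metrics import silhouette_score

        full_dist = _pearson_distance_matrix(X)
        min_size = max(2, int(np.ceil(min_cluster_frac * n)))
        scores = {}
        for k in ks:
            lab = hierarchical_cluster(1.0 - consensus_by_k[k], k,
                                       method=linkage_method)
            if len(np.unique(lab)) < 2 or np.bincount(lab)[1:].min() < min_size:
                continue
            scores[k] = float(silhouette_score(full_dist, lab,
                                               metric="precomputed"))
        if not scores:
            k_best = min(ks)
        else:
            k_best = min(k for k in scores
                         if scores[k] >= max(scores.values()) - 1e-12)

    consensus = consensus_by_k[k_best]
    final = hierarchical_cluster(1.0 - consensus, k_best, method=linkage_method)
    labels = pd.Series(final, index=scaled.index, name="cluster")
    centroids = scaled.groupby(labels).mean()
    model = ConsensusModel(
        consensus=consensus, k=int(k_best), labels=labels, centroids=centroids,
        scaling=scaling,
        settings={"B": B, "holdout": holdout, "seed": seed,
                  "linkage": linkage_method, "k_range": list(ks)},
    )
    return label_clusters_by_size(model)


def label_clusters_by_size(model: ConsensusModel) -> ConsensusModel:
    """Rename clusters A, B, C... by decreasing size (ties keep the
    original label order)."""
    sizes = model.labels.value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    names = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    model.labels = model.labels.map(names)
    model.centroids = model.centroids.rename(index=names).sort_index()
    return model


def assign_by_centroid(model: ConsensusModel, new_obs) -> str:
    """Label a new observation by the nearest centroid in Pearson distance.

    ``new_obs`` is on the raw feature scale and is standardized with the
    model's stored scaling parameters. Ties go to the lexicographically
    first cluster name.
    """
    if isinstance(new_obs, pd.Series):
        missing = [f for f in model.scaling.index if f not in new_obs.index]
        if missing:
            raise ValueError(f"missing features: {missing[:5]}")
        x = new_obs[model.scaling.index].to_numpy(float)
    else:
        x = np.asarray(new_obs, float)
        if x.shape[0] != len(model.scaling):
            raise ValueError("feature count mismatch")
    x = (x - model.scaling["mean"].to_numpy()) / model.scaling["sd"].to_numpy()
    best, best_d = None, np.inf
    for name in sorted(model.centroids.index):
        d = pearson_distance(x, model.centroids.loc[name].to_numpy())
        if d < best_d - 1e-15:
            best, best_d = name, d
    return best
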