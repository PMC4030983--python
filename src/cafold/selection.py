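"""Clustering-based model selection over mutual-GDT similarity.

Reconstructed models are clustered with DBSCAN where two models are
neighbours iff their mutual GDT is at least ε (equivalently, distance
1 − GDT ≤ 1 − ε).  Parameters are tuned by a deterministic grid search for a
configuration with five or more clusters whose largest cluster holds at
least 20 models (scaled proportionally for runs smaller than 1,000 models);
from each of the largest clusters the member with the highest sum of
within-cluster GDT scores is selected as a centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .metrics import MutualGdtMatrix

logger = logging.getLogger(__name__)

NOISE = -1
EPS_GRID = tuple(np.round(np.arange(0.9, 0.29, -0.05), 2))
MIN_PTS_GRID = (3, 5, 10, 20)
LARGEST_CLUSTER_REF = 20  # against 1,000-model runs
N_SELECT = 5


@dataclass(frozen=True)
class ClusterResult:
    """Labels (NOISE = −1), the (eps, min_pts) used, selected centroid model
    indices (distinct clusters, never noise) and whether the tuning target
    was met."""

    labels: np.ndarray
    eps: float
    min_pts: int
    selected: tuple = ()
    criterion_met: bool = True

    def cluster_sizes(self) -> dict:
        ids, counts = np.unique(self.labels[self.labels != NOISE], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {NOISE})


def cluster_models(M: MutualGdtMatrix, eps: float, min_pts: int) -> ClusterResult:
    """DBSCAN over mutual-GDT similarity: neighbourhood of i is
    {j : M(i, j) ≥ eps}; standard core/border/noise semantics."""
    if not 0.0 < eps <= 1.0:
        raise ValueError("eps must lie in (0, 1]")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    D = 1.0 - M.M
    np.fill_diagonal(D, 0.0)
    labels = DBSCAN(eps=1.0 - eps + 1e-12, min_samples=min_pts,
                    metric="precomputed").fit_predict(D)
    return ClusterResult(labels=labels, eps=eps, min_pts=min_pts)


def required_largest(n: int) -> int:
    """Largest-cluster requirement, scaled below 1,000-model runs."""
    if n >= 1000:
        return LARGEST_CLUSTER_REF
    return max(3, round(0.02 * n))


def tune_clustering(M: MutualGdtMatrix, n_clusters_min: int = 5) -> ClusterResult:
    """Deterministic grid search (eps descending, then min_pts ascending)
    for ≥ ``n_clusters_min`` clusters with a large-enough largest cluster;
    falls back to the configuration maximizing (cluster count, largest size)
    lexicographically, flagged via ``criterion_met=False``."""
    n = M.n
    need_largest = required_largest(n)
    best = None
    best_key = (-1, -1)
    for eps in EPS_GRID:
        for min_pts in MIN_PTS_GRID:
            res = cluster_models(M, float(eps), int(min_pts))
            sizes = res.cluster_sizes()
            largest = max(sizes.values(), default=0)
            if res.n_clusters >= n_clusters_min and largest >= need_largest:
                return res
            key = (res.n_clusters, largest)
            if key > best_key:
                best_key, best = key, res
    logger.warning("clustering criterion not met; best-effort: %d clusters, largest %d",
                   best_key[0], best_key[1])
    return ClusterResult(best.labels, best.eps, best.min_pts, criterion_met=False)


def select_centroids(result: ClusterResult, M: MutualGdtMatrix,
                     n_select: int = N_SELECT) -> list:
    """Centroids of the ``n_select`` largest clusters.

    Clusters are ordered by size descending (ties: the cluster containing
    the lower smallest model index first); within a cluster the member with
    the highest sum of GDT scores against its cluster mates wins (ties:
    lower index).  Fewer centroids are returned when clusters run out; noise
    points are never selected.
    """
    labels = result.labels
    clusters = []
    for cid in set(labels.tolist()) - {NOISE}:
        members = np.flatnonzero(labels == cid)
        clusters.append((len(members), members.min(), members))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    selected = []
    for _, _, members in clusters[:n_select]:
        sub = M.M[np.ix_(members, members)]
        sums = sub.sum(axis=1) - 1.0  # exclude self (diagonal is 1)
        best = members[int(np.argmax(sums))]  # argmax -> lowest index on ties
        selected.append(int(best))
    return selected


def select_models(M: MutualGdtMatrix, n_select: int = N_SELECT) -> ClusterResult:
    """Tune, cluster and select in one call."""
    result = tune_clustering(M)
    selected = select_centroids(result, M, n_select)
    return ClusterResult(result.labels, result.eps, result.min_pts,
                         tuple(selected), result.criterion_met)
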