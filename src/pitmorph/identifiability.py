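"""Unsupervised landmark identifiability on superimposed coordinates.

If a landmark is well defined, the pooled cloud of every analyst's
placements of it (after full GPA) should form a dense, isolated cluster.
Two density-based algorithms probe this: DBSCAN with MinPts = 30 (one
cluster should contain at least all placements of one landmark on one
sample's worth of pits) and an objectively selected epsilon from the
k-distance elbow, and flat-kernel mean shift with a 0.05-quantile
bandwidth.  Clusters are scored against the true landmark labels:
each cluster adopts its majority landmark; disagreeing points count as
misclassified; unassigned points count as noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .error_analysis import DEFAULT_SUBSETS
from .superimposition import full_gpa
from .types import ObserverDataset


class NoKneeError(ValueError):
    """The k-distance curve has no detectable elbow; supply epsilon manually."""


@dataclass(frozen=True)
class DBSCANParams:
    epsilon: float
    min_points: int = 30

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


def k_distance_curve(points: np.ndarray, k: int) -> np.ndarray:
    """Sorted distances from every point to its k-th nearest neighbour
    (excluding the point itself)."""
    points = np.asarray(points, float)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of points {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return np.sort(dist[:, k])


def elbow_epsilon(curve: np.ndarray, tol: float = 1e-6) -> float:
    """Knee of a sorted k-distance curve by normalised-difference detection.

    Both axes are normalised to [0, 1]; the knee is the point of maximum
    absolute deviation of the curve from the diagonal (the kneedle
    criterion, handling both convex and concave orientations).  A curve
    that is a straight line has no knee and raises :class:`NoKneeError`.
    """
    curve = np.asarray(curve, float)
    if curve.size < 3:
        raise ValueError("curve must have at least 3 points")
    y_range = curve.max() - curve.min()
    if y_range == 0:
        raise NoKneeError("constant curve has no knee")
    x = np.linspace(0.0, 1.0, curve.size)
    y = (curve - curve.min()) / y_range
    dev = y - x
    if np.max(np.abs(dev)) < tol:
        raise NoKneeError("curve is a straight line; no knee detected")
    idx = int(np.argmax(np.abs(dev)))
    return float(curve[idx])


def dbscan_cluster(points: np.ndarray, params: DBSCANParams) -> np.ndarray:
    """Standard DBSCAN labels: cluster ids 0.. and -1 for noise.

    A core point has >= MinPts neighbours within epsilon (the point itself
    included); clusters are maximal density-connected sets; border points
    claimable by several clusters go to the first by point order.
    """
    points = np.asarray(points, float)
    return DBSCAN(eps=params.epsilon, min_samples=params.min_points).fit_predict(points)


def estimate_bandwidth(points: np.ndarray, quantile: float = 0.05) -> float:
    """Mean over points of the distance to their ceil(quantile * n)-th
    nearest neighbour (excluding self)."""
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    points = np.asarray(points, float)
    n = points.shape[0]
    k = min(int(np.ceil(quantile * n)), n - 1)
    k = max(k, 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return float(dist[:, k].mean())


def mean_shift_cluster(
    points: np.ndarray,
    bandwidth: float,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-kernel mean shift seeded from every point.

    Each seed iterates to the mean of the points within ``bandwidth`` until
    it moves less than ``tol``; converged seeds closer than the bandwidth
    are merged into one mode (densest mode wins).  Returns (labels, modes);
    every point is assigned to the mode its own seed converged to, so a
    point with an empty neighbourhood forms its own singleton mode.
    """
    points = np.asarray(points, float)
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    n = points.shape[0]
    seeds = points.copy()
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        # pairwise distances of active seeds to all points, chunked
        for start in range(0, idx.size, 512):
            chunk = idx[start : start + 512]
            d2 = np.sum((seeds[chunk, None, :] - points[None, :, :]) ** 2, axis=-1)
            within = d2 <= bandwidth**2
            counts = within.sum(axis=1)
            new = np.where(
                counts[:, None] > 0,
                (within[:, :, None] * points[None, :, :]).sum(axis=1)
                / np.maximum(counts, 1)[:, None],
                seeds[chunk],
            )
            moved = np.linalg.norm(new - seeds[chunk], axis=1) > tol
            seeds[chunk] = new
            active[chunk] = moved

    # merge converged seeds into modes, densest first
    counts = np.zeros(n, dtype=int)
    for start in range(0, n, 512):
        d2 = np.sum((seeds[start : start + 512, None, :] - points[None, :, :]) ** 2, axis=-1)
        counts[start : start + 512] = (d2 <= bandwidth**2).sum(axis=1)
    order = np.argsort(-counts, kind="stable")
    modes: list[np.ndarray] = []
    labels = np.full(n, -1, dtype=int)
    for i in order:
        if labels[i] >= 0:
            continue
        assigned = False
        for m, mode in enumerate(modes):
            if np.linalg.norm(seeds[i] - mode) < bandwidth:
                labels[i] = m
                assigned = True
                break
        if not assigned:
            modes.append(seeds[i])
            labels[i] = len(modes) - 1
    return labels, np.asarray(modes)


@dataclass
class ClusterReport:
    """Cluster evaluation against true landmark identities."""

    n_clusters: int
    n_noise: int
    n_correct: int
    n_misclassified: int
    cluster_to_landmark: dict[int, str]
    points_of_interest: dict[int, np.ndarray]

    @property
    def total(self) -> int:
        return self.n_correct + self.n_misclassified + self.n_noise

    def to_row(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_noise": self.n_noise,
            "n_correct": self.n_correct,
            "n_misclassified": self.n_misclassified,
        }


def evaluate_landmark_clusters(
    labels: np.ndarray,
    true_landmark_ids: Sequence[str],
    points: np.ndarray | None = None,
) -> ClusterReport:
    """Map each cluster to its majority true landmark and count agreement.

    Points with label -1 are noise.  Within a cluster, points whose true
    landmark differs from the cluster majority count as misclassified.
    """
    labels = np.asarray(labels)
    true_ids = np.asarray(true_landmark_ids)
    if labels.shape[0] != true_ids.shape[0]:
        raise ValueError("labels and true ids must have equal length")
    mapping: dict[int, str] = {}
    centroids: dict[int, np.ndarray] = {}
    n_correct = n_mis = 0
    for cl in np.unique(labels):
        if cl == -1:
            continue
        members = labels == cl
        ids, counts = np.unique(true_ids[members], return_counts=True)
        majority = ids[np.argmax(counts)]
        mapping[int(cl)] = str(majority)
        n_correct += int(counts.max())
        n_mis += int(members.sum() - counts.max())
        if points is not None:
            centroids[int(cl)] = np.asarray(points)[members].mean(axis=0)
    return ClusterReport(
        n_clusters=len(mapping),
        n_noise=int(np.sum(labels == -1)),
        n_correct=n_correct,
        n_misclassified=n_mis,
        cluster_to_landmark=mapping,
        points_of_interest=centroids,
    )


def landmark_identifiability(
    dataset: ObserverDataset,
    subsets: Mapping[str, Sequence[str]] | None = None,
    method: str = "dbscan",
    min_points: int = 30,
    quantile: float = 0.05,
) -> dict[str, ClusterReport]:
    """Cluster the pooled fully superimposed landmark points per subset.

    Each subset scheme is superimposed by full GPA on its own, all aligned
    points are pooled (one point per configuration per landmark), clustered
    with the requested algorithm and scored against the true labels.  For
    mean shift, singleton clusters are reported as noise.
    """
    if subsets is None:
        present = set(dataset.scheme)
        subsets = {k: v for k, v in DEFAULT_SUBSETS.items() if set(v) <= present}
    out: dict[str, ClusterReport] = {}
    for name, labs in subsets.items():
        sub = dataset.subset_scheme(labs)
        ensemble = full_gpa(sub.configurations)
        coords = ensemble.coords_array()  # (n_cfg, k, 3)
        points = coords.reshape(-1, 3)
        true_ids = np.tile(np.asarray(labs), coords.shape[0])
        if method == "dbscan":
            curve = k_distance_curve(points, min_points)
            eps = elbow_epsilon(curve)
            labels = dbscan_cluster(points, DBSCANParams(epsilon=eps, min_points=min_points))
        elif method == "meanshift":
            bw = estimate_bandwidth(points, quantile=quantile)
            labels, _ = mean_shift_cluster(points, bw)
            ids, counts = np.unique(labels, return_counts=True)
            singletons = set(ids[counts == 1])
            labels = np.array([-1 if l in singletons else l for l in labels])
        else:
            raise ValueError(f"unknown method {method!r}")
        out[name] = evaluate_landmark_clusters(labels, true_ids, points)
    return out
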