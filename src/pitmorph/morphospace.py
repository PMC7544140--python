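"""Morphospace statistics: PCA, MANOVA, CVA and UPGMA trees.

PCA eigendecomposes the covariance of the mean-centred flattened landmark
coordinates.  MANOVA follows the statistic-selection rule used throughout
the analyses: Hotelling-Lawley trace when the pooled first-two PC scores
pass Shapiro-Wilk normality at alpha = 0.05, Wilks' lambda otherwise; p
comes from the analytic F approximation.  CVA reports Mahalanobis and
(score-space) Procrustes distances between two groups with add-one
permutation p-values.  UPGMA builds ultrametric average-linkage trees from
Procrustes distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.multivariate.manova import MANOVA as _SM_MANOVA

from .robust import normality_test
from .superimposition import AlignedEnsemble, full_gpa, partial_gpa
from .types import DistanceMatrix, ObserverDataset

logger = logging.getLogger(__name__)

_EIGEN_TOL = 1e-12  # relative eigenvalue floor defining the dimensionality


@dataclass
class PCAResult:
    scores: np.ndarray               # (n, n_components)
    proportion_variance: np.ndarray  # non-increasing, sums to 1 (or 0 if degenerate)
    dimensionality: int              # count of non-degenerate components
    loadings: np.ndarray             # (p, n_components), columns unit norm
    eigenvalues: np.ndarray
    mean_vector: np.ndarray
    degenerate: bool = False

    def cumulative_percent(self, k: int) -> float:
        """Cumulative % variance of the first k components."""
        return float(100.0 * self.proportion_variance[:k].sum())


def pca(data: AlignedEnsemble | np.ndarray) -> PCAResult:
    """PCA of superimposed coordinates (or any (n, p) matrix).

    Component signs follow the convention that each component's
    largest-magnitude loading is positive.
    """
    if isinstance(data, AlignedEnsemble):
        x = data.coords_array().reshape(len(data.configurations), -1)
    else:
        x = np.asarray(data, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 individuals")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    # degenerate: no variance beyond floating-point noise of the data scale
    noise_floor = 1e-20 * max(1.0, float(np.mean(x**2)))
    if total <= noise_floor:
        k = len(eig)
        return PCAResult(
            scores=np.zeros((n, k)),
            proportion_variance=np.zeros(k),
            dimensionality=0,
            loadings=vt.T,
            eigenvalues=eig,
            mean_vector=mean,
            degenerate=True,
        )
    # sign convention: largest-|loading| positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = xc @ vt.T
    dimensionality = int(np.sum(eig > _EIGEN_TOL * eig[0]))
    return PCAResult(
        scores=scores,
        proportion_variance=eig / total,
        dimensionality=dimensionality,
        loadings=vt.T,
        eigenvalues=eig,
        mean_vector=mean,
    )


def truncate_scores(result: PCAResult, labels: Sequence, var_target: float = 0.95) -> np.ndarray:
    """Score columns for MANOVA/CVA: enough components for ``var_target`` of
    the variance, capped at n - g - 1 to keep within-group covariances
    non-singular."""
    labels = np.asarray(labels)
    n, g = len(labels), len(np.unique(labels))
    cum = np.cumsum(result.proportion_variance)
    m95 = int(np.searchsorted(cum, var_target) + 1)
    m = max(1, min(m95, n - g - 1, result.dimensionality))
    return result.scores[:, :m]


@dataclass(frozen=True)
class ManovaResult:
    statistic_name: str  # "Hotelling-Lawley" or "Wilks"
    statistic: float
    p: float
    scores_normal: bool  # outcome of the selection rule's normality test


def manova(scores: np.ndarray, group_labels: Sequence) -> ManovaResult:
    """MANOVA of score columns across groups with the statistic-selection
    rule (Hotelling-Lawley for normal pooled PC1-2 scores, Wilks otherwise)."""
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray([str(g) for g in group_labels])
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise ValueError("MANOVA needs >= 2 groups with >= 2 members each")
    n, p = scores.shape
    if p >= n - len(groups):
        raise ValueError(
            "too many score columns for the sample size; truncate the scores "
            "(see truncate_scores)"
        )
    pooled = scores[:, : min(2, p)].ravel()
    _, p_norm = normality_test(pooled)
    scores_normal = bool(p_norm >= 0.05)

    df = pd.DataFrame(scores, columns=[f"s{i}" for i in range(p)])
    df["group"] = labels
    lhs = " + ".join(df.columns[:-1])
    try:
        fit = _SM_MANOVA.from_formula(f"{lhs} ~ group", data=df)
        table = fit.mv_test().results["group"]["stat"]
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group covariance; truncate the score columns"
        ) from exc
    row = "Hotelling-Lawley trace" if scores_normal else "Wilks' lambda"
    stat = float(table.loc[row, "Value"])
    pval = float(table.loc[row, "Pr > F"])
    return ManovaResult(
        statistic_name="Hotelling-Lawley" if scores_normal else "Wilks",
        statistic=stat,
        p=pval,
        scores_normal=scores_normal,
    )


@dataclass
class CVAResult:
    canonical_scores: np.ndarray
    mahalanobis_D: float
    procrustes_D: float
    p_mahalanobis: float
    p_procrustes: float
    n_permutations: int


def _two_group_distances(scores: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    g1, g2 = scores[mask], scores[~mask]
    diff = g1.mean(axis=0) - g2.mean(axis=0)
    n1, n2 = len(g1), len(g2)
    pooled = ((n1 - 1) * np.cov(g1, rowvar=False) + (n2 - 1) * np.cov(g2, rowvar=False)) / (
        n1 + n2 - 2
    )
    pooled = np.atleast_2d(pooled)
    dm = float(np.sqrt(diff @ np.linalg.pinv(pooled) @ diff))
    dp = float(np.linalg.norm(diff))
    return dm, dp


def cva(
    scores: np.ndarray,
    group_labels: Sequence,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> CVAResult:
    """Two-group canonical variates analysis with permutation tests.

    The canonical axis maximises between- over within-group variance
    (pooled-covariance whitened mean difference).  Mahalanobis D uses the
    pooled within-group covariance; Procrustes D is the Euclidean distance
    between group mean score vectors (scores embed the Procrustes-aligned
    shapes isometrically).  Permutation p-values use the add-one estimator
    p = (1 + #{D_perm >= D_obs}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray([str(g) for g in group_labels])
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("CVA as implemented requires exactly two groups")
    rng = np.random.default_rng(rng)
    mask = labels == groups[0]

    dm_obs, dp_obs = _two_group_distances(scores, mask)

    g1, g2 = scores[mask], scores[~mask]
    n1, n2 = len(g1), len(g2)
    pooled = ((n1 - 1) * np.cov(g1, rowvar=False) + (n2 - 1) * np.cov(g2, rowvar=False)) / (
        n1 + n2 - 2
    )
    axis = np.linalg.pinv(np.atleast_2d(pooled)) @ (g1.mean(axis=0) - g2.mean(axis=0))
    norm = np.linalg.norm(axis)
    if norm > 0:
        axis = axis / norm
    canonical = scores @ axis

    count_m = count_p = 0
    for _ in range(n_permutations):
        perm = rng.permutation(mask)
        dm, dp = _two_group_distances(scores, perm)
        count_m += dm >= dm_obs
        count_p += dp >= dp_obs
    return CVAResult(
        canonical_scores=canonical,
        mahalanobis_D=dm_obs,
        procrustes_D=dp_obs,
        p_mahalanobis=(1 + count_m) / (1 + n_permutations),
        p_procrustes=(1 + count_p) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class UPGMANode:
    height: float
    label: str | None = None
    children: tuple["UPGMANode", "UPGMANode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class UPGMATree:
    """Rooted ultrametric average-linkage tree; merge heights are half the
    average inter-cluster distance, so all leaves are equidistant from the
    root at the final merge height."""

    root: UPGMANode

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        def render(node: UPGMANode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{branch:.9g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.9g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic_depth(self) -> dict[frozenset, float]:
        """Merge height (ultrametric depth) for every leaf pair."""
        out: dict[frozenset, float] = {}

        def walk(node: UPGMANode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    out[frozenset((a, b))] = node.height
            return left + right

        walk(self.root)
        return out


def upgma(dist: DistanceMatrix) -> UPGMATree:
    """Average-linkage agglomeration with ties broken by the lowest leaf
    index; merge heights are half the average inter-cluster distance."""
    n = len(dist)
    if n < 2:
        raise ValueError("UPGMA needs at least two items")
    d = dist.values.astype(float).copy()
    # cluster bookkeeping: node, member count, smallest leaf index
    nodes = [UPGMANode(height=0.0, label=lab) for lab in dist.labels]
    sizes = [1] * n
    min_leaf = list(range(n))
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                lo, hi = sorted((min_leaf[a], min_leaf[b]))
                key = (d[a, b], lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        new_height = d[a, b] / 2.0
        merged = UPGMANode(height=new_height, children=(nodes[a], nodes[b]))
        # average-linkage update
        new_row = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (a, b):
                continue
            new_row[c] = (sizes[a] * d[a, c] + sizes[b] * d[b, c]) / (sizes[a] + sizes[b])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(merged)
        sizes.append(sizes[a] + sizes[b])
        min_leaf.append(min(min_leaf[a], min_leaf[b]))
        active = [c for c in active if c not in (a, b)] + [len(nodes) - 1]
    return UPGMATree(root=nodes[active[0]])


# ---------------------------------------------------------------------------
# model comparison

def model_comparison_report(
    datasets: Mapping[str, ObserverDataset | None],
    spaces: Sequence[str] = ("shape", "form"),
    group_field: str = "carnivore_label",
    n_permutations: int = 999,
    seed: int | None = 0,
    pca_cumulative: tuple[int, int] = (2, 10),
) -> pd.DataFrame:
    """One row per landmark scheme x space: PCA dimensionality and
    cumulative variance, MANOVA p and CVA distances/p for the group
    contrast (wolf vs dog by default)."""
    rows = []
    for scheme_name, dataset in datasets.items():
        if dataset is None:
            logger.warning("scheme %s missing; row skipped", scheme_name)
            continue
        for space in spaces:
            gpa = full_gpa if space == "shape" else partial_gpa
            ensemble = gpa(dataset.configurations)
            labels = [getattr(c, group_field) for c in ensemble.configurations]
            res = pca(ensemble)
            scores = truncate_scores(res, labels)
            try:
                man = manova(scores, labels)
                man_p, man_stat, man_name = man.p, man.statistic, man.statistic_name
            except ValueError as exc:
                logger.warning("MANOVA failed for %s/%s: %s", scheme_name, space, exc)
                man_p = man_stat = float("nan")
                man_name = "failed"
            cv = cva(scores, labels, n_permutations=n_permutations, rng=seed)
            k1, k2 = pca_cumulative
            rows.append(
                {
                    "scheme": scheme_name,
                    "space": space,
                    "n_landmarks": len(dataset.scheme),
                    "dimensionality": res.dimensionality,
                    f"pc1_{k1}_pct": res.cumulative_percent(k1),
                    f"pc1_{k2}_pct": res.cumulative_percent(k2),
                    "manova_statistic": man_name,
                    "manova_value": man_stat,
                    "manova_p": man_p,
                    "mahalanobis_D": cv.mahalanobis_D,
                    "p_mahalanobis": cv.p_mahalanobis,
                    "procrustes_D": cv.procrustes_D,
                    "p_procrustes": cv.p_procrustes,
                }
            )
    return pd.DataFrame(rows)
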