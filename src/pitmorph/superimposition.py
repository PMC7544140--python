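"""Ordinary and generalised Procrustes superimposition.

Full GPA (translation, rotation, scaling to unit centroid size) places
configurations in *shape space*; partial GPA omits the scaling step and
places them in *form space*, preserving the original centroid sizes in mm.
Rotations are proper (no reflections): tooth-pit landmark sets are chiral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import LandmarkConfiguration


class AlignmentError(ValueError):
    pass


class DegenerateConfigurationError(ValueError):
    pass


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def optimal_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||mobile @ R - target||_F (Kabsch).

    Both inputs must already be centred.  The determinant sign of the SVD
    factors is corrected so no reflection is ever returned.
    """
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def opa_align(
    mobile: LandmarkConfiguration,
    target: LandmarkConfiguration,
    allow_scale: bool = False,
) -> tuple[LandmarkConfiguration, float]:
    """Ordinary Procrustes alignment of ``mobile`` onto ``target``.

    Translation, proper rotation and (optionally) uniform scale minimising
    the summed squared distances; returns the aligned configuration and the
    minimised root-sum-of-squares residual.
    """
    if mobile.labels != target.labels:
        raise AlignmentError("landmark labels/order differ between configurations")
    a = mobile.coords - mobile.coords.mean(axis=0)
    b = target.coords - target.coords.mean(axis=0)
    r = optimal_rotation(a, b)
    ar = a @ r
    if allow_scale:
        denom = np.sum(a**2)
        if denom == 0:
            raise DegenerateConfigurationError(
                f"configuration {mobile.pit_id} has zero centroid size"
            )
        s = np.sum(ar * b) / denom
    else:
        s = 1.0
    aligned = s * ar + target.coords.mean(axis=0)
    residual = float(np.sqrt(np.sum((aligned - target.coords) ** 2)))
    return mobile.replace(coords=aligned), residual


@dataclass
class AlignedEnsemble:
    """Superimposed configurations plus their mean reference.

    ``space`` is ``"shape"`` (scaled to unit centroid size) or ``"form"``
    (original sizes preserved).  ``centroid_sizes`` always stores the
    *original* sizes in mm.
    """

    space: str
    configurations: list[LandmarkConfiguration]
    mean_shape: LandmarkConfiguration
    centroid_sizes: list[float]
    iterations_used: int
    converged: bool

    def coords_array(self) -> np.ndarray:
        """(n, k, 3) stack of the aligned coordinates."""
        return np.stack([c.coords for c in self.configurations])


def _prepare(configs: Sequence[LandmarkConfiguration]) -> tuple[np.ndarray, list[float]]:
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    scheme = configs[0].labels
    for c in configs:
        if c.labels != scheme:
            raise AlignmentError(f"configuration {c.pit_id} has a different scheme")
    arr = np.stack([c.coords for c in configs]).astype(float)
    arr -= arr.mean(axis=1, keepdims=True)
    sizes = [float(np.sqrt(np.sum(a**2))) for a in arr]
    for c, s in zip(configs, sizes):
        if s < 1e-12:
            raise DegenerateConfigurationError(
                f"configuration {c.pit_id} has zero centroid size"
            )
    return arr, sizes


def _gpa(arr: np.ndarray, scale: bool, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, int, bool]:
    if scale:
        arr = arr / np.sqrt(np.sum(arr**2, axis=(1, 2)))[:, None, None]
    mean = arr[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(arr.shape[0]):
            arr[i] = arr[i] @ optimal_rotation(arr[i], mean)
        new_mean = arr.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if scale:
            new_mean /= np.sqrt(np.sum(new_mean**2))
        delta = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if delta < tol:
            converged = True
            break
    return arr, mean, iterations, converged


def _build_ensemble(
    configs: Sequence[LandmarkConfiguration],
    arr: np.ndarray,
    mean: np.ndarray,
    sizes: list[float],
    space: str,
    iterations: int,
    converged: bool,
) -> AlignedEnsemble:
    aligned = [c.replace(coords=a) for c, a in zip(configs, arr)]
    mean_cfg = LandmarkConfiguration(
        pit_id="mean", labels=configs[0].labels, coords=mean
    )
    return AlignedEnsemble(
        space=space,
        configurations=aligned,
        mean_shape=mean_cfg,
        centroid_sizes=sizes,
        iterations_used=iterations,
        converged=converged,
    )


def full_gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedEnsemble:
    """Generalised Procrustes analysis in shape space.

    All configurations are centred, scaled to unit centroid size and
    iteratively rotated to the running mean (itself renormalised to unit
    size each round) until the mean moves less than ``tol``.
    """
    arr, sizes = _prepare(configs)
    arr, mean, iterations, converged = _gpa(arr, scale=True, tol=tol, max_iter=max_iter)
    return _build_ensemble(configs, arr, mean, sizes, "shape", iterations, converged)


def partial_gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedEnsemble:
    """GPA without the scaling step (form space); centroid sizes preserved."""
    arr, sizes = _prepare(configs)
    arr, mean, iterations, converged = _gpa(arr, scale=False, tol=tol, max_iter=max_iter)
    return _build_ensemble(configs, arr, mean, sizes, "form", iterations, converged)


def procrustes_distance(
    a: LandmarkConfiguration,
    b: LandmarkConfiguration,
    space: str = "shape",
) -> float:
    """Chordal Procrustes distance after optimal superimposition.

    In shape space both configurations are first scaled to unit centroid
    size; in form space sizes are kept.  The distance is the root sum of
    squared coordinate differences after centring and optimal rotation.
    """
    if a.labels != b.labels:
        raise AlignmentError("landmark schemes differ")
    if space not in ("shape", "form"):
        raise ValueError(f"space must be 'shape' or 'form', got {space!r}")
    xa = a.coords - a.coords.mean(axis=0)
    xb = b.coords - b.coords.mean(axis=0)
    if space == "shape":
        sa, sb = np.sqrt(np.sum(xa**2)), np.sqrt(np.sum(xb**2))
        if sa < 1e-12 or sb < 1e-12:
            raise DegenerateConfigurationError("zero centroid size")
        xa, xb = xa / sa, xb / sb
    r = optimal_rotation(xa, xb)
    return float(np.sqrt(np.sum((xa @ r - xb) ** 2)))


def pairwise_procrustes_distances(
    configs: Sequence[LandmarkConfiguration], space: str = "shape"
) -> np.ndarray:
    """Symmetric matrix of pairwise Procrustes distances."""
    n = len(configs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = procrustes_distance(configs[i], configs[j], space=space)
            out[i, j] = out[j, i] = d
    return out
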