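"""Fuzzy c-means (fuzzy k-means) pixel clustering and lesion-mask extraction.

Pixels are clustered in RGB space by minimizing the fuzzy objective

    L = sum_j sum_i  b_ij^f * ||x_i - C_j||^2

where ``b_ij`` in [0, 1] is the membership of pixel i in cluster j (rows
sum to 1), ``C_j`` are the cluster centroids and ``f > 1`` is the
fuzzifier controlling membership softness.  Alternating the closed-form
block minimizers

    b_ij = 1 / sum_l (g_ij / g_il)^(1/(f-1)),      g_ij = ||x_i - C_j||^2
    C_j  = sum_i b_ij^f x_i / sum_i b_ij^f

never increases L, so the objective trace is monotone non-increasing and
iteration stops once |delta L| < tol.

The lesion is identified as the cluster whose centroid has the lowest
luminance (0.299 R + 0.587 G + 0.114 B): pigmented lesions are darker
than surrounding skin.  A pixel enters the binary mask iff its maximal
membership is in that cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FkmConfig",
    "FkmResult",
    "fkm_objective",
    "fkm_fit",
    "select_lesion_cluster",
    "segment_image",
    "dice_coefficient",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FkmConfig:
    k: int = 2
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FkmResult:
    memberships: np.ndarray  # n_points x k, rows sum to 1
    centroids: np.ndarray  # k x dim
    objective_trace: list[float] = field(default_factory=list)

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def fkm_objective(
    memberships: np.ndarray,
    points: np.ndarray,
    centroids: np.ndarray,
    fuzzifier: float,
) -> float:
    """Fuzzy clustering objective: sum of membership-weighted squared
    Euclidean distances, ``sum_ij b_ij^f * ||x_i - C_j||^2``."""
    memberships = np.asarray(memberships, dtype=float)
    points = np.asarray(points, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if memberships.shape != (points.shape[0], centroids.shape[0]):
        raise ValueError("membership matrix shape mismatch")
    if points.shape[1] != centroids.shape[1]:
        raise ValueError("point/centroid dimension mismatch")
    g = _sq_distances(points, centroids)
    return float(np.sum(memberships**fuzzifier * g))


def _sq_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - centroids[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _update_memberships(g: np.ndarray, fuzzifier: float) -> np.ndarray:
    # b_ij = 1 / sum_l (g_ij / g_il)^(1/(f-1)); points coinciding with a
    # centroid (g == 0) get crisp membership there (limit of the update).
    power = 1.0 / (fuzzifier - 1.0)
    zero_rows = np.any(g <= 0.0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = g ** (-power)
        b = inv / inv.sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        b[zero_rows] = 0.0
        hits = g[zero_rows] <= 0.0
        b[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return b


def _farthest_point_init(
    points: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded farthest-point centroid initialization over distinct points."""
    distinct = np.unique(points, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(
            f"need at least {k} distinct points, got {distinct.shape[0]}"
        )
    first = rng.integers(distinct.shape[0])
    chosen = [distinct[first]]
    d = np.sum((distinct - chosen[0]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        chosen.append(distinct[nxt])
        d = np.minimum(d, np.sum((distinct - distinct[nxt]) ** 2, axis=1))
    return np.array(chosen, dtype=float)


def fkm_fit(points: np.ndarray, config: FkmConfig) -> FkmResult:
    """Run fuzzy c-means to convergence on an n x dim point set."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D (n x dim)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    rng = np.random.default_rng(config.seed)
    centroids = _farthest_point_init(points, config.k, rng)

    trace: list[float] = []
    memberships = None
    prev_obj = np.inf
    for _ in range(config.max_iter):
        g = _sq_distances(points, centroids)
        memberships = _update_memberships(g, config.fuzzifier)
        bf = memberships**config.fuzzifier
        centroids = (bf.T @ points) / bf.sum(axis=0)[:, None]
        obj = fkm_objective(memberships, points, centroids, config.fuzzifier)
        trace.append(obj)
        if abs(prev_obj - obj) < config.tol:
            break
        prev_obj = obj
    return FkmResult(
        memberships=memberships, centroids=centroids, objective_trace=trace
    )


def select_lesion_cluster(result: FkmResult, image: np.ndarray) -> int:
    """Index of the darkest cluster (lowest centroid luminance).

    Ties break toward the lowest index.  For single-channel feature
    spaces the centroid value itself is the luminance.
    """
    centroids = result.centroids
    if centroids.shape[1] == 3:
        luminance = centroids @ _LUMA
    else:
        luminance = centroids.mean(axis=1)
    return int(np.argmin(luminance))


def segment_image(image: np.ndarray, config: FkmConfig | None = None) -> np.ndarray:
    """Binary lesion mask for an H x W x 3 image via fuzzy c-means on RGB.

    A pixel is lesion iff its maximal membership lies in the darkest
    cluster.  Raises on images with fewer distinct colors than k.
    """
    if config is None:
        config = FkmConfig()
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    points = image.reshape(h * w, -1)
    result = fkm_fit(points, config)
    lesion = select_lesion_cluster(result, image)
    return (result.hard_labels == lesion).reshape(h, w)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)
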