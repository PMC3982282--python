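"""Unsupervised intensity clustering for threshold-free binarization.

The gray-level edge-magnitude image produced by the Gabor bank is converted
into a binary image without picking a threshold: pixel intensities are
partitioned into two clusters by k-means or fuzzy c-means (FCM), and the
cluster with the larger center becomes the foreground (edge) class.

Both algorithms operate on intensity alone (no spatial features) and are
implemented directly from their update equations:

* k-means minimizes the sum of squared Euclidean distances of each
  intensity to its nearest cluster center, alternating nearest-center
  assignment with center-of-mass updates.
* FCM minimizes a membership-weighted cost, alternating the
  membership-weighted center update

      c_i = sum_j mu_ij^m x_j / sum_j mu_ij^m

  with the inverse-distance membership update

      mu_ij = 1 / sum_k (|x_j - c_i| / |x_j - c_k|)^(2/(m-1)),

  where m > 1 is the fuzziness exponent.  A pixel coinciding with one or
  more centers gets membership split equally over the coinciding centers
  (the standard removable singularity).

Reported costs use the squared-distance convention in both cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateInputError",
    "ClusterResult",
    "FcmConfig",
    "kmeans_cluster",
    "fcm_cluster",
    "fcm_membership_update",
    "binarize",
]


class DegenerateInputError(ValueError):
    """Raised when the input carries fewer distinct values than clusters."""


@dataclass
class ClusterResult:
    """Outcome of a clustering run.

    Attributes
    ----------
    centers : ndarray, shape (n_clusters,)
        Intensity-space centroids.
    labels : ndarray of int
        Hard cluster index per pixel; same shape as the input values.
    memberships : ndarray, shape (n_pixels, n_clusters), or None
        FCM only: graded membership of each (flattened) pixel in each
        cluster; rows sum to 1.
    cost_trace : ndarray
        Cost after each iteration (squared-distance convention).
    iterations : int
    converged : bool
    """

    centers: np.ndarray
    labels: np.ndarray
    memberships: np.ndarray | None
    cost_trace: np.ndarray
    iterations: int
    converged: bool


@dataclass(frozen=True)
class FcmConfig:
    """Fuzzy c-means settings.

    ``fuzziness`` is the exponent m > 1 controlling how soft the memberships
    are; 2.0 is the conventional choice.  ``tol`` is the convergence
    tolerance on the largest center movement between iterations.
    """

    n_clusters: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.fuzziness <= 1.0:
            raise ValueError(
                f"fuzziness must be > 1 (got {self.fuzziness}); the membership "
                "exponent divides by fuzziness - 1"
            )
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


def _prepare(values: np.ndarray, n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    flat = arr.reshape(-1)
    distinct = np.unique(flat)
    if distinct.size < n_clusters:
        raise DegenerateInputError(
            f"need at least {n_clusters} distinct values, got {distinct.size}"
        )
    return arr, distinct


def kmeans_cluster(
    values: np.ndarray,
    n_clusters: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterResult:
    """Hard k-means on pixel intensities.

    Centers are initialized as ``n_clusters`` distinct values drawn at
    random from the data under ``seed``; the assign/update loop stops when
    the largest center movement falls below ``tol``.  The cost recorded per
    iteration (sum of squared distances to the assigned center) is
    non-increasing by construction.
    """
    if n_clusters < 1:
        raise ValueError(f"n_clusters must be >= 1, got {n_clusters}")
    arr, distinct = _prepare(values, n_clusters)
    flat = arr.reshape(-1)
    rng = np.random.default_rng(seed)
    centers = rng.choice(distinct, size=n_clusters, replace=False)

    cost_trace = []
    converged = False
    labels = np.zeros(flat.shape, dtype=np.intp)
    for iteration in range(1, max_iter + 1):
        d2 = (flat[:, np.newaxis] - centers[np.newaxis, :]) ** 2
        labels = np.argmin(d2, axis=1)
        cost_trace.append(float(d2[np.arange(flat.size), labels].sum()))
        new_centers = centers.copy()
        for i in range(n_clusters):
            members = flat[labels == i]
            if members.size:  # empty clusters keep their previous center
                new_centers[i] = members.mean()
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            converged = True
            break

    return ClusterResult(
        centers=centers,
        labels=labels.reshape(arr.shape),
        memberships=None,
        cost_trace=np.asarray(cost_trace),
        iterations=iteration,
        converged=converged,
    )


def fcm_membership_update(
    values: np.ndarray, centers: np.ndarray, fuzziness: float
) -> np.ndarray:
    """Membership matrix for given centers (one inverse-distance-ratio step).

    Returns an (n_pixels, n_clusters) matrix whose rows sum to 1.  Pixels at
    zero distance from one or more centers get membership split equally over
    the coinciding centers.
    """
    flat = np.asarray(values, dtype=np.float64).reshape(-1)
    centers = np.asarray(centers, dtype=np.float64).reshape(-1)
    d = np.abs(flat[:, np.newaxis] - centers[np.newaxis, :])
    zero_rows = np.any(d == 0.0, axis=1)
    p = 2.0 / (fuzziness - 1.0)
    mu = np.empty_like(d)
    ok = ~zero_rows
    # Normalizing by the per-pixel minimum distance keeps every ratio >= 1,
    # so ratio**(-p) stays in (0, 1] even for fuzziness close to 1.
    ratio = d[ok] / d[ok].min(axis=1, keepdims=True)
    inv = ratio ** (-p)
    mu[ok] = inv / inv.sum(axis=1, keepdims=True)
    if np.any(zero_rows):
        hits = d[zero_rows] == 0.0
        mu[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return mu


def fcm_cluster(values: np.ndarray, config: FcmConfig | None = None) -> ClusterResult:
    """Fuzzy c-means on pixel intensities.

    Memberships are initialized at random (normalized per pixel) under
    ``config.seed``; center and membership updates alternate until the
    largest center movement drops below ``config.tol``.  Hard labels are the
    argmax membership per pixel.
    """
    config = config or FcmConfig()
    arr, _ = _prepare(values, config.n_clusters)
    flat = arr.reshape(-1)
    rng = np.random.default_rng(config.seed)
    mu = rng.random((flat.size, config.n_clusters))
    mu /= mu.sum(axis=1, keepdims=True)

    m = config.fuzziness
    centers = np.full(config.n_clusters, np.nan)
    cost_trace = []
    converged = False
    for iteration in range(1, config.max_iter + 1):
        w = mu**m
        new_centers = (w * flat[:, np.newaxis]).sum(axis=0) / w.sum(axis=0)
        mu = fcm_membership_update(flat, new_centers, m)
        d2 = (flat[:, np.newaxis] - new_centers[np.newaxis, :]) ** 2
        cost_trace.append(float((mu**m * d2).sum()))
        shift = (
            np.inf
            if np.any(np.isnan(centers))
            else float(np.max(np.abs(new_centers - centers)))
        )
        centers = new_centers
        if shift < config.tol:
            converged = True
            break

    return ClusterResult(
        centers=centers,
        labels=np.argmax(mu, axis=1).reshape(arr.shape),
        memberships=mu,
        cost_trace=np.asarray(cost_trace),
        iterations=iteration,
        converged=converged,
    )


def binarize(result: ClusterResult) -> np.ndarray:
    """Two-cluster result -> {0, 1} image; the brighter cluster is foreground.

    Deterministic regardless of how initialization ordered the cluster
    indices.
    """
    if result.centers.shape[0] != 2:
        raise ValueError(
            f"binarize requires exactly 2 clusters, got {result.centers.shape[0]}"
        )
    foreground = int(np.argmax(result.centers))
    return (result.labels == foreground).astype(np.uint8)
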