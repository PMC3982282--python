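"""Brute-force reference implementations used only as test oracles.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and independent of the library code paths it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Symmetric (reflect) boundary rule: ... 2 1 0 | 0 1 2 ... n-1 | n-1 ..."""
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        else:
            i = 2 * n - 1 - i
    return i


def conv2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-sum true 2D convolution with reflect borders, same-size output."""
    h, w = image.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    out = np.zeros((h, w), dtype=np.result_type(image.dtype, kernel.dtype, np.float64))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    rr = reflect_index(r - (a - rh), h)
                    cc = reflect_index(c - (b - rw), w)
                    acc = acc + kernel[a, b] * image[rr, cc]
            out[r, c] = acc
    return out


def correlate2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-sum cross-correlation (no kernel flip) with reflect borders."""
    return conv2d_reflect(image, kernel[::-1, ::-1])


def median_filter_bruteforce(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel sort-based median over a reflect-padded square window."""
    h, w = image.shape
    r = window // 2
    out = np.zeros_like(image, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            vals = sorted(
                image[reflect_index(i + di, h), reflect_index(j + dj, w)]
                for di in range(-r, r + 1)
                for dj in range(-r, r + 1)
            )
            out[i, j] = vals[len(vals) // 2]
    return out


def best_two_partition_cost(values: np.ndarray) -> float:
    """Globally optimal 2-cluster sum-of-squares cost by exhaustive enumeration."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    best = np.inf
    for mask in range(1, 2**n - 1):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a, b = values[sel], values[~sel]
        cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        best = min(best, cost)
    return float(best)


def fcm_fixed_point(
    values: np.ndarray,
    init_memberships: np.ndarray,
    fuzziness: float,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> np.ndarray:
    """Loop-coded alternating center/membership iteration, run to tolerance."""
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    mu = np.array(init_memberships, dtype=np.float64)
    n, k = mu.shape
    centers = np.zeros(k)
    prev = None
    for _ in range(max_iter):
        for i in range(k):
            num = den = 0.0
            for j in range(n):
                wij = mu[j, i] ** fuzziness
                num += wij * values[j]
                den += wij
            centers[i] = num / den
        for j in range(n):
            d = [abs(values[j] - centers[i]) for i in range(k)]
            if any(x == 0.0 for x in d):
                hits = [1.0 if x == 0.0 else 0.0 for x in d]
                s = sum(hits)
                mu[j] = [h / s for h in hits]
                continue
            for i in range(k):
                mu[j, i] = 1.0 / sum(
                    (d[i] / d[m]) ** (2.0 / (fuzziness - 1.0)) for m in range(k)
                )
        if prev is not None and max(abs(centers[i] - prev[i]) for i in range(k)) < tol:
            break
        prev = centers.copy()
    return centers.copy()


def fom_bruteforce(truth: np.ndarray, detected: np.ndarray, alpha: float) -> float:
    """Figure of merit with an all-pairs nearest-neighbor distance scan."""
    t_pts = np.argwhere(np.asarray(truth, bool))
    d_pts = np.argwhere(np.asarray(detected, bool))
    if len(d_pts) == 0:
        return 0.0
    total = 0.0
    for p in d_pts:
        dmin = min(float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in t_pts)
        total += 1.0 / (1.0 + alpha * dmin**2)
    return total / max(len(t_pts), len(d_pts))
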