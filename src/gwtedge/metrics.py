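"""Edge-detection quality statistics: MCR, Pratt's figure of merit, PSNR.

Misclassification rate (MCR) is the percentage of pixels where the detected
binary edge map disagrees with the ground truth (logical exclusive-or count
over the total pixel count); lower is better and identical maps score 0.

Pratt's figure of merit (FOM) tolerates small localization errors:

    FOM = 1/max(N_t, N_d) * sum_{i in detected} 1 / (1 + alpha * L(i)^2)

where N_t and N_d are the true and detected edge-pixel counts, L(i) is the
Euclidean distance from detected pixel i to the nearest true edge pixel and
alpha (conventionally 1/9) scales the distance penalty.  FOM lies in
[0, 1]; 1 means perfect detection, and both missed and spurious edges lower
it through the max(N_t, N_d) normalization.  An empty detection scores 0.

PSNR = 10 log10(peak^2 / MSE) in dB quantifies the severity of additive
noise in the phantom experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["EdgeEvaluation", "mcr", "fom", "psnr", "evaluate_edges"]

#: Conventional distance-penalty scaling factor for the figure of merit.
DEFAULT_ALPHA = 1.0 / 9.0


@dataclass(frozen=True)
class EdgeEvaluation:
    """Scores for one (ground truth, detected) edge-map pair."""

    mcr_percent: float
    fom: float
    n_true_edge: int
    n_detected_edge: int


def _check_pair(truth: np.ndarray, detected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    d = np.asarray(detected)
    if t.shape != d.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs detected {d.shape}")
    if t.ndim != 2:
        raise ValueError("edge maps must be 2D")
    for name, a in (("truth", t), ("detected", d)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} must be a binary {{0,1}} image")
    return t.astype(bool), d.astype(bool)


def mcr(truth: np.ndarray, detected: np.ndarray) -> float:
    """Misclassification rate in percent: 100 * |truth XOR detected| / total."""
    t, d = _check_pair(truth, detected)
    return 100.0 * float(np.mean(t ^ d))


def fom(truth: np.ndarray, detected: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Pratt's figure of merit in [0, 1]; 1 iff the detection is perfect."""
    t, d = _check_pair(truth, detected)
    n_t = int(t.sum())
    if n_t == 0:
        raise ValueError("truth edge map must contain at least one edge pixel")
    n_d = int(d.sum())
    if n_d == 0:
        return 0.0
    # Exact Euclidean distance from every pixel to the nearest true edge pixel.
    dist = ndimage.distance_transform_edt(~t)
    scores = 1.0 / (1.0 + alpha * dist[d] ** 2)
    return float(scores.sum() / max(n_t, n_d))


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; infinite for identical images."""
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def evaluate_edges(
    truth: np.ndarray, detected: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> EdgeEvaluation:
    """Convenience wrapper computing MCR and FOM for one edge-map pair."""
    t, d = _check_pair(truth, detected)
    return EdgeEvaluation(
        mcr_percent=mcr(truth, detected),
        fom=fom(truth, detected, alpha=alpha),
        n_true_edge=int(t.sum()),
        n_detected_edge=int(d.sum()),
    )
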