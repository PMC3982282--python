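"""Synthetic phantom of overlapping ellipses with exact ground-truth edges.

Real medical images have no reliable ground truth, so edge detectors are
benchmarked on a phantom: each ellipse stands in for a tissue, ellipses
drawn later overwrite earlier ones where they overlap, and the region map
(hence the exact boundary) is known by construction.  Additive Gaussian
noise calibrated to a target PSNR emulates acquisition noise; a median
filter is provided as the classical pre-filtering arm of the benchmark.

The shipped "paperlike" spec is a synthetic stand-in — a 256x256 field of
five overlapping ellipses at distinct intensities on a dark background —
for the kind of phantom such benchmarks use; it is not a reproduction of
any particular published phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomOutput",
    "paperlike_spec",
    "render_phantom",
    "add_gaussian_noise",
    "median_filter",
]


@dataclass(frozen=True)
class Ellipse:
    """One tissue: a rotated ellipse painted at a constant intensity.

    ``cx``/``cy`` are the center in pixel coordinates (x along columns,
    y along rows), ``a``/``b`` the semi-axes in pixels, ``rotation`` the
    counterclockwise angle of the a-axis in radians.
    """

    cx: float
    cy: float
    a: float
    b: float
    rotation: float = 0.0
    intensity: float = 255.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry: image size, ordered ellipse list, background level."""

    size: tuple[int, int] = (256, 256)
    ellipses: tuple[Ellipse, ...] = ()
    background_intensity: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ellipses) == 0:
            raise ValueError("a phantom needs at least one ellipse")
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError(f"size must be positive, got {self.size}")


@dataclass
class PhantomOutput:
    """Rendered phantom: intensity image, region labels, exact edge map."""

    image: np.ndarray
    truth_edge: np.ndarray
    truth_regions: np.ndarray


def paperlike_spec(size: tuple[int, int] = (256, 256)) -> PhantomSpec:
    """Default five-ellipse phantom: a body outline containing two
    overlapping organs, a small bright inclusion and an off-center lobe.

    Tissue intensities are distinct but moderate (adjacent-tissue steps of
    30-60 gray levels on the 0-255 scale), so that strong additive noise
    genuinely competes with the weaker boundaries — the regime in which
    noise robustness separates detectors.  Internal boundaries (the
    inclusion inside an organ, the organ overlap) are part of the ground
    truth.
    """
    h, w = size
    sy, sx = h / 256.0, w / 256.0

    def e(cx, cy, a, b, rot, val):
        return Ellipse(cx * sx, cy * sy, a * sx, b * sy, rot, val)

    return PhantomSpec(
        size=size,
        ellipses=(
            e(128, 128, 105, 85, 0.0, 100.0),        # body
            e(95, 115, 45, 60, 0.35, 150.0),         # organ 1
            e(165, 140, 50, 38, -0.5, 180.0),        # organ 2, overlaps organ 1
            e(100, 110, 14, 10, 0.2, 220.0),         # bright inclusion in organ 1
            e(135, 195, 38, 18, 0.1, 60.0),          # dark lobe near the body edge
        ),
        background_intensity=20.0,
    )


def render_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Rasterize the phantom and extract its exact one-pixel-wide edge map.

    A pixel belongs to an ellipse iff its center satisfies the rotated
    ellipse inequality; later ellipses overwrite earlier ones, and
    ``truth_regions`` records the final owner (0 = background).  The edge
    map marks, for every boundary between two region labels, the pixels on
    the higher-label (interior / later-drawn) side, giving a deterministic
    one-pixel-wide contour per boundary.
    """
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    for idx, ell in enumerate(spec.ellipses, start=1):
        dx = xx - ell.cx
        dy = yy - ell.cy
        c, s = np.cos(ell.rotation), np.sin(ell.rotation)
        u = (dx * c + dy * s) / ell.a
        v = (-dx * s + dy * c) / ell.b
        labels[u**2 + v**2 <= 1.0] = idx

    intensities = np.concatenate(
        ([spec.background_intensity], [ell.intensity for ell in spec.ellipses])
    )
    image = intensities[labels]

    # Edge = pixel with at least one 4-neighbor of strictly smaller label;
    # image borders replicate so the frame itself is not an edge.
    padded = np.pad(labels, 1, mode="edge")
    edge = np.zeros((h, w), dtype=bool)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        neighbor = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        edge |= neighbor < labels
    return PhantomOutput(
        image=image, truth_edge=edge.astype(np.uint8), truth_regions=labels
    )


def add_gaussian_noise(
    image: np.ndarray,
    target_psnr_db: float,
    peak: float = 255.0,
    seed: int = 0,
    clip: bool = True,
) -> np.ndarray:
    """Add zero-mean Gaussian noise calibrated to a target PSNR.

    The noise standard deviation is ``peak / 10**(target_psnr_db / 20)``,
    which makes the expected mean squared error equal to the MSE implied by
    the target PSNR.  With ``clip`` (default) the result is clipped to
    [0, peak]; pass ``clip=False`` to measure the achieved PSNR exactly.
    An infinite target returns the image unchanged.
    """
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    if not np.isfinite(target_psnr_db):
        if target_psnr_db > 0:  # +inf sentinel: zero-noise limit
            return np.asarray(image, dtype=np.float64).copy()
        raise ValueError(f"target_psnr_db must be finite or +inf, got {target_psnr_db}")
    arr = np.asarray(image, dtype=np.float64)
    sigma = peak / 10.0 ** (target_psnr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = arr + rng.normal(0.0, sigma, size=arr.shape)
    if clip:
        np.clip(noisy, 0.0, peak, out=noisy)
    return noisy


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with a square window and reflect-padded borders."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    arr = np.asarray(image, dtype=np.float64)
    return ndimage.median_filter(arr, size=window, mode="reflect")
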