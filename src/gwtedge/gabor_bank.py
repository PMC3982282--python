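"""Complex 2D Gabor wavelet filter bank.

A Gabor wavelet is a Gaussian envelope modulated by a complex sinusoidal
plane wave:

    G(x, y) = 1/(2 pi sigma^2) * exp(-(x^2 + y^2) / (2 sigma^2))
                               * exp(2 pi j u (x cos(theta) + y sin(theta)))

where ``u`` is the frequency of the sinusoid, ``theta`` the orientation of
the wave vector and ``sigma`` the isotropic standard deviation of the
envelope.  Convolving a grayscale image with G and taking the modulus
enhances intensity edges perpendicular to the wave vector while averaging
out uncorrelated noise.  Fusing the moduli over several orientations yields
a single edge-magnitude image covering all edge directions.

Kernel offsets are mapped to normalized coordinates (``coord_scale``,
default ``1/support``, so x and y span roughly (-0.5, 0.5) across the
kernel); the sigma values this module is used with (0.03-0.3) are sub-pixel
in pixel units and only make sense under such a mapping.  Pixel-unit
behaviour remains available by passing ``coord_scale=1.0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "DEFAULT_THETAS",
    "GaborParams",
    "OrientationResponse",
    "make_gabor_kernel",
    "apply_gabor",
    "fuse_orientations",
]

#: Orientation bank covering edge directions every 45 degrees.
DEFAULT_THETAS: tuple[float, ...] = (np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single complex Gabor kernel.

    Parameters
    ----------
    sigma : float
        Standard deviation of the Gaussian envelope, in normalized kernel
        coordinates (see ``coord_scale``).  Must be positive.
    freq : float
        Frequency ``u`` of the sinusoidal plane wave, in cycles per
        normalized coordinate unit.  ``freq = 0`` degenerates to a pure real
        Gaussian.
    theta : float
        Orientation of the wave vector, radians.
    support : int
        Side length of the square kernel in pixels; odd, >= 3.
    coord_scale : float, optional
        Factor mapping pixel offsets to the (x, y) coordinates of the kernel
        formula.  Defaults to ``1/support`` so the kernel spans roughly
        (-0.5, 0.5) in each axis.
    """

    sigma: float
    freq: float
    theta: float
    support: int = 31
    coord_scale: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive real, got {self.sigma}")
        if self.freq < 0 or not np.isfinite(self.freq):
            raise ValueError(f"freq must be a non-negative real, got {self.freq}")
        if self.support < 3 or self.support % 2 == 0:
            raise ValueError(
                f"support must be an odd integer >= 3, got {self.support}"
            )
        if self.coord_scale is not None and self.coord_scale <= 0:
            raise ValueError(
                f"coord_scale must be positive, got {self.coord_scale}"
            )

    @property
    def scale(self) -> float:
        """Effective pixel-to-coordinate factor (``1/support`` by default)."""
        return 1.0 / self.support if self.coord_scale is None else self.coord_scale


@dataclass
class OrientationResponse:
    """Multi-orientation Gabor responses and their fused magnitude image.

    ``fused`` is the elementwise sum (or, optionally, maximum) of the
    per-orientation magnitude images and carries the total edge information
    of the bank.
    """

    thetas: tuple[float, ...]
    per_orientation: list[np.ndarray]
    magnitudes: list[np.ndarray]
    fused: np.ndarray


def make_gabor_kernel(params: GaborParams) -> np.ndarray:
    """Build a ``support x support`` complex Gabor kernel.

    The entry at pixel offset (dx, dy) from the kernel center is the Gabor
    formula evaluated at ``x = dx * coord_scale``, ``y = dy * coord_scale``
    (x along columns, y along rows).  At the origin both exponentials are 1,
    so the center value is exactly ``1/(2 pi sigma^2)``.
    """
    r = params.support // 2
    offsets = np.arange(-r, r + 1, dtype=np.float64) * params.scale
    x = offsets[np.newaxis, :]  # columns
    y = offsets[:, np.newaxis]  # rows
    sigma2 = params.sigma**2
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma2)) / (2.0 * np.pi * sigma2)
    phase = 2.0 * np.pi * params.freq * (
        x * np.cos(params.theta) + y * np.sin(params.theta)
    )
    return envelope * np.exp(1j * phase)


def apply_gabor(image: np.ndarray, params: GaborParams) -> np.ndarray:
    """Convolve a grayscale image with a complex Gabor kernel.

    True 2D convolution (kernel flipped) with symmetric (reflect) border
    padding; the output has the same height and width as the input.  The
    FFT-based implementation is numerically equivalent to the direct sum.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if params.support > min(image.shape):
        warnings.warn(
            f"kernel support {params.support} exceeds the smallest image "
            f"dimension {min(image.shape)}; border effects will dominate",
            stacklevel=2,
        )
    kernel = make_gabor_kernel(params)
    r = params.support // 2
    # np.pad cannot reflect beyond the current size; grow iteratively so
    # kernels larger than the image still get well-defined borders.
    padded = image
    remaining = [r, r]
    while remaining[0] > 0 or remaining[1] > 0:
        step = (
            min(remaining[0], padded.shape[0]),
            min(remaining[1], padded.shape[1]),
        )
        padded = np.pad(padded, ((step[0],) * 2, (step[1],) * 2), mode="symmetric")
        remaining[0] -= step[0]
        remaining[1] -= step[1]
    out = fftconvolve(padded, kernel, mode="same")
    return out[r : r + image.shape[0], r : r + image.shape[1]]


def fuse_orientations(
    image: np.ndarray,
    sigma: float,
    freq: float,
    thetas: tuple[float, ...] = DEFAULT_THETAS,
    support: int = 31,
    coord_scale: float | None = None,
    fusion: str = "sum",
) -> OrientationResponse:
    """Run the orientation bank and fuse the magnitude responses.

    Parameters
    ----------
    fusion : {"sum", "max"}
        ``"sum"`` (default) adds the orientation magnitudes elementwise;
        ``"max"`` takes their elementwise maximum.
    """
    thetas = tuple(thetas)
    if len(thetas) == 0:
        raise ValueError("thetas must be a non-empty sequence of orientations")
    if fusion not in ("sum", "max"):
        raise ValueError(f"fusion must be 'sum' or 'max', got {fusion!r}")
    responses = []
    magnitudes = []
    for theta in thetas:
        params = GaborParams(
            sigma=sigma, freq=freq, theta=theta,
            support=support, coord_scale=coord_scale,
        )
        resp = apply_gabor(image, params)
        responses.append(resp)
        magnitudes.append(np.abs(resp))
    if fusion == "sum":
        fused = np.sum(magnitudes, axis=0)
    else:
        fused = np.max(magnitudes, axis=0)
    return OrientationResponse(
        thetas=thetas, per_orientation=responses, magnitudes=magnitudes, fused=fused
    )
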