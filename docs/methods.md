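# Methods

## Problem and pipeline

Tissue boundaries in CT/MRI slices must be located in images that are never
free of acquisition noise. Classical gradient operators (Sobel, Prewitt)
differentiate the image directly, so they amplify exactly the
high-frequency content that noise lives in. This package implements a
three-stage detector that separates *enhancement* from *decision*:

1. **Gabor wavelet bank.** The image is convolved with complex kernels

   G(x, y) = 1/(2πσ²) · exp(−(x²+y²)/(2σ²)) · exp(2πj·u·(x cosθ + y sinθ)),

   one per orientation θ. The modulus of each response rises where the
   image contains a step perpendicular to the wave vector and stays low in
   flat regions, because the Gaussian envelope averages uncorrelated noise
   while the sinusoid rejects the local mean. The per-orientation moduli
   are fused by an elementwise **sum** (a max rule is available behind
   `fusion="max"`); the default orientation set {π/4, π/2, 3π/4, π} covers
   edge directions every 45°.
2. **Threshold-free binarization.** The fused magnitude image is split
   into two intensity clusters by k-means or fuzzy c-means (FCM), both
   implemented from their update equations; the cluster with the larger
   center becomes the edge class. No gray-level threshold is ever chosen,
   which matters because the magnitude histogram has no reliable valley.
3. **Morphological cleanup.** The edge band is thinned to one-pixel-wide
   curves (Zhang–Suen-class thinning via scikit-image, which preserves
   8-connectivity) and 8-connected components smaller than `min_size`
   pixels are removed. Default order: skeletonize, then prune.

Classical Sobel/Prewitt baselines share stages 2–3 so that comparisons
isolate stage 1. How gradient maps "should" be thresholded is not
well-defined; reusing the clustering stage is this package's deliberate
fair-comparison convention and tends to *flatter* the baselines (the
cleanup rescues much of their noise clutter).

## Parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `sigma` | 0.14 | normalized kernel coords | envelope width; larger = more smoothing, worse localization |
| `freq` (u) | 4.0 | cycles per unit | with `sigma` sets DC rejection (see below) |
| `support` | 25 | pixels, odd | kernel side; envelope in pixels is `sigma·support` |
| `coord_scale` | 1/support | — | maps pixel offsets to (x, y); pixel units available via `coord_scale=1` |
| `thetas` | {π/4, π/2, 3π/4, π} | radians | 45° coverage; θ and θ+π give identical moduli |
| `fuzziness` | 2.0 | > 1 | conventional FCM exponent |
| `tol`, `max_iter` | 1e−6, 300 | — | convergence on max center movement |
| `min_size` | 10 | pixels | smallest surviving component |

**Kernel coordinates.** σ values in the 0.03–0.3 range are sub-pixel if
read in pixel units, so kernel offsets are mapped to normalized
coordinates spanning roughly (−0.5, 0.5) across the kernel
(`coord_scale = 1/support`). The 1/(2πσ²) prefactor is kept verbatim; no
energy renormalization.

**Choosing (σ, u).** The kernel's DC gain is ∝ exp(−2π²σ²u²), so the
product σ·u controls how strongly flat regions are rejected relative to
edges. All shipped presets keep σ·u ≈ 0.55 — about one sinusoid
wavelength inside the envelope, giving DC suppression below 1% — and
differ only in the envelope's pixel footprint:

* `default` (0.14, 4.0, 25): envelope ≈ 3.5 px; best edge localization on
  clean or lightly noisy images.
* `phantom-noise` (0.2, 3.0, 25): envelope ≈ 5 px; trades ~0.1 FOM of
  clean-image localization for stability under heavy noise. The
  noisy-phantom benchmark runs with this preset.

Gabor parameters are application-dependent, as with any filter bank;
per-image-class selection is expected and both fields remain free.

**Convolution conventions.** True convolution (kernel flipped) with
symmetric (reflect) border padding; reflection avoids spurious dark
borders that would register as edges. For the even real part flipping is
irrelevant and for the odd imaginary part it only changes sign, which the
modulus erases — documented purely for reproducibility. The implementation
is FFT-based for speed and is tested against a direct-sum oracle at 1e−9
relative tolerance.

## Clustering details

* k-means centers initialize as distinct random data values under the
  given seed; empty clusters keep their previous center. The recorded cost
  (sum of squared distances to the assigned center, evaluated after each
  assignment) is non-increasing by construction.
* FCM initializes random per-pixel memberships (normalized), then
  alternates the membership-weighted center update with the
  inverse-distance-ratio membership update. A pixel coinciding with one or
  more centers takes membership split equally over the coinciding centers
  — the standard removable singularity. Ratios are normalized by the
  per-pixel minimum distance before exponentiation so memberships stay
  finite even for fuzziness just above 1. Cost is reported with the
  squared-distance convention.
* Results depend on the seed only through initialization; identical
  inputs + seed reproduce results bit-for-bit. A near-uniform magnitude
  image (relative spread below 1e−9) is reported as a no-edge result with
  a warning instead of clustering float round-off.

## Evaluation statistics

* **MCR** = 100 · |truth XOR detected| / (total pixels). Symmetric; 0 for
  identical maps, 100 for complements; lower is better.
* **Pratt FOM** = 1/max(N_t, N_d) · Σ_detected 1/(1 + α·L²), with α = 1/9
  and L the exact Euclidean distance (distance transform) to the nearest
  true edge pixel; empty detections score 0. Bounded in [0, 1]; both
  missed and spurious edges lower it.
* **PSNR** = 10·log₁₀(peak²/MSE) dB; identical images report +inf.

## Synthetic phantom

The generator rasterizes an ordered list of rotated ellipses (pixel-center
inside test; later ellipses overwrite earlier), records the owning region
per pixel, and derives the exact edge map: a pixel is an edge pixel iff
some 4-neighbor carries a strictly smaller region label. Marking the
higher-label (interior/later-drawn) side yields a deterministic
one-pixel-wide contour, including internal boundaries that intensity alone
cannot reveal (e.g. a nested ellipse of equal intensity).

The shipped `paperlike_spec` is a 256×256 field of five overlapping
ellipses — body, two overlapping organs, a bright inclusion, a dark lobe —
on a dark background, with **moderate adjacent-tissue contrast (30–60 gray
levels)**. This is deliberate: with large steps everywhere, additive noise
at the benchmark's harshest level never competes with the edges and every
detector (including plain Sobel) looks fine; the moderate-contrast regime
is where noise robustness actually separates methods. The phantom is a
synthetic stand-in, not a reproduction of any specific published object.

Noise is zero-mean Gaussian with σ = peak/10^(PSNR/20), which makes the
expected MSE match the target PSNR exactly; the result is clipped to
[0, peak], and calibration is checked pre-clip (mean over 20 seeds within
±0.1 dB). Real CT/MRI noise is neither Gaussian nor stationary (Poisson
statistics, Rician magnitude noise, streaks, bias fields), and the phantom
has none of the texture or partial-volume blur of tissue — so passing
benchmarks here demonstrates noise robustness of the pipeline under
controlled conditions, not clinical performance.

## Benchmark design

`run_benchmark` renders the phantom once, degrades it at each PSNR level
(35.01, 30.01, 25.02, 23.00 dB by default) over several noise seeds, runs
each detector, and scores MCR/FOM against the exact truth. The optional
median pre-filter (3×3) applies to the classical methods only, mirroring
designs in which classical operators are granted denoising while the
Gabor pipeline runs on the raw noisy image. External detectors join via
`extra_methods` as callables returning a binary map — by design there is
no built-in Canny arm.

Problem sizes in the shipped test suite: 256×256 phantom, 10 noise seeds
per cell, 4 PSNR levels; clustering runs on all 65 536 pixels. The full
benchmark completes in well under a minute on one CPU.

## Known limitations

* Intensity-only clustering: no spatial regularization, so isolated bright
  noise clusters survive until the morphology stage.
* The truth edge sits on the interior side of each boundary while the
  fused-magnitude ridge straddles the intensity step, so even an ideal
  run carries a ~0.5–1 px systematic offset; with α = 1/9 this caps
  realistic FOM near 0.95 rather than 1.
* One (σ, u) pair per run — no multi-frequency pyramid.
* Strictly 2D; no DICOM ingestion (convert slices to PNG/TIFF first).
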