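# gwtedge

Edge detection for noisy grayscale medical images (CT/MRI slices), built
on the Gabor wavelet transform. The detector enhances edges while
suppressing noise by convolving the image with a bank of complex Gabor
kernels

    G(x, y) = 1/(2πσ²) · exp(−(x²+y²)/(2σ²)) · exp(2πj·u·(x cosθ + y sinθ))

at orientations θ ∈ {π/4, π/2, 3π/4, π}, fusing the response moduli into a
single edge-magnitude image, converting that gray-level image to binary
**without any threshold** via two-cluster k-means or fuzzy c-means, and
thinning the result to one-pixel-wide edges with morphological
skeletonization. It ships the standard evaluation statistics for edge
maps — misclassification rate (MCR) and Pratt's figure of merit (FOM,
α = 1/9) — plus a synthetic phantom of overlapping ellipses with exact
ground-truth edges and a PSNR-calibrated noise model, so the detector can
be benchmarked against Sobel/Prewitt baselines under controlled noise.

Intended users: image-analysis researchers and engineers who need a
reproducible, noise-robust 2D edge detector and a harness for comparing
detectors against known ground truth. See `docs/methods.md` for the model,
parameter guidance and limitations.

## Worked example

```python
from gwtedge import (add_gaussian_noise, detect_edges, evaluate_edges,
                     gradient_baseline, paperlike_spec, preset_config,
                     render_phantom)

out = render_phantom(paperlike_spec())              # 256x256, 5 ellipses
noisy = add_gaussian_noise(out.image, 23.0, seed=0) # heavy noise: 23 dB PSNR

cfg = preset_config("phantom-noise", seed=0)        # sigma=0.2, u=3.0
detected = detect_edges(noisy, cfg)                 # GWT -> k-means -> skeleton
ev = evaluate_edges(out.truth_edge, detected)
print(f"MCR = {ev.mcr_percent:.4f}%   FOM = {ev.fom:.4f}")
print(f"true edge pixels: {ev.n_true_edge}   detected: {ev.n_detected_edge}")

base = evaluate_edges(out.truth_edge, gradient_baseline(noisy, "sobel", cfg))
print(f"sobel baseline: MCR = {base.mcr_percent:.4f}%   FOM = {base.fom:.4f}")
```

prints

```
MCR = 2.4796%   FOM = 0.8298
true edge pixels: 1207   detected: 1270
sobel baseline: MCR = 4.1519%   FOM = 0.6096
```

Reading: at a punishing 23 dB PSNR the Gabor pipeline keeps its detected
skeleton within about a pixel of the true boundaries (FOM 0.83, where 1 is
perfect and an empty detection is 0) and mislabels 2.5% of pixels, while
the Sobel baseline — binarized and cleaned by the *same* downstream stages
— drops to FOM 0.61 with 4.2% misclassified. On the clean phantom the
default preset reaches FOM ≈ 0.92.

## Command line

```sh
gwtedge phantom --size 256 --psnr 23 --out-prefix phantom   # render + noise
gwtedge detect phantom_noisy.png edges.png --preset phantom-noise --seed 0
gwtedge score phantom_truth.png edges.png                   # MCR/FOM CSV row
gwtedge bench --n-seeds 10 --out bench.csv                  # full ladder
```

`--config file.yaml` supplies any `PipelineConfig` field; explicit flags
override the file.

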