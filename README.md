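# uhdog

Joint U-Net / Hessian-convexity detection of small bright blobs — cell
nuclei in 2D micrographs, glomeruli in 3D kidney MRI.

## The problem

Small blobs are numerous, low-contrast, noisy, and often touching.
Scale-space detectors (Laplacian/Difference of Gaussian) find every locally
dome-like region, including noise — they *over-detect*. Learned
segmentations (a U-Net probability map) know what blob tissue looks like
but merge touching blobs — they *under-segment*. This package intersects
the two:

1. **Local convexity.** The γ-normalized DoG response
   `R(·;σ) = −σ^(γ−1) · f ∗ (G(σ+Δσ) − G(σ)) / Δσ` (γ = 2, Δσ = 0.001) is
   computed over a grid of scales; a voxel is a blob candidate where the
   Hessian of R is negative definite (Sylvester's criterion, strict). The
   optimum scale σ* maximizes the average response over candidate voxels,
   `B(σ) = Σ R·HI / Σ HI`, giving the convexity map `HI(·;σ*)`.
2. **Global likelihood.** A small U-Net (numpy implementation, 3 levels,
   16 base channels, BCE + Adam, trained on noise-corrupted binary masks)
   yields a probability map U; `I = (U > δ_b)` with δ_b = 0.5.
3. **Joint map.** `UH = HI ∘ I`; connected components of UH (8-conn in 2D,
   26-conn in 3D) are the detected blobs, with response-weighted centroids,
   voxel counts, and apparent volumes (count × voxel volume).

Detection quality against dot annotations uses duplicate-protected
true-positive counting
`TP = min(#{j: min_i D_ij ≤ d}, #{i: min_j D_ij ≤ d})`, precision = TP/n,
recall = TP/m, F = harmonic mean, with d defaulting to the average blob
diameter `2·√(A/π)`.

For 3D kidney volumes a preprocessing step isolates the cortex: binarize
the organ, take the Euclidean distance transform, and zero voxels deeper
than a chosen cortex depth (the medulla contains no glomeruli).

## Worked example

Generate a synthetic fluorescence-style field (30 Gaussian blobs, radius
3–5 px, additive noise σ = 0.05) and detect with the noise-free support
mask as an oracle probability map:

```python
import numpy as np
from uhdog import synthetic, detect, evaluate_image

sample = synthetic.generate_blob_image(synthetic.BlobSpec(seed=7))
blobs = detect(sample.image, sample.mask.astype(float))
metrics = evaluate_image(sample.dots, blobs)

print("sigma* =", blobs.sigma_star)        # sigma* = 3.0
print("n_blobs =", blobs.n_blobs)          # n_blobs = 30
print("d = %.2f" % metrics.d)              # d = 5.10
print("precision = %.3f  recall = %.3f  F = %.3f"
      % (metrics.precision, metrics.recall, metrics.f_score))
# precision = 1.000  recall = 1.000  F = 1.000
```

All 30 ground-truth blobs are recovered, none spuriously: σ* = 3.0 won the
B(σ) scan on the 0.5–3.0 grid, and every joint-map component centroid fell
within the average-diameter radius d ≈ 5.1 px of its true center.

The same flow from the shell:

```sh
uhdog simulate --preset fluorescent2d --seed 7 --out-dir work/
uhdog detect --input work/fluorescent2d_0007_image.tif \
             --prob-map work/fluorescent2d_0007_mask.tif \
             --out-centroids work/cents.csv --out-report work/report.json
uhdog evaluate --truth work/fluorescent2d_0007_truth.csv \
               --pred work/cents.csv --d 5.1
```

`uhdog train` fits the U-Net on synthetic noisy-mask pairs and writes a
single-file checkpoint usable via `uhdog detect --model`; `uhdog
preprocess` removes the medulla from a kidney NIfTI volume
(`--distance-threshold` is required — the cortex depth is a deliberate,
explicit choice).

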