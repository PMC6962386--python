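# Methods

## The detection model

The package detects *small bright blobs* — objects a few voxels across,
roughly convex, sitting on a darker background: cell nuclei in 2D
micrographs, cationic-ferritin-labeled glomeruli in 3D kidney MRI. Two
constraints are intersected, each covering the other's failure mode.

### Local convexity: Hessian of the normalized DoG response

The image f is convolved with unit-sum sampled Gaussian kernels and the
γ-normalized Difference-of-Gaussian response is formed as

    R(·; σ) = − σ^(γ−1) · f ∗ (G(σ+Δσ) − G(σ)) / Δσ ,

a finite-difference approximation of the γ-normalized Laplacian of Gaussian
σ^γ ∇²L. Defaults: γ = 2, Δσ = 0.001. The leading minus sign is a
deliberate polarity convention: extra smoothing *lowers* a bright blob's
peak, so the raw finite difference is negative inside blobs; negating it
makes blob interiors local maxima of R, which is what the
negative-definiteness criterion below expects. The response is linear in
the input and zero on constant images.

At each voxel the Hessian of R is assembled from second-order central
differences (unit voxel step; the one-voxel border, where the stencil is
undefined, is excluded). The binary *convexity map* HI(·;σ) marks voxels
whose Hessian is negative definite — locally dome-like in every direction.
Definiteness is decided by Sylvester's criterion on the leading principal
minors, strict, with minors within ±1e−12 of zero failing; this is exact
for the 2×2/3×3 matrices involved and is verified against an
eigenvalue-sign oracle in the tests.

A single optimum scale per image is selected by scanning an ascending σ
grid and maximizing the average response over convex voxels,
B(σ) = Σ R·HI / Σ HI. Ties break toward the smaller σ (it resolves close
blobs better); scales with empty maps are flagged and skipped; if all are
empty the image is declared blob-free. Default grids: σ = 0.5…3.0 step 0.5
in 2D, σ = 0.5…1.8 step 0.1 in 3D. An alternative normalization that
divides by one extra factor of σ is switchable (`variant="eq9"`); at any
fixed σ the two differ by a positive constant, so only cross-scale
selection can differ.

The numerator of B uses the polarity-corrected response: with the raw
(negative-inside-blobs) sign, the argmax would select the scale at which
blobs respond *worst*.

### Global blob likelihood: the U-Net probability map

A small encoder–decoder network with skip connections maps the image to a
per-voxel blob probability U ∈ [0,1]. Because no deep-learning framework
is a dependency of this package, the network — forward pass,
backpropagation, and Adam — is implemented directly in numpy. The
architecture is compact by design: 3 resolution levels, 16 base channels,
one 3×3 convolution + ReLU per block, 2×2 max-pooling, nearest-neighbor
upsampling followed by a channel-halving convolution, skip concatenation,
and a 1×1 convolution with a sigmoid output. This trains on synthetic
fixtures in seconds-to-minutes on one CPU; a finite-difference gradient
check of the backward pass agrees to ~1e−7 relative.

Training follows the noisy-mask recipe: inputs are binary label masks
corrupted with additive Gaussian noise (μ = 0, σ² = 0.01) and clipped to
[0,1]; the loss is mean binary cross entropy with predictions clamped to
[1e−7, 1−1e−7]; the optimizer is Adam at learning rate 1e−3 (unstated in
the original description; chosen as the standard default — the
reproducibility contract matters more than the specific choice). One
gradient step per pair visit, cycling in order; every random draw flows
from one integer seed, so the loss trajectory is exactly reproducible.
Optional augmentation applies one random affine (rotation ±15°, shifts
±10%, shear ±8°, zoom 0.9–1.1, horizontal flip) identically to input and
label, re-binarizing the label at 0.5.

3D volumes are predicted slice-wise along z and stacked — the probability
map is defined per 2D slice, not by a 3D network. Inputs whose extent is
not a multiple of the downsampling factor are reflect-padded and cropped.
Checkpoints are single `.npz` files; predictions after a save/load round
trip are bit-identical.

The detector also accepts an externally supplied probability map. The test
suite uses *oracle* maps — the noise-free ground-truth support mask of a
synthetic image — to exercise the joint stage independently of training
quality.

### The joint constraint

With I = (U > δ_b) (strict inequality; default δ_b = 0.5), the joint map
is the elementwise product UH = HI ∘ I. Its connected components under the
full neighborhood (8 neighbors in 2D; the 27-voxel neighborhood, i.e. 26
neighbors, in 3D) are the detected blobs. The probability map removes the
convex noise speckles that the Hessian map over-detects; the convexity map
splits touching blobs that the thresholded probability map merges. No
post-pruning and no minimum size filter are applied by default (a
configurable floor exists for practical use).

Per-blob centroids are intensity-weighted over the polarity-corrected
response clipped at zero (a component with no positive response falls back
to its geometric centroid; a single-voxel blob's centroid is the voxel
center). Whether "intensity centroid" should weight by raw image intensity
instead is genuinely open; the response weighting is the default because
the response is the field in which the blob was defined.

## Kidney preprocessing

Glomeruli live in the cortex; the medulla contains none. The volume is
binarized (Otsu on a lightly smoothed volume by default, or a fixed
level), the largest component kept and holes filled; the Euclidean
distance transform of the foreground gives each voxel's depth from the
organ boundary; voxels deeper than a caller-supplied threshold are zeroed.
The threshold is deliberately required (no default): the right cortex
depth depends on species and voxel size. Distances are in voxel units
unless a physical spacing is passed.

## Evaluation protocol

Ground truth is a dot list of blob centers. A candidate matches a truth
dot within Euclidean distance d; true positives are counted with duplicate
protection, TP = min(#candidates-near-truth, #truths-near-candidate) —
deliberately *not* a one-to-one assignment, which is documented out of
scope. Precision = TP/n, recall = TP/m, F = harmonic mean. Undefined
ratios (empty candidate or truth list) are flagged NaN and counted as 0 in
batch averages.

The default d is the average blob diameter from the detected foreground:
d = 2·√(A/π) with A the *average per-blob* area. Read literally, the
printed rule would use the total foreground area inside the root — the
diameter of the pooled area — which contradicts the accompanying "average
diameter of the blobs" description; the per-blob reading is the default
and the literal one is switchable (`mode="literal"`). In 3D the analogue
is the equivalent-sphere diameter of the average per-blob volume.

## Synthetic study conditions

The generators define the conditions under which the detector is tested.

**Blob model.** A blob of radius r is an isotropic Gaussian profile with
σ_b = r/2, i.e. the stated radius is the ~95% energy radius — the
convention used when reporting nucleus/glomerulus sizes. The ground-truth
support mask is the half-peak level set of the noise-free composite image.
This pairing is load-bearing for the overlap experiment: two equal
Gaussians at center distance 1.3·r are separable by the convexity map for
σ ≲ 1.3·σ_b (the response develops a genuine positive-curvature band at
the midpoint), while their summed profile still exceeds half peak at the
midpoint, so the thresholded oracle probability map sees one connected
region. Under the alternative convention σ_b = r/1.18 (radius = half-peak
radius), the midpoint curvature of the response is negative for *every*
σ > 0 and no scale can split the pair — any apparent split is a
discretization artifact.

**Fluorescence-style fields** (`fluorescent2d`): 30 blobs, radius 3–5 px,
peaks 0.8–1.0, pairwise separation ≥ 4× the larger radius, i.i.d. additive
Gaussian noise σ = 0.05, clipped to [0,1], in 128×128 images. The image
size matches the blob density of crowded nucleus imagery; density matters
because B(σ) is a whole-image average: in a sparse field the many small
noise-induced convex domes dominate the average and drag σ* to the finest
grid scale, whereas at realistic density the blob response anchors σ* at
blob scale. Placement and noise use separate seed streams.

**Overlapping pairs**: two equal blobs at a specified center distance,
noise-free (the pair construction isolates the splitting geometry; the
seed varies orientation and sub-voxel placement). With noise added, a
mostly-empty pair image again loses the σ* race to noise.

**Speckled fields**: true blobs (radius 4–5) plus many small convex
distractors (radius ≈ 1.6) that receive near-zero oracle probability —
the over-detection scenario the probability map is meant to fix.

**Kidney phantom**: an ellipsoidal organ (semi-axes 1.0/0.85/0.8 ×
outer radius) of elevated tissue intensity, 200 blobs placed only where
boundary distance ≤ cortex depth, 50 bright distractors strictly deeper,
noise σ = 0.02. It emulates geometry and contrast, not MRI physics — no
partial-volume effects, bias fields, or anisotropic voxels.

What passing these tests shows: the numerics (Hessian, definiteness,
distance transform, TP counting) are exact against independent oracles,
and the joint constraint behaves as designed — splitting, denoising, scale
adaptation — on images satisfying the blob model. What it does not show:
performance on real micrographs or MRI, where noise is spatially
correlated, blobs deviate from Gaussian profiles, and the probability map
comes from a network trained on finite data rather than an oracle.

## Numerical choices and degenerate inputs

- Convolution boundary: reflect padding (zero padding creates spurious
  convex shells at borders). Kernels are truncated at radius ⌈4σ⌉ and
  renormalized to unit sum; smoothing is separable per axis.
- σ is applied in voxel units identically on all axes; anisotropic spacing
  is carried through for volume statistics but does not rescale the
  detector.
- Constant images rescale to all zeros on load rather than NaN, and flow
  through the pipeline to an empty detection.
- The scale scan raises "no blobs detectable" only when *every* scale
  yields an empty convexity map; `detect` converts that into an empty,
  valid result.
- Empty blob sets report n = 0 with NaN volumes rather than raising.

## Problem sizes

Default test and acceptance runs use 128² 2D fields (20–30 blobs), 96²
pair images, and a ~77×81×93 phantom (200 blobs) — sizes chosen so the
full suite, including training the network from scratch, completes in
about half a minute of compute while every pathway (2D, 3D, training,
preprocessing, evaluation) runs end to end.

## Known limitations

- The scale selector picks one global σ* per image; fields mixing very
  different blob sizes are served by whichever scale wins the average.
- B(σ)'s whole-image average is sensitive to background texture (see the
  density discussion above); on sparse noisy images σ* can collapse to
  the finest scale.
- The duplicate-protected TP count can exceed the size of a maximum
  one-to-one matching in adversarial configurations; this is the
  documented counting rule, not a bug.
- Slice-wise 3D prediction ignores through-plane context.
- The numpy network is CPU-bound and meant for small models; it is not a
  general training framework.
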