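"""Joint-constraint blob detection: UH = HI ∘ I.

The two constraints are complementary. The Hessian convexity map HI finds
every locally dome-like region — all true blobs plus convex noise — and
separates touching blobs. The thresholded probability map I keeps only
regions the U-Net considers blob-like, but cannot split touching blobs.
Their voxelwise intersection UH inherits both strengths: connected
components of UH (8-connectivity in 2D, 26-connectivity in 3D, i.e. the
"27-connected" neighborhood including the center voxel) are the detected
blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImageGrid
from .hessian_convexity import (
    ConvexityMap,
    ScaleSelection,
    select_optimal_scale,
)
from .scale_space import ScaleSpec, DoGResponse

__all__ = [
    "BlobSet",
    "BlobStatistics",
    "DetectConfig",
    "threshold_probability",
    "joint_map",
    "extract_blobs",
    "blob_statistics",
    "detect",
]

#: default σ grids (2D micrographs / 3D kidney volumes)
SIGMA_GRID_2D = (0.5, 3.0, 0.5)
SIGMA_GRID_3D = (0.5, 1.8, 0.1)


@dataclass
class BlobSet:
    """Connected components of the joint map with per-blob summaries."""

    label_image: np.ndarray
    centroids: np.ndarray  # (K, rank), voxel coordinates
    voxel_counts: np.ndarray  # (K,)
    sigma_star: float
    spacing: tuple[float, ...] = ()
    selection: ScaleSelection | None = None

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if not self.spacing:
            self.spacing = (1.0,) * self.label_image.ndim

    @property
    def n_blobs(self) -> int:
        return len(self.voxel_counts)


@dataclass
class BlobStatistics:
    """Count and apparent-volume summary (voxel count × voxel volume)."""

    n_glom: int
    mean_av: float  # mm^3; NaN when there are no blobs
    median_av: float


@dataclass(frozen=True)
class DetectConfig:
    """Parameters of the full detection pipeline."""

    sigma_min: float = 0.5
    sigma_max: float = 3.0
    sigma_step: float = 0.5
    delta_sigma: float = 0.001
    gamma: float = 2.0
    variant: str = "eq4"
    prob_threshold: float = 0.5
    min_blob_voxels: int = 0

    def sigma_grid(self) -> np.ndarray:
        n = int(round((self.sigma_max - self.sigma_min) / self.sigma_step)) + 1
        return self.sigma_min + self.sigma_step * np.arange(n)

    @classmethod
    def for_ndim(cls, ndim: int, **overrides) -> "DetectConfig":
        grid = SIGMA_GRID_2D if ndim == 2 else SIGMA_GRID_3D
        base = dict(sigma_min=grid[0], sigma_max=grid[1], sigma_step=grid[2])
        base.update(overrides)
        return cls(**base)


def threshold_probability(prob: np.ndarray, delta_b: float = 0.5) -> np.ndarray:
    """Binary indicator I = (U > δ_b); the inequality is strict."""
    if not 0.0 <= delta_b <= 1.0:
        raise ValueError(f"probability threshold must lie in [0, 1], got {delta_b}")
    prob = np.asarray(getattr(prob, "data", prob), dtype=float)
    return prob > delta_b


def joint_map(convexity: ConvexityMap | np.ndarray, indicator: np.ndarray) -> np.ndarray:
    """Elementwise intersection UH = HI ∘ I."""
    hi = np.asarray(getattr(convexity, "data", convexity), dtype=bool)
    ind = np.asarray(indicator, dtype=bool)
    if hi.shape != ind.shape:
        raise ValueError("convexity map and indicator shapes differ")
    return hi & ind


def _full_connectivity(ndim: int) -> np.ndarray:
    return np.ones((3,) * ndim, dtype=int)


def extract_blobs(
    joint: np.ndarray,
    response: DoGResponse | np.ndarray,
    sigma_star: float = float("nan"),
    spacing: tuple[float, ...] = (),
    min_blob_voxels: int = 0,
    selection: ScaleSelection | None = None,
) -> BlobSet:
    """Label UH components and compute response-weighted intensity centroids.

    Components use the full neighborhood (8-conn in 2D, 26-conn in 3D).
    Centroid weights are the bright-blob-positive response clipped at zero;
    a blob with no positive response falls back to its geometric centroid.
    """
    joint = np.asarray(joint, dtype=bool)
    resp = np.asarray(getattr(response, "data", response), dtype=float)
    labels, k = ndimage.label(joint, structure=_full_connectivity(joint.ndim))

    if k and min_blob_voxels > 1:
        counts = np.bincount(labels.ravel(), minlength=k + 1)
        keep = np.flatnonzero(counts[1:] >= min_blob_voxels) + 1
        remap = np.zeros(k + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
        k = len(keep)

    if k == 0:
        return BlobSet(
            np.zeros_like(joint, dtype=np.int32),
            np.empty((0, joint.ndim)),
            np.empty(0, dtype=int),
            sigma_star,
            spacing,
            selection,
        )

    counts = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    weights = np.clip(resp, 0.0, None)
    idx = np.arange(1, k + 1)
    wsum = ndimage.sum_labels(weights, labels, idx)
    centroids = np.empty((k, joint.ndim))
    weighted = wsum > 0
    if weighted.any():
        cm = ndimage.center_of_mass(weights, labels, idx[weighted])
        centroids[weighted] = np.asarray(cm).reshape(-1, joint.ndim)
    if (~weighted).any():
        cm = ndimage.center_of_mass(joint.astype(float), labels, idx[~weighted])
        centroids[~weighted] = np.asarray(cm).reshape(-1, joint.ndim)

    return BlobSet(labels.astype(np.int32), centroids, counts, sigma_star, spacing, selection)


def blob_statistics(blobs: BlobSet, spacing: tuple[float, ...] | None = None) -> BlobStatistics:
    """N_glom plus mean/median apparent volume = voxel count × voxel volume."""
    spacing = tuple(spacing) if spacing is not None else tuple(blobs.spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    if blobs.n_blobs == 0:
        return BlobStatistics(0, float("nan"), float("nan"))
    volumes = blobs.voxel_counts * float(np.prod(spacing))
    return BlobStatistics(blobs.n_blobs, float(np.mean(volumes)), float(np.median(volumes)))


def detect(
    image: ImageGrid,
    model_or_map,
    config: DetectConfig | None = None,
) -> BlobSet:
    """Full joint-constraint detection.

    ``model_or_map`` is either a trained :class:`~uhdog.unet_prob.ModelState`
    (a probability map is predicted from it) or an existing probability map
    (:class:`~uhdog.unet_prob.ProbabilityMap` or a bare array in [0, 1], e.g.
    an oracle map derived from a known mask).

    Pipeline: probability map → σ-grid DoG/Hessian scan → σ* by B_DoG
    argmax → optimum convexity map → UH = HI ∘ I → connected components.
    An empty result is a valid outcome.
    """
    config = config or DetectConfig.for_ndim(image.ndim)

    prob = model_or_map
    if hasattr(prob, "predict_probability_map"):
        prob = prob.predict_probability_map(image)
    prob = np.asarray(getattr(prob, "data", prob), dtype=float)
    if prob.shape != image.shape:
        raise ValueError(
            f"probability map shape {prob.shape} != image shape {image.shape}"
        )
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")

    defaults = ScaleSpec(
        sigma=config.sigma_min,
        delta_sigma=config.delta_sigma,
        gamma=config.gamma,
        variant=config.variant,
    )
    from .hessian_convexity import NoBlobsDetectableError

    try:
        selection = select_optimal_scale(image, config.sigma_grid(), defaults)
    except NoBlobsDetectableError:
        # a featureless image has no convex candidates anywhere: empty result
        return BlobSet(
            np.zeros(image.shape, dtype=np.int32),
            np.empty((0, image.ndim)),
            np.empty(0, dtype=int),
            float("nan"),
            image.spacing,
        )
    indicator = threshold_probability(prob, config.prob_threshold)
    uh = joint_map(selection.map_star, indicator)
    return extract_blobs(
        uh,
        selection.response_star,
        sigma_star=selection.sigma_star,
        spacing=image.spacing,
        min_blob_voxels=config.min_blob_voxels,
        selection=selection,
    )
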