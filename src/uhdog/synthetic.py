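"""Synthetic fixtures: blob images with exact ground truth, overlapping-blob
pairs, convex noise speckles, U-Net training masks, and a 3D kidney phantom.

Blob model
----------
A blob of radius ``r`` is an isotropic Gaussian intensity profile with
standard deviation ``σ_b = r / 2`` — i.e. the stated radius is the ~95%
energy radius, the convention used for reporting nucleus/glomerulus sizes.
The ground-truth support mask is the half-peak level set of the noise-free
composite image; for an isolated blob this is a disc of radius ≈ 1.18 σ_b,
and for overlapping pairs it is connected (the summed profile at the
midpoint exceeds half peak), mirroring how a probability map sees touching
blobs as one region.

All generators are pure functions of their parameters and seed. Placement
and noise use separate seed streams so noise realizations can vary at fixed
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .image_io import ImageGrid, DotList

__all__ = [
    "BlobSpec",
    "BlobSample",
    "PairSample",
    "PhantomSample",
    "generate_blob_image",
    "generate_overlapping_pair",
    "generate_kidney_phantom",
    "generate_training_masks",
]

#: half-peak radius of a unit Gaussian profile, in units of σ_b
_HALF_PEAK = float(np.sqrt(2.0 * np.log(2.0)))

_MAX_PLACEMENT_TRIES = 10_000


@dataclass(frozen=True)
class BlobSpec:
    """Parameters of a synthetic blob image.

    ``min_separation`` multiplies the larger radius of each pair of blobs;
    the default 4.0 keeps blobs well separated (supports disjoint).
    ``n_speckles`` adds small convex distractors (radius ``speckle_radius``)
    that are *not* part of the ground truth — they emulate the high-spatial-
    frequency noise structure that the Hessian map over-detects.
    """

    n_blobs: int = 30
    radius_range: tuple[float, float] = (3.0, 5.0)
    peak_range: tuple[float, float] = (0.8, 1.0)
    min_separation: float = 4.0
    noise_sigma: float = 0.05
    seed: int = 0
    dims: tuple[int, ...] = (128, 128)
    n_speckles: int = 0
    speckle_radius: float = 1.2

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_blobs < 0 or self.n_speckles < 0:
            raise ValueError("counts must be non-negative")
        if len(self.dims) not in (2, 3):
            raise ValueError("dims must be 2D or 3D")


class BlobSample(NamedTuple):
    image: ImageGrid
    dots: DotList
    mask: np.ndarray


class PairSample(NamedTuple):
    image: ImageGrid
    dots: DotList
    mask: np.ndarray


class PhantomSample(NamedTuple):
    image: ImageGrid
    dots: DotList
    mask: np.ndarray
    distractors: DotList


def _coord_grids(dims: tuple[int, ...]) -> list[np.ndarray]:
    return [g.astype(float) for g in np.meshgrid(*map(np.arange, dims), indexing="ij")]


def _add_gaussian(
    canvas: np.ndarray, grids: list[np.ndarray], center: np.ndarray,
    sigma_b: float, peak: float
) -> None:
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    canvas += peak * np.exp(-r2 / (2.0 * sigma_b**2))


def _place_centers(
    rng: np.random.Generator,
    dims: tuple[int, ...],
    n: int,
    radii: np.ndarray,
    sep_factor: float,
    margin_factor: float = 2.0,
) -> np.ndarray:
    """Rejection-sample centers honoring pairwise separation sep_factor*max(r_i,r_j).

    Blobs are placed in descending radius order (large blobs are the
    hardest to fit); each keeps a border margin of ``margin_factor`` times
    its own radius.
    """
    order = np.argsort(-np.asarray(radii))
    placed: dict[int, np.ndarray] = {}
    for i in order:
        lo = np.full(len(dims), margin_factor * radii[i])
        hi = np.asarray(dims, float) - 1.0 - lo
        if np.any(hi <= lo):
            raise ValueError("dims too small for the requested blob radii")
        for _ in range(_MAX_PLACEMENT_TRIES):
            cand = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(cand - c) >= sep_factor * max(radii[i], radii[j])
                for j, c in placed.items()
            ):
                placed[i] = cand
                break
        else:
            raise RuntimeError(
                f"could not place blob {len(placed) + 1}/{n} "
                f"after {_MAX_PLACEMENT_TRIES} tries"
            )
    return np.asarray([placed[i] for i in range(n)]).reshape(n, len(dims))


def generate_blob_image(spec: BlobSpec) -> BlobSample:
    """Sum of Gaussian-profile blobs + optional speckles + Gaussian noise.

    Returns the noisy image, the exact blob centers, and the noise-free
    half-peak support mask (speckles are excluded from both).
    """
    rng_place = np.random.default_rng([spec.seed, 0])
    rng_noise = np.random.default_rng([spec.seed, 1])

    radii = rng_place.uniform(*spec.radius_range, size=spec.n_blobs)
    peaks = rng_place.uniform(*spec.peak_range, size=spec.n_blobs)
    centers = _place_centers(
        rng_place, spec.dims, spec.n_blobs, radii, spec.min_separation
    )

    grids = _coord_grids(spec.dims)
    clean = np.zeros(spec.dims, dtype=float)
    for c, r, p in zip(centers, radii, peaks):
        _add_gaussian(clean, grids, c, r / 2.0, p)
    half_level = 0.5 * (peaks.min() if spec.n_blobs else 1.0)
    mask = clean >= half_level

    image = clean.copy()
    if spec.n_speckles:
        sp_radii = np.full(spec.n_speckles, spec.speckle_radius)
        sp_centers = _place_centers(
            rng_place, spec.dims, spec.n_speckles, sp_radii, 1.0
        )
        for c in sp_centers:
            _add_gaussian(image, grids, c, spec.speckle_radius / 2.0, 0.9)
    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sigma, spec.dims)
    image = np.clip(image, 0.0, 1.0)

    return BlobSample(ImageGrid(image), DotList(centers), mask)


def generate_overlapping_pair(
    radius: float,
    center_distance: float,
    dims: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> PairSample:
    """Two equal Gaussian blobs with overlapping half-peak supports.

    Noise-free by construction; the seed varies pair orientation and
    sub-voxel placement. Requires ``0 < center_distance < 2·radius`` so the
    supports genuinely overlap.
    """
    if not 0.0 < center_distance < 2.0 * radius:
        raise ValueError("center_distance must lie in (0, 2*radius)")
    if len(dims) != 2:
        raise ValueError("overlapping pairs are generated in 2D")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, np.pi)
    jitter = rng.uniform(-0.5, 0.5, size=2)
    mid = np.asarray(dims, float) / 2.0 + jitter
    half = 0.5 * center_distance * np.array([np.sin(theta), np.cos(theta)])
    centers = np.stack([mid - half, mid + half])

    grids = _coord_grids(dims)
    clean = np.zeros(dims, dtype=float)
    for c in centers:
        _add_gaussian(clean, grids, c, radius / 2.0, 1.0)
    mask = clean >= 0.5
    return PairSample(ImageGrid(np.clip(clean, 0.0, 1.0)), DotList(centers), mask)


def generate_kidney_phantom(
    outer_radius: float = 40.0,
    cortex_depth: float = 7.0,
    n_blobs: int = 200,
    seed: int = 0,
    n_distractors: int = 50,
    blob_radius: float = 3.0,
    noise_sigma: float = 0.02,
    dims: tuple[int, int, int] | None = None,
) -> PhantomSample:
    """3D ellipsoidal "kidney" with blobs only in the cortex shell.

    The organ is an ellipsoid of elevated tissue intensity (semi-axes
    ``outer_radius × 0.85·outer_radius × 0.8·outer_radius``). Ground-truth
    blobs are placed where the Euclidean distance to the organ boundary is
    at most ``cortex_depth``; bright distractor speckles are placed strictly
    deeper (the medulla), where no true blob lives.
    """
    if cortex_depth >= outer_radius:
        raise ValueError("cortex_depth must be smaller than outer_radius")
    from scipy import ndimage

    rng_place = np.random.default_rng([seed, 0])
    rng_noise = np.random.default_rng([seed, 1])

    semi = np.array([0.8, 0.85, 1.0]) * outer_radius  # (z, y, x)
    if dims is None:
        dims = tuple(int(2 * s + 13) for s in semi)
    center = (np.asarray(dims, float) - 1.0) / 2.0
    grids = _coord_grids(dims)
    ell = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    organ = ell <= 1.0
    dist = ndimage.distance_transform_edt(organ)

    cortex = organ & (dist <= cortex_depth)
    medulla = organ & (dist > cortex_depth + 2.0)

    sigma_b = blob_radius / 2.0

    def sample_in(region: np.ndarray, n: int, min_sep: float) -> np.ndarray:
        coords = np.argwhere(region)
        if len(coords) == 0:
            raise RuntimeError("empty placement region")
        chosen: list[np.ndarray] = []
        for i in range(n):
            for _ in range(_MAX_PLACEMENT_TRIES):
                cand = coords[rng_place.integers(len(coords))].astype(float)
                cand += rng_place.uniform(-0.5, 0.5, size=3)
                if all(np.linalg.norm(cand - c) >= min_sep for c in chosen):
                    chosen.append(cand)
                    break
            else:
                raise RuntimeError(f"could not place object {i + 1}/{n} in region")
        return np.asarray(chosen).reshape(n, 3)

    blob_centers = sample_in(cortex, n_blobs, 2.2 * blob_radius)
    distractor_centers = (
        sample_in(medulla, n_distractors, 3.0)
        if n_distractors
        else np.empty((0, 3))
    )

    clean_blobs = np.zeros(dims, dtype=float)
    for c in blob_centers:
        _add_gaussian(clean_blobs, grids, c, sigma_b, 0.65)
    mask = clean_blobs >= 0.5 * 0.65

    image = 0.05 + 0.30 * organ.astype(float) + clean_blobs
    for c in distractor_centers:
        _add_gaussian(image, grids, c, 0.8, 0.6)
    if noise_sigma > 0:
        image = image + rng_noise.normal(0.0, noise_sigma, dims)
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(
        ImageGrid(image), DotList(blob_centers), mask, DotList(distractor_centers)
    )


def generate_training_masks(
    n: int,
    dims: tuple[int, int] = (64, 64),
    seed: int = 0,
    n_nuclei_range: tuple[int, int] = (4, 10),
    radius_range: tuple[float, float] = (3.0, 7.0),
) -> list[np.ndarray]:
    """Binary nucleus-style label masks (random filled ellipses) for training."""
    rng = np.random.default_rng(seed)
    grids = _coord_grids(dims)
    masks = []
    for _ in range(n):
        mask = np.zeros(dims, dtype=bool)
        for _ in range(rng.integers(*n_nuclei_range, endpoint=True)):
            c = rng.uniform([5, 5], [dims[0] - 6, dims[1] - 6])
            ax = rng.uniform(*radius_range, size=2)
            theta = rng.uniform(0, np.pi)
            dy, dx = grids[0] - c[0], grids[1] - c[1]
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            mask |= (u / ax[0]) ** 2 + (v / ax[1]) ** 2 <= 1.0
        masks.append(mask)
    return masks
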