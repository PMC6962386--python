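"""Image and annotation I/O and the grid conventions used across the package.

Conventions
-----------
* Arrays are indexed ``(y, x)`` in 2D and ``(z, y, x)`` in 3D, 0-based.
* CSV dot lists on disk are ordered ``x,y[,z]`` (viewer-friendly) and are
  converted to the internal axis order at this boundary.
* Intensities are rescaled to ``[0, 1]`` on load; a constant image rescales
  to all zeros.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ImageGrid",
    "DotList",
    "read_image",
    "read_dots",
    "write_dots",
    "write_labelmap",
    "read_labelmap",
    "write_probability_map",
    "read_probability_map",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".gz"}


@dataclass
class ImageGrid:
    """A 2D or 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity array, ``(y, x)`` or ``(z, y, x)``, finite values only.
    spacing
        Physical size per voxel along each axis in mm, same length as
        ``data.ndim``. Defaults to 1.0 mm isotropic.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = ()
    intensity_range: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"ImageGrid rank must be 2 or 3, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if not self.spacing:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match image rank")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.intensity_range = (float(self.data.min()), float(self.data.max()))

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DotList:
    """Blob-center coordinates in voxel units, axis order matching ImageGrid."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, pts.shape[1] if pts.ndim == 2 else 2)
        if pts.ndim != 2:
            raise ValueError("points must be a (n, rank) array")
        self.points = pts

    @property
    def count(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, shape: tuple[int, ...]) -> None:
        if self.count == 0:
            return
        if self.points.shape[1] != len(shape):
            raise ValueError("dot rank does not match grid rank")
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        if np.any(lo < 0) or np.any(hi > np.asarray(shape) - 1):
            raise ValueError("dot coordinates lie outside the grid bounds")


def _rescale_unit(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def read_image(path: str | os.PathLike, kind: str) -> ImageGrid:
    """Read a 2D (TIFF/PNG) or 3D (NIfTI) image, rescaled to [0, 1].

    ``kind`` is ``"2d"`` or ``"3d"``. Spacing is taken from the NIfTI
    header when present, else 1.0 mm. Raises ``ValueError`` on a rank
    mismatch and ``IOError`` on an unreadable file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if kind not in ("2d", "3d"):
        raise ValueError(f"kind must be '2d' or '3d', got {kind!r}")

    if kind == "2d":
        suffix = path.suffix.lower()
        try:
            if suffix in _TIFF_SUFFIXES:
                import tifffile

                data = np.asarray(tifffile.imread(path))
            else:
                import imageio.v3 as iio

                data = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"could not read image {path}: {exc}") from exc
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> luminance
            data = data[..., :3].mean(axis=-1)
        if data.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {data.shape}")
        spacing = (1.0, 1.0)
    else:
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asarray(img.get_fdata())
        except Exception as exc:
            raise IOError(f"could not read volume {path}: {exc}") from exc
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {data.shape}")
        # NIfTI stores (x, y, z); internal order is (z, y, x).
        data = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in reversed(zooms)) if all(
            z > 0 for z in zooms
        ) else (1.0, 1.0, 1.0)

    if not np.all(np.isfinite(data)):
        raise ValueError(f"image {path} contains non-finite values")
    return ImageGrid(_rescale_unit(data), spacing)


def read_dots(path: str | os.PathLike, grid: ImageGrid | None = None) -> DotList:
    """Read a CSV dot list (columns x,y[,z]) into internal axis order.

    If ``grid`` is given, coordinates are validated against its bounds.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return DotList(np.empty((0, 2)))
    if df.empty:
        return DotList(np.empty((0, df.shape[1] or 2)))
    # tolerate headerless numeric files
    if not all(str(c).lower() in ("x", "y", "z") for c in df.columns):
        df = pd.read_csv(path, header=None)
        pts_xy = df.to_numpy(dtype=float)
    else:
        cols = [c for c in ("x", "y", "z") if c in [str(k).lower() for k in df.columns]]
        lookup = {str(k).lower(): k for k in df.columns}
        pts_xy = df[[lookup[c] for c in cols]].to_numpy(dtype=float)
    dots = DotList(pts_xy[:, ::-1])  # x,y[,z] -> [z,]y,x
    if grid is not None:
        dots.validate_bounds(grid.shape)
    return dots


def write_dots(dots: DotList, path: str | os.PathLike) -> None:
    """Write a dot list as CSV with columns x,y[,z]."""
    import pandas as pd

    rank = dots.points.shape[1] if dots.count else 2
    cols = ["x", "y", "z"][:rank]
    pd.DataFrame(dots.points[:, ::-1], columns=cols).to_csv(path, index=False)


def _write_array(data: np.ndarray, path: Path, spacing: tuple[float, ...]) -> None:
    if data.ndim == 2:
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import nibabel as nib

        affine = np.diag(list(reversed(spacing)) + [1.0])
        nib.save(nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine), str(path))


def write_labelmap(blobs, path: str | os.PathLike) -> None:
    """Write a BlobSet's integer label image (TIFF for 2D, NIfTI for 3D)."""
    path = Path(path)
    labels = np.asarray(blobs.label_image, dtype=np.int32)
    spacing = getattr(blobs, "spacing", None) or (1.0,) * labels.ndim
    try:
        _write_array(labels, path, tuple(spacing))
    except Exception as exc:
        raise IOError(f"could not write label map to {path}: {exc}") from exc


def read_labelmap(path: str | os.PathLike) -> np.ndarray:
    """Read back an integer label image written by :func:`write_labelmap`."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        return np.asarray(tifffile.imread(path)).astype(np.int32)
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).get_fdata())
    return np.rint(np.transpose(data, (2, 1, 0))).astype(np.int32)


def write_probability_map(data: np.ndarray, path: str | os.PathLike) -> None:
    """Persist a probability map as float TIFF (2D) or NIfTI (3D)."""
    data = np.asarray(data, dtype=np.float32)
    _write_array(data, Path(path), (1.0,) * data.ndim)


def read_probability_map(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
    else:
        import nibabel as nib

        data = np.transpose(np.asarray(nib.load(str(path)).get_fdata()), (2, 1, 0))
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return data
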