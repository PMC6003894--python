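"""Volume data model, NIfTI-1 I/O, and grid resampling.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` along world axes ``(x, y, z)``.  The world
position (mm) of the centre of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` — a voxel-centre, 0-based convention.  Only
axis-aligned grids are supported: NIfTI affines must be diagonal (up to a
small tolerance) because the analysis relies on simultaneous PET/MR
acquisition rather than inter-scan registration.

PET volumes carry standardized uptake values (unitless); ADC maps carry the
apparent diffusion coefficient in 1e-6 mm^2/s, the scale on which clinical
scanners report it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "RegionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_grid",
]

MODALITIES = ("PET_SUV", "ADC", "DWI")
MASK_LABELS = ("tumor_VOI", "MTV", "muscle")

_AFFINE_TOL = 1e-6


@dataclass
class ImageVolume:
    """A 3D scalar field on a regular, axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    modality : str
        One of ``PET_SUV``, ``ADC``, ``DWI``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PET_SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive and finite, got {self.spacing}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def same_grid(self, other: "ImageVolume | RegionMask", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol, rtol=0.0)
            and np.allclose(self.origin, other.origin, atol=tol, rtol=0.0)
        )


@dataclass
class RegionMask:
    """A boolean region aligned to a reference grid (tumor VOI, MTV, muscle)."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "tumor_VOI"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not all(s > 0 and np.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive and finite, got {self.spacing}")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; expected one of {MASK_LABELS}")
        if self.label in ("tumor_VOI", "MTV") and not self.mask.any():
            raise ValueError(f"{self.label} mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _grid_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _decode_affine(affine: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > _AFFINE_TOL * max(1.0, np.abs(rot).max()):
        raise ValueError(
            f"{path}: affine is not axis-aligned; oblique/rotated grids are not supported"
        )
    spacing = tuple(float(abs(rot[a, a])) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    return spacing, origin


def read_volume(path, modality: str = "PET_SUV") -> ImageVolume:
    """Read a single 3D NIfTI-1 image into an :class:`ImageVolume`.

    Rejects 4D images and images containing non-finite voxels (the count of
    offending voxels is named in the error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a single 3D scalar image, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s); refusing to load")
    spacing, origin = _decode_affine(img.affine, path)
    return ImageVolume(data=data, spacing=spacing, origin=origin, modality=modality)


def write_volume(volume: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1; ``read_volume`` inverts it."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data, _grid_affine(volume.spacing, volume.origin))
    img.to_filename(str(path))


def read_mask(path, label: str = "tumor_VOI") -> RegionMask:
    """Read a 0/1 NIfTI volume as a :class:`RegionMask` (voxels > 0.5 are in)."""
    vol = read_volume(path, modality="PET_SUV")
    return RegionMask(mask=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin, label=label)


def write_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _grid_affine(mask.spacing, mask.origin)
    )
    img.to_filename(str(path))


def resample_to_grid(
    source: ImageVolume,
    target: "ImageVolume | RegionMask",
    method: str = "trilinear",
) -> tuple[ImageVolume, np.ndarray]:
    """Resample ``source`` onto the grid of ``target``.

    Each output voxel takes the interpolated source value at that voxel's
    world centre.  Voxels whose centre falls outside the source extent are
    flagged out-of-field in the returned boolean validity mask (not filled
    with zeros) so downstream masked statistics are never contaminated by
    padding.

    Returns
    -------
    (resampled, valid) : (ImageVolume, ndarray of bool)
        ``resampled`` lives on the target grid; ``valid[i,j,k]`` is False for
        out-of-field voxels, whose values are extrapolated edge values and
        must not be used.
    """
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"method must be 'trilinear' or 'nearest', got {method!r}")
    if isinstance(target, ImageVolume) and source.same_grid(target):
        out = ImageVolume(
            data=source.data.copy(),
            spacing=source.spacing,
            origin=source.origin,
            modality=source.modality,
        )
        return out, np.ones(source.shape, dtype=bool)

    tgt_shape = target.shape
    # fractional source-index coordinate of each target voxel centre, per axis
    idx_1d = []
    for a in range(3):
        centers = target.origin[a] + target.spacing[a] * np.arange(tgt_shape[a])
        idx_1d.append((centers - source.origin[a]) / source.spacing[a])

    eps = 1e-9
    valid = (
        ((idx_1d[0] >= -eps) & (idx_1d[0] <= source.shape[0] - 1 + eps))[:, None, None]
        & ((idx_1d[1] >= -eps) & (idx_1d[1] <= source.shape[1] - 1 + eps))[None, :, None]
        & ((idx_1d[2] >= -eps) & (idx_1d[2] <= source.shape[2] - 1 + eps))[None, None, :]
    )
    if not valid.any():
        raise ValueError("source and target grids have no overlapping extent")

    coords = np.meshgrid(*idx_1d, indexing="ij")
    order = 1 if method == "trilinear" else 0
    data = ndimage.map_coordinates(
        source.data, np.stack(coords), order=order, mode="nearest"
    )
    out = ImageVolume(
        data=data,
        spacing=target.spacing,
        origin=target.origin,
        modality=source.modality,
    )
    return out, valid
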