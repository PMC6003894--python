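"""Metabolic tumor volume segmentation and global PET / ADC metrics.

The metabolic tumor volume (MTV) is the connected component — 26-neighbour
connectivity in 3D, which avoids fragmenting thin lesion necks on
anisotropic grids — of the superlevel set ``SUV >= f * SUVmax`` that
contains the hottest voxel, where ``SUVmax`` is taken within the supplied
tumor volume of interest and ``f`` defaults to 0.40.  The threshold is
inclusive so the maximum voxel always qualifies.

Global metrics follow standard PET/MR oncology definitions: SUVmean is
computed within the MTV, TLG = MTV x SUVmean, tumor-to-muscle ratios divide
by the mean of a gluteal-muscle reference region, and ADC statistics are
computed within the diffusion-defined tumor VOI after excluding non-positive
ADC voxels (log/ratio safety; the exclusion count is recorded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, RegionMask

__all__ = [
    "GlobalMetrics",
    "segment_mtv",
    "mask_volume_ml",
    "compute_pet_metrics",
    "compute_adc_metrics",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class GlobalMetrics:
    """Per-tumor scalar summary. Ratio fields are None when no muscle mask is given.

    Units: SUV fields unitless; MTV/ADCvol in mL; ADC fields in 1e-6 mm^2/s;
    TLG in mL (SUV-weighted).  TLG is derived at construction from
    MTV x SUVmean, never supplied.
    """

    suv_max: float | None = None
    suv_mean: float | None = None
    suv_tm: float | None = None
    mtv_ml: float | None = None
    adc_min: float | None = None
    adc_mean: float | None = None
    adc_tm: float | None = None
    adc_vol_ml: float | None = None
    n_adc_excluded: int = 0
    tlg: float | None = None

    def __post_init__(self) -> None:
        if self.mtv_ml is not None and self.suv_mean is not None:
            self.tlg = self.mtv_ml * self.suv_mean
        if self.suv_max is not None and self.suv_mean is not None:
            if self.suv_mean > self.suv_max * (1 + 1e-12):
                raise ValueError(
                    f"SUVmean ({self.suv_mean}) exceeds SUVmax ({self.suv_max})"
                )
        if self.adc_min is not None and self.adc_mean is not None:
            if self.adc_min > self.adc_mean * (1 + 1e-12):
                raise ValueError(
                    f"ADCmin ({self.adc_min}) exceeds ADCmean ({self.adc_mean})"
                )
        for name in ("mtv_ml", "adc_vol_ml"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("suv_tm", "adc_tm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @classmethod
    def merge(cls, pet: "GlobalMetrics", adc: "GlobalMetrics") -> "GlobalMetrics":
        """Join PET-side and ADC-side partial metrics into one record."""
        return cls(
            suv_max=pet.suv_max,
            suv_mean=pet.suv_mean,
            suv_tm=pet.suv_tm,
            mtv_ml=pet.mtv_ml,
            adc_min=adc.adc_min,
            adc_mean=adc.adc_mean,
            adc_tm=adc.adc_tm,
            adc_vol_ml=adc.adc_vol_ml,
            n_adc_excluded=adc.n_adc_excluded,
        )

    def as_dict(self) -> dict:
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "suv_tm": self.suv_tm,
            "mtv_ml": self.mtv_ml,
            "tlg": self.tlg,
            "adc_min": self.adc_min,
            "adc_mean": self.adc_mean,
            "adc_tm": self.adc_tm,
            "adc_vol_ml": self.adc_vol_ml,
        }


def _check_aligned(vol: ImageVolume, mask: RegionMask, what: str) -> None:
    if vol.shape != mask.shape:
        raise ValueError(
            f"{what} mask shape {mask.shape} does not match volume shape {vol.shape}"
        )


def segment_mtv(
    pet: ImageVolume,
    seed_region: RegionMask,
    threshold_fraction: float = 0.40,
    *,
    connected: bool = True,
    connectivity: int = 26,
    valid: np.ndarray | None = None,
) -> RegionMask:
    """Threshold segmentation of the metabolic tumor volume.

    ``SUVmax`` is the maximum PET value within ``seed_region`` (restricted to
    in-field voxels when ``valid`` is given).  The returned mask is the
    connected component of ``{SUV >= threshold_fraction * SUVmax}`` containing
    the argmax voxel (ties broken by lowest linear index).  With
    ``connected=False`` the full superlevel set is returned instead.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError(f"threshold_fraction must lie in (0, 1), got {threshold_fraction}")
    _check_aligned(pet, seed_region, "seed")
    if valid is None:
        valid = np.ones(pet.shape, dtype=bool)
    seed_sel = seed_region.mask & valid
    if not seed_sel.any():
        raise ValueError("seed region is empty after out-of-field exclusion")

    seed_vals = np.where(seed_sel, pet.data, -np.inf)
    argmax_flat = int(np.argmax(seed_vals))  # ties -> lowest linear index
    suv_max = float(seed_vals.flat[argmax_flat])
    threshold = threshold_fraction * suv_max
    candidate = (pet.data >= threshold) & valid

    in_field = pet.data[valid]
    if in_field.size and float(np.ptp(in_field)) == 0.0:
        warnings.warn(
            "PET image is constant over the field of view; the 40%-threshold "
            "region is the whole connected in-field volume",
            stacklevel=2,
        )

    if connected:
        struct = _STRUCT_26 if connectivity == 26 else _STRUCT_6
        labels, _ = ndimage.label(candidate, structure=struct)
        comp_id = labels.flat[argmax_flat]
        mask = labels == comp_id
    else:
        mask = candidate
    return RegionMask(mask=mask, spacing=pet.spacing, origin=pet.origin, label="MTV")


def mask_volume_ml(mask: RegionMask) -> float:
    """Region volume in mL: voxel count times voxel volume (mm^3) / 1000."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def compute_pet_metrics(
    pet: ImageVolume,
    tumor_voi: RegionMask,
    mtv_mask: RegionMask,
    muscle: RegionMask | None = None,
    *,
    valid: np.ndarray | None = None,
) -> GlobalMetrics:
    """PET-side global metrics: SUVmax (over the VOI), SUVmean (within the
    MTV), MTV, TLG, and the tumor-to-muscle ratio SUV_T/M."""
    _check_aligned(pet, tumor_voi, "tumor VOI")
    _check_aligned(pet, mtv_mask, "MTV")
    if valid is None:
        valid = np.ones(pet.shape, dtype=bool)

    voi_sel = tumor_voi.mask & valid
    mtv_sel = mtv_mask.mask & valid
    if not voi_sel.any():
        raise ValueError("tumor VOI is empty after out-of-field exclusion")
    if not mtv_sel.any():
        raise ValueError("MTV mask is empty after out-of-field exclusion")

    suv_max = float(pet.data[voi_sel].max())
    suv_mean = float(pet.data[mtv_sel].mean())
    mtv_ml = mask_volume_ml(mtv_mask)

    suv_tm = None
    if muscle is not None:
        _check_aligned(pet, muscle, "muscle")
        mus_sel = muscle.mask & valid
        if mus_sel.any():
            suv_tm = suv_mean / float(pet.data[mus_sel].mean())
        else:
            warnings.warn("muscle mask empty; SUV_T/M not computed", stacklevel=2)
    return GlobalMetrics(suv_max=suv_max, suv_mean=suv_mean, suv_tm=suv_tm, mtv_ml=mtv_ml)


def compute_adc_metrics(
    adc: ImageVolume,
    tumor_voi: RegionMask,
    muscle: RegionMask | None = None,
) -> GlobalMetrics:
    """ADC-side global metrics: ADCmin and ADCmean over retained tumor voxels
    (ADC > 0), ADCvol from the full VOI, and ADC_T/M against muscle."""
    _check_aligned(adc, tumor_voi, "tumor VOI")
    retained = tumor_voi.mask & (adc.data > 0)
    n_excl = int(tumor_voi.n_voxels - retained.sum())
    if not retained.any():
        raise ValueError(
            f"all {tumor_voi.n_voxels} tumor VOI voxels have non-positive ADC"
        )
    vals = adc.data[retained]
    adc_tm = None
    if muscle is not None:
        _check_aligned(adc, muscle, "muscle")
        mus = muscle.mask & (adc.data > 0)
        if mus.any():
            adc_tm = float(vals.mean()) / float(adc.data[mus].mean())
        else:
            warnings.warn("muscle mask empty; ADC_T/M not computed", stacklevel=2)
    return GlobalMetrics(
        adc_min=float(vals.min()),
        adc_mean=float(vals.mean()),
        adc_tm=adc_tm,
        adc_vol_ml=mask_volume_ml(tumor_voi),
        n_adc_excluded=n_excl,
    )
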