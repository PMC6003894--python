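"""Matched per-voxel (SUV, ADC) pairs and the per-tumor linear association.

With the PET volume resampled onto the ADC grid, every tumor-VOI voxel
yields one (SUV, ADC) pair.  The per-tumor biomarker is the Pearson
correlation r of those pairs, with an ordinary least-squares line fitted
with ADC as the response and SUV as the regressor (r is symmetric in the
two, so the biomarker does not depend on the orientation; the slope does,
and its orientation — dADC/dSUV in 1e-6 mm^2/s per SUV unit — is fixed
here and in output headers).  Significance is the classical two-sided
t-test: t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.

Neighbouring voxels are spatially correlated and no adjustment is made for
that, so per-tumor p-values are optimistic about the effective sample size;
see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging import ImageVolume, RegionMask

__all__ = ["VoxelPairSet", "AssociationResult", "extract_pairs", "fit_association"]


@dataclass
class VoxelPairSet:
    """Matched per-voxel samples from one tumor, in VOI scan (C) order."""

    suv: np.ndarray
    adc: np.ndarray
    patient_id: str = ""
    excluded: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=np.float64)
        self.adc = np.asarray(self.adc, dtype=np.float64)
        if self.suv.shape != self.adc.shape or self.suv.ndim != 1:
            raise ValueError("suv and adc must be 1D vectors of equal length")

    @property
    def n(self) -> int:
        return int(self.suv.size)


@dataclass
class AssociationResult:
    """Least-squares / Pearson summary of one association.

    slope and intercept are for the regression of the second variable (ADC)
    on the first (SUV); p is the two-sided t-test p-value on n-2 df.
    """

    r: float
    slope: float
    intercept: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"Pearson r out of [-1, 1]: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p}")


def extract_pairs(
    pet_on_adc_grid: ImageVolume,
    adc: ImageVolume,
    tumor_voi: RegionMask,
    *,
    pet_valid: np.ndarray | None = None,
    patient_id: str = "",
) -> VoxelPairSet:
    """Collect matched (SUV, ADC) pairs for all valid tumor-VOI voxels.

    A voxel contributes a pair when it is inside the VOI, its resampled PET
    value is in-field, and its ADC is strictly positive.  Exclusion counts
    are recorded on the result; fewer than 3 surviving pairs is an error
    naming the responsible filters.
    """
    if pet_on_adc_grid.shape != adc.shape or adc.shape != tumor_voi.shape:
        raise ValueError(
            "PET (resampled), ADC, and VOI must share one grid; shapes are "
            f"{pet_on_adc_grid.shape}, {adc.shape}, {tumor_voi.shape}"
        )
    if not pet_on_adc_grid.same_grid(adc):
        raise ValueError("PET volume is not on the ADC grid; resample it first")
    if pet_valid is None:
        pet_valid = np.ones(adc.shape, dtype=bool)

    voi = tumor_voi.mask
    n_out_of_field = int((voi & ~pet_valid).sum())
    n_nonpos_adc = int((voi & pet_valid & ~(adc.data > 0)).sum())
    keep = voi & pet_valid & (adc.data > 0)
    flat = np.flatnonzero(keep)  # C scan order
    if flat.size < 3:
        raise ValueError(
            f"only {flat.size} voxel pair(s) remain in the VOI "
            f"({tumor_voi.n_voxels} voxels) after excluding {n_out_of_field} "
            f"out-of-field PET voxel(s) and {n_nonpos_adc} non-positive ADC voxel(s)"
        )
    return VoxelPairSet(
        suv=pet_on_adc_grid.data.flat[flat],
        adc=adc.data.flat[flat],
        patient_id=patient_id,
        excluded={"out_of_field": n_out_of_field, "nonpositive_adc": n_nonpos_adc},
    )


def fit_association(pairs: "VoxelPairSet | np.ndarray", y: np.ndarray | None = None) -> AssociationResult:
    """Least squares of ADC on SUV with Pearson r and its two-sided t-test.

    Accepts either a :class:`VoxelPairSet` or two plain vectors ``(x, y)``
    (used by the cohort-level metric correlations).
    """
    if isinstance(pairs, VoxelPairSet):
        x, yv = pairs.suv, pairs.adc
    else:
        if y is None:
            raise TypeError("fit_association(x, y) needs both vectors")
        x = np.asarray(pairs, dtype=np.float64)
        yv = np.asarray(y, dtype=np.float64)
        if x.shape != yv.shape or x.ndim != 1:
            raise ValueError("x and y must be 1D vectors of equal length")
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a fit, got {n}")
    if float(np.ptp(x)) == 0.0 or float(np.ptp(yv)) == 0.0:
        raise ValueError("zero variance in SUV or ADC; Pearson r is undefined")
    res = stats.linregress(x, yv)
    return AssociationResult(
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
        n=n,
    )
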