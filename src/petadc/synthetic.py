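"""Synthetic PET/ADC phantom cohorts with known ground truth.

Each patient is an ellipsoidal tumor phantom rendered on two grids — a PET
grid (default 4.17 x 4.17 x 2.03 mm) and a coarser-in-plane ADC grid
(default 3.4 mm in plane, 5 mm slices) — sharing one world coordinate
frame, so the pipeline's PET-onto-ADC resampling stage is genuinely
exercised.  Within the tumor, voxel SUV and ADC fluctuate around their
tissue means following two smoothed Gaussian random fields mixed as
``w = rho * u + sqrt(1 - rho^2) * v`` to impose a prescribed voxel-level
SUV-ADC correlation ``rho``.  The mixing uses coefficients estimated by
standardizing ``u`` and orthogonalizing ``v`` against ``u`` over the
realized ADC-grid tumor voxels (Gram-Schmidt on samples), so the realized
noise-free correlation equals ``rho`` to machine precision rather than only
in expectation; the truth record stores the realized value as the recovery
target.

The ADC map is not handed to the pipeline directly: diffusion-weighted
signals are synthesized per b-value from the mono-exponential model
``S(b) = S0 * exp(-b * ADC)`` (b in s/mm^2, ADC converted from 1e-6 mm^2/s),
Gaussian noise is added, and the ADC map is refitted by per-voxel
log-linear least squares — emulating the scanner's ADC computation.
b-value schemes cycle through (50, 500, 1000), (50, 500, 800) and
(50, 400, 600).

Cohort-level generation adds clinical covariates (histology, grade,
treatment) matching the composition of a 17-patient cervical-cancer cohort,
per-histology distributions of ``rho`` and target metabolic tumor volume,
optional coupling of ``rho`` to volume, and exponential outcome times whose
hazard is ``lambda0 * exp(beta * 1[rho below the cohort median])`` — a
stronger inverse SUV-ADC coupling carries the worse prognosis.  All outputs
are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .imaging import ImageVolume, RegionMask, resample_to_grid, write_volume, write_mask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "SyntheticCohort",
    "generate_phantom",
    "synthesize_dwi",
    "fit_adc_map",
    "generate_cohort",
    "write_cohort",
    "simulate_survival",
]

B_VALUE_SCHEMES = ((50.0, 500.0, 1000.0), (50.0, 500.0, 800.0), (50.0, 400.0, 600.0))

#: nominal maximum of the standardized tumor SUV field, used to predict the
#: 40%-of-SUVmax iso-surface when sizing the ellipsoid for a target MTV
_NOMINAL_FIELD_MAX = 2.2

_ASPECT = (1.0, 0.8, 0.65)  # tumor semi-axis ratios x:y:z


@dataclass
class PhantomSpec:
    """Geometry, intensity, correlation and acquisition parameters for one phantom.

    Units: mm for lengths, SUV unitless, ADC in 1e-6 mm^2/s, b in s/mm^2.
    ``peak_suv`` is the tumor plateau level; the realized SUVmax exceeds it
    by roughly ``_NOMINAL_FIELD_MAX * suv_sd``.
    """

    patient_id: str = "phantom"
    target_mtv_ml: float = 35.0
    rho: float = -0.35
    peak_suv: float = 10.5
    background_suv: float = 1.0
    muscle_suv: float = 0.8
    tumor_adc: float = 950.0
    muscle_adc: float = 1230.0
    background_adc: float = 1350.0
    suv_sd: float = 1.2
    adc_sd: float = 120.0
    smoothness_mm: float = 6.0
    falloff_k: float = 4.0
    pet_noise_sd: float = 0.3
    dwi_noise_sd: float = 5.0
    s0: float = 1000.0
    b_values: tuple[float, float, float] = B_VALUE_SCHEMES[0]
    pet_spacing: tuple[float, float, float] = (4.17, 4.17, 2.03)
    adc_spacing: tuple[float, float, float] = (3.4, 3.4, 5.0)
    ref_spacing_mm: float = 2.5
    fov_mm: tuple[float, float, float] = (130.0, 130.0, 100.0)
    muscle_semi_axes: tuple[float, float, float] = (12.0, 12.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        for name in ("suv_sd", "adc_sd", "pet_noise_sd", "dwi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pet_spacing", "adc_spacing"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.target_mtv_ml <= 0:
            raise ValueError("target_mtv_ml must be > 0")
        if tuple(self.b_values) not in B_VALUE_SCHEMES:
            raise ValueError(
                f"b_values must be one of {B_VALUE_SCHEMES}, got {self.b_values}"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def threshold_r2(self) -> float:
        """Predicted squared elliptical radius of the 40%-of-SUVmax surface."""
        suvmax_nom = self.peak_suv + _NOMINAL_FIELD_MAX * self.suv_sd
        thr = 0.4 * suvmax_nom
        if thr <= self.background_suv:
            raise ValueError("background SUV exceeds the 40% threshold; phantom invalid")
        return 1.0 + math.log((self.peak_suv - self.background_suv) / (thr - self.background_suv)) / self.falloff_k

    @property
    def semi_axes_mm(self) -> tuple[float, float, float]:
        """Ellipsoid semi-axes sized so the predicted MTV matches the target."""
        v_ell_mm3 = self.target_mtv_ml * 1000.0 / self.threshold_r2 ** 1.5
        s = (v_ell_mm3 * 3.0 / (4.0 * math.pi * _ASPECT[0] * _ASPECT[1] * _ASPECT[2])) ** (1.0 / 3.0)
        return tuple(s * a for a in _ASPECT)  # type: ignore[return-value]


@dataclass
class Phantom:
    """One generated patient: volumes, masks, and the latent truth record."""

    pet: ImageVolume
    adc: ImageVolume
    adc_truth: ImageVolume
    suv_truth: ImageVolume  # noise-free SUV rendered directly on the ADC grid
    tumor_voi: RegionMask
    muscle: RegionMask
    truth: dict
    spec: PhantomSpec


def _centered_grid(fov, spacing, pad_voxels: int = 0):
    shape = tuple(int(math.floor(fov[a] / spacing[a])) + pad_voxels for a in range(3))
    origin = tuple(-(shape[a] - 1) * spacing[a] / 2.0 for a in range(3))
    return shape, origin


def _r2_field(shape, spacing, origin, center, semi_axes) -> np.ndarray:
    axes = [
        ((origin[a] + spacing[a] * np.arange(shape[a]) - center[a]) / semi_axes[a]) ** 2
        for a in range(3)
    ]
    return axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]


def _envelope(r2: np.ndarray, k: float) -> np.ndarray:
    return np.where(r2 <= 1.0, 1.0, np.exp(-k * np.maximum(r2 - 1.0, 0.0)))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one two-grid PET/ADC tumor phantom from its spec.

    Deterministic in ``spec`` (including ``spec.seed``): identical specs give
    bitwise-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    semi = spec.semi_axes_mm
    center = (0.0, 0.0, 0.0)

    # muscle reference sits along +z, clear of the tumor falloff and the FOV edge
    z_m = min(semi[2] * 1.5 + 12.0, spec.fov_mm[2] / 2.0 - spec.muscle_semi_axes[2] - 3.0)
    muscle_center = (0.0, 0.0, z_m)
    if z_m < semi[2] * 1.15 + spec.muscle_semi_axes[2]:
        raise ValueError("tumor too large for the field of view (muscle ROI would overlap)")
    if any(1.15 * semi[a] > spec.fov_mm[a] / 2.0 for a in range(3)):
        raise ValueError("tumor extends beyond the field of view")

    # latent fields on a fine common reference grid covering both image grids
    ref_sp = (spec.ref_spacing_mm,) * 3
    ref_fov = tuple(f + 16.0 for f in spec.fov_mm)
    ref_shape, ref_origin = _centered_grid(ref_fov, ref_sp, pad_voxels=1)
    sigma_vox = [spec.smoothness_mm / s for s in ref_sp]
    u_ref = gaussian_filter(rng.standard_normal(ref_shape), sigma=sigma_vox)
    v_ref = gaussian_filter(rng.standard_normal(ref_shape), sigma=sigma_vox)
    u_img = ImageVolume(u_ref, ref_sp, ref_origin, modality="PET_SUV")
    v_img = ImageVolume(v_ref, ref_sp, ref_origin, modality="PET_SUV")

    adc_shape, adc_origin = _centered_grid(spec.fov_mm, spec.adc_spacing)
    pet_shape, pet_origin = _centered_grid(
        tuple(f + 2.0 * spec.pet_spacing[a] for a, f in enumerate(spec.fov_mm)),
        spec.pet_spacing,
        pad_voxels=1,
    )
    adc_grid = ImageVolume(np.zeros(adc_shape), spec.adc_spacing, adc_origin, modality="ADC")
    pet_grid = ImageVolume(np.zeros(pet_shape), spec.pet_spacing, pet_origin, modality="PET_SUV")

    u_adc, _ = resample_to_grid(u_img, adc_grid)
    v_adc, _ = resample_to_grid(v_img, adc_grid)
    u_pet, _ = resample_to_grid(u_img, pet_grid)
    v_pet, _ = resample_to_grid(v_img, pet_grid)

    r2_adc = _r2_field(adc_shape, spec.adc_spacing, adc_origin, center, semi)
    voi_mask = r2_adc <= 1.0
    if not voi_mask.any():
        raise ValueError("tumor VOI contains no ADC voxels; enlarge target MTV or FOV")

    # standardize u and orthogonalize v against u over the realized VOI voxels,
    # so the mixed field has sample correlation exactly rho with u there
    ua = u_adc.data[voi_mask]
    va = v_adc.data[voi_mask]
    mu_u, sd_u = float(ua.mean()), float(ua.std())
    mu_v, sd_v = float(va.mean()), float(va.std())
    if sd_u == 0.0 or sd_v == 0.0:
        raise ValueError("degenerate latent field (zero variance in VOI)")
    uh_a = (ua - mu_u) / sd_u
    vh_a = (va - mu_v) / sd_v
    c = float((uh_a * vh_a).mean())
    resid_sd = float((vh_a - c * uh_a).std())

    def _w(u_grid: np.ndarray, v_grid: np.ndarray) -> np.ndarray:
        uh = (u_grid - mu_u) / sd_u
        vt = ((v_grid - mu_v) / sd_v - c * uh) / resid_sd
        return spec.rho * uh + math.sqrt(max(1.0 - spec.rho**2, 0.0)) * vt

    def _suv_field(shape, spacing, origin, w_grid):
        r2 = _r2_field(shape, spacing, origin, center, semi)
        env = _envelope(r2, spec.falloff_k)
        suv = spec.background_suv + env * (
            spec.peak_suv - spec.background_suv + spec.suv_sd * w_grid
        )
        mus = _r2_field(shape, spacing, origin, muscle_center, spec.muscle_semi_axes) <= 1.0
        suv[mus] = spec.muscle_suv
        return suv, mus

    def _adc_field(shape, spacing, origin, u_grid):
        r2 = _r2_field(shape, spacing, origin, center, semi)
        env = _envelope(r2, spec.falloff_k)
        uh = (u_grid - mu_u) / sd_u  # standardized over VOI voxels
        adc = spec.background_adc + env * (
            spec.tumor_adc - spec.background_adc + spec.adc_sd * uh
        )
        mus = _r2_field(shape, spacing, origin, muscle_center, spec.muscle_semi_axes) <= 1.0
        adc[mus] = spec.muscle_adc
        return np.maximum(adc, 1.0), mus

    suv_nf_pet, _ = _suv_field(pet_shape, spec.pet_spacing, pet_origin, _w(u_pet.data, v_pet.data))
    suv_nf_adc, _ = _suv_field(adc_shape, spec.adc_spacing, adc_origin, _w(u_adc.data, v_adc.data))
    adc_nf, muscle_mask = _adc_field(adc_shape, spec.adc_spacing, adc_origin, u_adc.data)

    pet_data = np.maximum(suv_nf_pet + rng.normal(0.0, spec.pet_noise_sd, pet_shape), 0.0)
    pet = ImageVolume(pet_data, spec.pet_spacing, pet_origin, modality="PET_SUV")
    adc_truth = ImageVolume(adc_nf, spec.adc_spacing, adc_origin, modality="ADC")

    dwis = synthesize_dwi(adc_truth, spec.s0, spec.b_values, spec.dwi_noise_sd, rng=rng)
    adc_fit, adc_valid = fit_adc_map(dwis, spec.b_values)
    adc_fit.data[~adc_valid] = 0.0  # flagged voxels excluded by the ADC > 0 rule

    tumor_voi = RegionMask(voi_mask, spec.adc_spacing, adc_origin, label="tumor_VOI")
    muscle = RegionMask(muscle_mask, spec.adc_spacing, adc_origin, label="muscle")

    nf_s = suv_nf_adc[voi_mask]
    nf_a = adc_nf[voi_mask]
    r_realized = float(np.corrcoef(nf_s, nf_a)[0, 1])
    truth = {
        "patient_id": spec.patient_id,
        "rho_requested": spec.rho,
        "r_realized": r_realized,
        "voi_ml": tumor_voi.n_voxels * tumor_voi.voxel_volume_mm3 / 1000.0,
        "n_voi_voxels": tumor_voi.n_voxels,
        "target_mtv_ml": spec.target_mtv_ml,
        "semi_axes_mm": semi,
    }
    return Phantom(
        pet=pet,
        adc=adc_fit,
        adc_truth=adc_truth,
        suv_truth=ImageVolume(suv_nf_adc, spec.adc_spacing, adc_origin, modality="PET_SUV"),
        tumor_voi=tumor_voi,
        muscle=muscle,
        truth=truth,
        spec=spec,
    )


def synthesize_dwi(
    adc_truth: ImageVolume,
    s0: float,
    b_values,
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
) -> list[ImageVolume]:
    """Mono-exponential DWI synthesis: S(b) = S0 exp(-b * ADC) plus Gaussian
    noise, clipped at zero.  ``adc_truth`` is in 1e-6 mm^2/s, b in s/mm^2."""
    if s0 <= 0:
        raise ValueError(f"S0 must be > 0, got {s0}")
    if (adc_truth.data < 0).any():
        raise ValueError("adc_truth must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    adc_phys = adc_truth.data * 1e-6  # mm^2/s
    out = []
    for b in b_values:
        signal = s0 * np.exp(-float(b) * adc_phys)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, signal.shape)
        out.append(
            ImageVolume(
                np.maximum(signal, 0.0),
                adc_truth.spacing,
                adc_truth.origin,
                modality="DWI",
            )
        )
    return out


def fit_adc_map(dwis: list[ImageVolume], b_values) -> tuple[ImageVolume, np.ndarray]:
    """Per-voxel log-linear least-squares ADC fit over the b-value scheme.

    Returns the fitted ADC map (1e-6 mm^2/s) and a validity mask; voxels with
    any non-positive signal are flagged invalid (their value is set to 0).
    """
    b = np.asarray(b_values, dtype=np.float64)
    if b.size < 2:
        raise ValueError("need at least 2 b-values for an ADC fit")
    if len(dwis) != b.size:
        raise ValueError(f"{len(dwis)} DWI volumes but {b.size} b-values")
    ref = dwis[0]
    for d in dwis[1:]:
        if not ref.same_grid(d):
            raise ValueError("DWI volumes must share one grid")
    stack = np.stack([d.data for d in dwis])  # (nb, nx, ny, nz)
    valid = (stack > 0).all(axis=0)
    if not valid.any():
        raise ValueError("no voxel has positive signal at every b-value")
    logs = np.zeros_like(stack)
    np.log(stack, out=logs, where=stack > 0)
    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = np.tensordot(bc, logs - logs.mean(axis=0), axes=(0, 0)) / denom
    adc = -slope * 1e6
    adc[~valid] = 0.0
    return (
        ImageVolume(adc, ref.spacing, ref.origin, modality="ADC"),
        valid,
    )


# ---------------------------------------------------------------------------
# cohort generation


#: per-histology grade composition (cycled): mirrors the cohort's overlap of
#: histology and differentiation (most SCCAs poorly differentiated, most
#: AdenoCAs well/moderately differentiated)
_GRADE_PATTERNS = {
    "SCCA": ("poor", "poor", "poor", "poor", "poor", "poor", "poor", "moderate", "well"),
    "AdenoCA": ("well", "moderate", "poor", "well", "moderate", "poor"),
    "small_cell": ("poor",),
    "adenosquamous": ("poor",),
}


def _default_histology_counts() -> dict:
    return {"SCCA": 9, "AdenoCA": 6, "small_cell": 1, "adenosquamous": 1}


def _default_rho_mean() -> dict:
    return {"SCCA": -0.35, "AdenoCA": -0.068, "small_cell": -0.20, "adenosquamous": -0.20}


def _default_rho_sd() -> dict:
    return {"SCCA": 0.10, "AdenoCA": 0.25, "small_cell": 0.15, "adenosquamous": 0.15}


def _default_mtv_mean() -> dict:
    return {"SCCA": 41.1, "AdenoCA": 24.7, "small_cell": 30.0, "adenosquamous": 30.0}


@dataclass
class CohortSpec:
    """Full declarative description of a synthetic cohort.

    Hazards are per month; ``*_log_hr`` is the log hazard ratio attached to
    the high-risk group (voxel correlation below the cohort median, i.e. the
    stronger inverse SUV-ADC coupling).  ``imaging=False`` skips phantom
    rendering and produces only the clinical and truth tables.
    """

    n: int = 17
    histology_counts: dict = field(default_factory=_default_histology_counts)
    rho_mean: dict = field(default_factory=_default_rho_mean)
    rho_sd: dict = field(default_factory=_default_rho_sd)
    mtv_mean_ml: dict = field(default_factory=_default_mtv_mean)
    mtv_log_sd: float = 0.35
    couple_rho_to_mtv: bool = False
    rho_mtv_coupling: float = -0.5
    dfs_baseline_hazard: float = 0.0055
    dfs_log_hr: float = math.log(3.0)
    os_baseline_hazard: float = 0.0028
    os_log_hr: float = math.log(2.0)
    censor_horizon_months: float = 48.0
    surgery_fraction: float = 3.0 / 17.0
    imaging: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.histology_counts.values()) != self.n:
            raise ValueError(
                f"histology mix {self.histology_counts} does not sum to n = {self.n}"
            )
        if self.dfs_baseline_hazard <= 0 or self.os_baseline_hazard <= 0:
            raise ValueError("baseline hazards must be > 0")
        if not 0 < self.censor_horizon_months:
            raise ValueError("censor horizon must be > 0")
        if not -1.0 <= self.rho_mtv_coupling <= 1.0:
            raise ValueError("rho_mtv_coupling must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    truth: pd.DataFrame
    phantoms: list[Phantom] | None
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one full synthetic cohort (clinical table, truth table, and —
    unless ``spec.imaging`` is off — one phantom per patient)."""
    rng = np.random.default_rng(spec.seed)

    histologies: list[str] = []
    grades: list[str] = []
    for hist, count in spec.histology_counts.items():
        pattern = _GRADE_PATTERNS.get(hist, ("poor",))
        for k in range(count):
            histologies.append(hist)
            grades.append(pattern[k % len(pattern)])
    n = spec.n
    ids = [f"P{i + 1:03d}" for i in range(n)]

    n_surgery = int(round(spec.surgery_fraction * n))
    treatment = ["chemoradiation"] * n
    for i in range(n - n_surgery, n):
        treatment[i] = "surgery"

    # target volumes (lognormal around per-histology means, clipped to a
    # range the field of view accommodates)
    mtv = np.array(
        [
            float(
                np.clip(
                    spec.mtv_mean_ml.get(h, 30.0)
                    * math.exp(rng.normal(-0.5 * spec.mtv_log_sd**2, spec.mtv_log_sd)),
                    8.0,
                    80.0,
                )
            )
            for h in histologies
        ]
    )

    # voxel-level correlation targets, optionally coupled to tumor volume
    log_mtv = np.log(mtv)
    z_mtv = (log_mtv - log_mtv.mean()) / (log_mtv.std() if log_mtv.std() > 0 else 1.0)
    eps = rng.standard_normal(n)
    cpl = spec.rho_mtv_coupling if spec.couple_rho_to_mtv else 0.0
    rho = np.array(
        [
            float(
                np.clip(
                    spec.rho_mean.get(h, -0.2)
                    + spec.rho_sd.get(h, 0.15)
                    * (cpl * z_mtv[i] + math.sqrt(1.0 - cpl**2) * eps[i]),
                    -0.95,
                    0.95,
                )
            )
            for i, h in enumerate(histologies)
        ]
    )

    # outcome model: stronger inverse coupling (rho below the median) raises the hazard
    high_risk = rho <= np.median(rho)
    lam_dfs = spec.dfs_baseline_hazard * np.exp(spec.dfs_log_hr * high_risk)
    lam_os = spec.os_baseline_hazard * np.exp(spec.os_log_hr * high_risk)
    t_dfs = rng.exponential(1.0 / lam_dfs)
    t_os = rng.exponential(1.0 / lam_os)
    censor = rng.uniform(0.0, spec.censor_horizon_months, size=n)
    dfs_time = np.minimum(t_dfs, censor)
    dfs_event = t_dfs <= censor
    os_time = np.minimum(t_os, censor)
    os_event = t_os <= censor

    clinical = pd.DataFrame(
        {
            "id": ids,
            "histology": histologies,
            "grade": grades,
            "treatment": treatment,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "os_time": os_time,
            "os_event": os_event,
        }
    )

    phantoms: list[Phantom] | None = None
    r_realized = np.full(n, np.nan)
    voi_ml = np.full(n, np.nan)
    schemes = [B_VALUE_SCHEMES[i % len(B_VALUE_SCHEMES)] for i in range(n)]
    seeds = rng.integers(0, 2**31 - 1, size=n)
    if spec.imaging:
        phantoms = []
        for i in range(n):
            ph = generate_phantom(
                PhantomSpec(
                    patient_id=ids[i],
                    target_mtv_ml=float(mtv[i]),
                    rho=float(rho[i]),
                    b_values=schemes[i],
                    seed=int(seeds[i]),
                )
            )
            phantoms.append(ph)
            r_realized[i] = ph.truth["r_realized"]
            voi_ml[i] = ph.truth["voi_ml"]

    truth = pd.DataFrame(
        {
            "id": ids,
            "histology": histologies,
            "grade": grades,
            "rho_requested": rho,
            "r_realized": r_realized,
            "target_mtv_ml": mtv,
            "voi_ml": voi_ml,
            "high_risk": high_risk,
            "dfs_hazard": lam_dfs,
            "os_hazard": lam_os,
            "b_scheme": ["-".join(str(int(b)) for b in s) for s in schemes],
            "phantom_seed": seeds,
        }
    )
    return SyntheticCohort(clinical=clinical, truth=truth, phantoms=phantoms, spec=spec)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort to disk: per-patient NIfTI volumes/masks plus
    clinical.csv and truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.truth.drop(columns=["phantom_seed"]).to_csv(outdir / "truth.csv", index=False)
    if cohort.phantoms is None:
        return
    for ph in cohort.phantoms:
        pid = ph.spec.patient_id
        write_volume(ph.pet, outdir / f"{pid}_pet.nii.gz")
        write_volume(ph.adc, outdir / f"{pid}_adc.nii.gz")
        write_mask(ph.tumor_voi, outdir / f"{pid}_voi.nii.gz")
        write_mask(ph.muscle, outdir / f"{pid}_muscle.nii.gz")


def simulate_survival(
    n: int,
    hazard_ratio: float,
    baseline_hazard: float = 0.05,
    censor_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two balanced groups with exponential event times, group hazard
    ``baseline * HR``, and independent exponential censoring tuned to leave
    roughly ``censor_fraction`` of subjects censored.

    Returns (times, events, group indicator).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValueError("hazard ratio and baseline hazard must be > 0")
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError("censor_fraction must lie in [0, 1)")
    x = np.zeros(n)
    x[n // 2 :] = 1.0
    lam = baseline_hazard * hazard_ratio**x
    t_event = rng.exponential(1.0 / lam)
    if censor_fraction > 0:
        mu = censor_fraction / (1.0 - censor_fraction) * float(lam.mean())
        t_cens = rng.exponential(1.0 / mu, size=n)
    else:
        t_cens = np.full(n, np.inf)
    times = np.minimum(t_event, t_cens)
    events = t_event <= t_cens
    return times, events, x
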