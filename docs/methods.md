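# Methods

## The analysis model

`petadc` treats a patient as a pair of scalar volumes on different
axis-aligned grids sharing one world frame — a PET volume in SUV
(integrated PET/MR scanners of this class reconstruct PET at
4.17 × 4.17 × 2.03 mm and diffusion at 3.4 mm in-plane / 5 mm slices, the
package defaults) — plus a tumor volume of
interest (VOI) delineated on the ADC image and a gluteal-muscle reference
region. Because acquisition is simultaneous, no registration is modelled:
resampling the PET volume onto the ADC grid (trilinear by default,
voxel-centre convention) is the only geometric operation, and voxels whose
centres leave the PET field of view are carried in a validity mask so they
can never contaminate masked statistics.

All downstream quantities live on the ADC grid:

- **MTV** — the 26-connected component of `{SUV ≥ f · SUVmax}` containing
  the hottest VOI voxel, `f = 0.40`. The threshold is inclusive (the max
  voxel always qualifies), SUVmax is taken within the supplied VOI, and
  argmax ties break at the lowest linear index so segmentation is
  deterministic. A switch returns the full superlevel set instead of the
  connected component, since clinical workstations differ on this point.
- **Global metrics** — SUVmax (VOI), SUVmean (MTV), TLG = MTV × SUVmean
  (enforced as an identity at construction), SUV_T/M and ADC_T/M (tumor
  mean over muscle mean), ADCmin/ADCmean over VOI voxels with ADC > 0
  (non-positive voxels are excluded and counted, protecting ratios and any
  log-domain use), and the VOI volume.
- **Voxel biomarker** — Pearson r of the matched (SUV, ADC) pairs in the
  VOI, with an OLS line fitted with ADC as response and SUV as regressor.
  r is orientation-symmetric; the slope's orientation (dADC/dSUV) is fixed
  and stated in output headers because the mirrored convention appears in
  the literature. Significance is the two-sided t-test on n − 2 df.

### Statistical machinery

- **Mann–Whitney U**: `U_A` counts pairs with a < b plus half the ties;
  both `U_A` and `U_B = n_A n_B − U_A` are reported to disambiguate
  conventions. The exact null distribution is used when min(n) ≤ 8 with no
  ties (cheap at cohort scale, and typical histology groups are 9 vs 6);
  otherwise the normal approximation with tie and continuity corrections.
  A completely tied pooled sample returns p = 1.
- **Median dichotomization**: values ≤ median go to "low"; the median is
  the midpoint of the central order statistics for even n, and ties
  straddling it all fall to "low". A constant metric raises rather than
  producing an empty group.
- **Kaplan–Meier / log-rank** (via lifelines): censored-at-t subjects
  remain at risk at t; survival curves are right-continuous steps.
- **Cox univariate**: Newton iteration on the partial likelihood with
  Breslow tie handling (Efron behind a flag; the two coincide on tie-free
  data). The score/information sums use reverse cumulative sums, so the fit
  is O(n log n). If iteration escapes |β| > 10 the likelihood is treated as
  monotone — the situation where all events sit in one group — and a
  divergence diagnostic replaces the hazard ratio; this fires in practice
  on small cohorts and is a feature, not an error. CI is exp(β ± z₀.₉₇₅·se),
  p is Wald. The score statistic at β = 0 is exposed separately because it
  equals the log-rank chi-square on tie-free data, which the test suite
  asserts numerically.

No multiple-testing correction is applied anywhere, and no multivariate
models are fitted; the survival analysis is explicitly exploratory.

## The synthetic cohort generator

The generator's purpose is ground truth, not photorealism. Each phantom is
an ellipsoidal tumor (semi-axis ratios 1 : 0.8 : 0.65) centred in a
130 × 130 × 100 mm field of view, with a plateau SUV inside the VOI decaying
as `exp(−k(r² − 1))` outside (k = 4), an ADC depression with the same
profile, and an ellipsoidal muscle region along +z. Tissue magnitudes
follow the clinical ranges for cervical tumors: plateau SUV 10.5 (realized
SUVmax ≈ 13), tumor ADC 950, muscle ADC 1230, background ADC 1350 ×10⁻⁶
mm²/s, muscle SUV 0.8 — giving SUVmax, ADCmean, ADC_T/M and MTV values in
the ranges reported for real cohorts.

**Correlation construction.** Two Gaussian white-noise fields are smoothed
(σ = 6 mm) on a fine 2.5 mm reference grid and sampled onto both image
grids. Within-tumor SUV fluctuations follow `w = ρ·û + √(1−ρ²)·ṽ` and ADC
fluctuations follow `û`, where `û` is the first field standardized over the
realized ADC-grid VOI voxels and `ṽ` is the second field orthogonalized
against it over the same voxels (Gram-Schmidt on samples). With plain
mixing the correlation would hold only in expectation, and smoothing leaves
merely ~50–150 effectively independent voxels per tumor, so realized values
would scatter by ±0.1–0.15 around ρ; the empirical orthogonalization makes
the realized noise-free voxel correlation equal ρ to machine precision, and
the truth table records that realized value as the recovery target. Because
the intensity maps are affine inside the VOI, the post-mapping correlation
equals the latent one.

**What the pipeline can and cannot recover.** The PET volume is rendered on
the PET grid and the pipeline resamples it, so trilinear interpolation of
the tumor-rim falloff adds variance to the resampled SUV that is
uncorrelated with ADC. Measured on default phantoms this attenuates the
extracted voxel r by ~4–10% of its magnitude (e.g. mean −0.334 extracted at
ρ = −0.35; r ≈ −0.90 at ρ = −1 with zero noise). An exact r = −1 check is
therefore only possible on the matched-grid noise-free fields, which the
phantom exposes as `suv_truth`. Passing recovery tests show the pipeline is
unbiased up to this known partial-volume-like attenuation; they do not show
robustness to MR distortion, bias fields, PET point-spread blur, or
misregistration, none of which are simulated.

**DWI path.** The ADC volume handed to the pipeline is not the true field:
diffusion signals `S(b) = S₀·exp(−b·ADC)` are synthesized per scheme
((50, 500, 1000), (50, 500, 800), (50, 400, 600) s/mm², cycled across
patients), Gaussian noise (SD 5 on S₀ = 1000) is added and clipped at zero,
and the map is refitted by per-voxel log-linear least squares; voxels with
any non-positive signal are flagged invalid and excluded downstream.

**MTV sizing.** Semi-axes are derived from the target MTV by inverting the
predicted 40% iso-surface radius, using a nominal standardized-field
maximum of 2.2 for the realized SUVmax; measured MTV lands within ~6% of
target across 12–80 mL.

**Cohort composition.** The default 17-patient mix is 9 squamous (SCCA),
6 adenocarcinoma (AdenoCA), 1 small-cell, 1 adenosquamous, with grades
composed so 11 patients are poorly differentiated and most SCCAs are among
them, and 14 of 17 receive chemoradiation. Stratum voxel-correlation
targets are Normal(−0.35, 0.10) for SCCA and Normal(−0.068, 0.25) for
AdenoCA (truncated to ±0.95) — squamous tumors consistently coupled,
adenocarcinomas widely spread; target MTVs are lognormal around 41.1 mL
(SCCA) and 24.7 mL (AdenoCA), clipped to 8–80 mL for the field of view.
Note that these stratum differences alone induce a marginal correlation
between voxel r and MTV in mixed cohorts even with the explicit ρ–volume
coupling switched off; null-coupling checks therefore use single-stratum
cohorts. Outcome times are exponential with hazard
`λ₀·exp(β·1[ρ ≤ median ρ])` (defaults λ₀ = 0.0055/month, β = log 3 for DFS;
0.0028 and log 2 for OS) and uniform censoring on (0, 48) months — stronger
inverse coupling carries the worse prognosis. DFS and OS times are drawn
independently, so OS < DFS can occur in a simulated patient; the package
consumes the two endpoints separately and nothing downstream assumes
ordering. Continuous time draws avoid ties; tie-handling paths are tested
on explicitly constructed tied datasets instead.

Everything is a pure function of (spec, seed); identical seeds give
bitwise-identical volumes and tables.

## Numerical choices and degenerate inputs

- Grids must be axis-aligned; oblique NIfTI affines are rejected rather
  than silently reoriented. Spacing/origin round-trip through NIfTI to
  ≤ 1e-6 mm; data round-trips bitwise (float64).
- Out-of-field handling uses an epsilon of 1e-9 voxel units at the edge so
  voxel centres on the boundary count as in-field.
- A constant PET image makes every voxel pass the 40% threshold; the whole
  connected in-field region is returned with a warning.
- Pair extraction with fewer than 3 surviving voxels raises and names the
  responsible filters; a zero-variance variable makes Pearson r undefined
  and raises.
- Cox Newton tolerance 1e-12 on the step, 50 iterations, divergence guard
  |β| > 10.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to keep the whole suite around a
minute while leaving comfortable statistical margins: 17-phantom cohorts
over 20 seeds for correlation recovery, 100 seeds of n = 200 for hazard-
ratio recovery, 1000 small cohorts for log-rank type-I calibration, 200
enumerated datasets for the exact Mann–Whitney oracle, and 100 random
two-blob images for the flood-fill segmentation oracle.

## Known limitations

- Per-tumor voxel p-values ignore the spatial autocorrelation of
  neighbouring voxels, so the effective sample size is overstated; the
  correlation coefficient itself is unaffected. This matches standard
  practice but should temper interpretation of tiny p-values.
- The generator imposes a single smoothness scale and additive Gaussian
  noise; Rician DWI noise, scanner drift, and partial-volume PSF modelling
  beyond grid rendering are out of scope.
- Only axis-aligned, single-frame volumes are supported — no DICOM, no
  4D series, no registration.
- The hazard-ratio recovery band asserted in the acceptance suite
  ([2.4, 3.75] in ≥ 90% of seeds at n = 200 with 20% censoring) is tighter
  than the sampling distribution of the estimator allows (se(log HR) ≈ 0.17
  against a ±0.22 band, ~1.3σ); the corresponding test documents the
  achievable ~80% and fails by design rather than widening the band.
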