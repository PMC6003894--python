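# petadc

Voxel-matched analysis of paired [¹⁸F]FDG-PET and MR diffusion imaging of
tumors, with a synthetic phantom cohort generator that provides known ground
truth for every stage.

Simultaneous PET/MR acquisition makes it possible to compare the
standardized uptake value (SUV) and the apparent diffusion coefficient
(ADC, in 10⁻⁶ mm²/s) of the *same* tumor voxel — glucose metabolism against
cellularity. In cervical cancer, squamous cell carcinomas tend to show a
consistent inverse voxel-level SUV–ADC correlation while adenocarcinomas
often do not, and the strength of that per-tumor correlation is a candidate
prognostic biomarker for disease-free survival. `petadc` implements that
whole analysis as a tested library for imaging scientists: volume handling,
segmentation, metric extraction, the voxel-level biomarker, cohort
statistics, and survival stratification.

## What it computes

- **imaging**: NIfTI-1 volume/mask I/O on axis-aligned grids; trilinear (or
  nearest-neighbour) resampling of the PET volume onto the ADC voxel grid,
  with out-of-field voxels tracked in a validity mask rather than zero-filled.
- **metrics**: metabolic tumor volume (MTV) as the 26-connected component of
  `SUV ≥ 0.4 · SUVmax` containing the hottest VOI voxel; SUVmax; SUVmean
  (within the MTV); total lesion glycolysis TLG = MTV × SUVmean; tumor-to-
  muscle ratios SUV_T/M and ADC_T/M; ADCmin, ADCmean, ADC volume.
- **voxelwise**: matched per-voxel (SUV, ADC) pairs inside the tumor VOI and
  the per-tumor least-squares fit — Pearson r, slope dADC/dSUV, intercept,
  and the two-sided t-test `t = r·√((n−2)/(1−r²))` on n−2 df.
- **cohort**: cross-patient Pearson correlations between global metrics,
  two-sided Mann–Whitney U group comparisons (exact null when min(n) ≤ 8 and
  tie-free, otherwise the tie- and continuity-corrected normal
  approximation), the voxel-r–vs–MTV relationship, and cohort composition
  summaries. No multiple-testing correction is applied.
- **survival**: median dichotomization of imaging metrics, Kaplan–Meier
  product-limit curves, the two-group log-rank test, and univariate Cox
  proportional hazards (Newton on the partial likelihood, Breslow ties,
  Wald 95% CI, with a monotone-likelihood divergence diagnostic).
- **synthetic**: two-grid tumor phantoms with a *prescribed* voxel-level
  SUV–ADC correlation ρ (realized exactly on the noise-free fields), DWI
  synthesis `S(b) = S₀·e^(−b·ADC)` over the clinical b-value schemes with a
  per-voxel log-linear ADC refit, and full cohorts with clinical covariates
  and outcome times whose hazard depends on the biomarker.

## Worked example

```python
import petadc as pa

cohort = pa.generate_cohort(pa.CohortSpec(seed=1))   # 17 synthetic patients
table = pa.analyze_cohort(cohort)                    # resample -> segment -> metrics -> voxel fit

print(table[["id", "histology", "suv_max", "adc_mean", "mtv_ml", "voxel_r"]].head(3))
#   id histology  suv_max  adc_mean  mtv_ml  voxel_r
# P001      SCCA   12.611   950.568  44.333   -0.319
# P002      SCCA   13.233   950.309  53.234   -0.418
# P003      SCCA   13.003   951.426  43.292   -0.370

pa.metric_correlation(table, "suv_max", "adc_mean")
# r = -0.363, p = 0.152        (global metrics are inversely related)

pa.group_compare(table, "voxel_r", {"histology": "SCCA"}, {"histology": "AdenoCA"})
# U_A = 52.0, p = 0.002 (exact) (SCCAs carry the stronger inverse voxel coupling)

pa.correlation_vs_volume(table)
# r = -0.653, p = 0.0045       (larger tumors -> stronger inverse correlation)

pa.survival_table(table, ["voxel_r", "suv_max", "adc_mean"])
#    metric     hr  ci_low  ci_high  cox_p  logrank_p
#   voxel_r    NaN     NaN      NaN    NaN      0.069   <- monotone likelihood:
#   suv_max  1.823   0.165   20.199  0.625      0.619      all events fell in one
#  adc_mean  0.386   0.033    4.572  0.450      0.436      group; HR withheld
```

The per-patient `voxel_r` values average −0.388 in the squamous stratum and
−0.039 in the adenocarcinoma stratum for this seed, mirroring the generator's
stratum targets; the survival table's `NaN` row shows the divergence
diagnostic — at 17 patients a median split can put every event in one group,
where a finite hazard ratio would be spurious.

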