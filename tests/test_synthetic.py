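import numpy as np
import pytest

from petadc import (
    CohortSpec,
    ImageVolume,
    PhantomSpec,
    analyze_patient,
    extract_pairs,
    fit_adc_map,
    fit_association,
    generate_cohort,
    generate_phantom,
    synthesize_dwi,
    write_cohort,
)
from petadc.synthetic import B_VALUE_SCHEMES


class TestPhantom:
    def test_same_seed_bitwise_identical(self):
        a = generate_phantom(PhantomSpec(seed=42))
        b = generate_phantom(PhantomSpec(seed=42))
        np.testing.assert_array_equal(a.pet.data, b.pet.data)
        np.testing.assert_array_equal(a.adc.data, b.adc.data)
        assert a.truth == b.truth
        c = generate_phantom(PhantomSpec(seed=43))
        assert not np.array_equal(a.pet.data, c.pet.data)

    @pytest.mark.parametrize("rho", [-0.8, -0.35, 0.0, 0.5])
    def test_realized_correlation_equals_requested(self, rho):
        ph = generate_phantom(PhantomSpec(seed=5, rho=rho, target_mtv_ml=60.0))
        assert ph.truth["n_voi_voxels"] >= 500
        assert ph.truth["r_realized"] == pytest.approx(rho, abs=1e-9)

    def test_perfect_anticorrelation_on_matched_grids(self):
        # with rho = -1 and zero noise the noise-free SUV field on the ADC
        # grid is an exact affine function of ADC inside the VOI
        ph = generate_phantom(PhantomSpec(seed=2, rho=-1.0, pet_noise_sd=0.0, dwi_noise_sd=0.0))
        pairs = extract_pairs(ph.suv_truth, ph.adc_truth, ph.tumor_voi)
        assert fit_association(pairs).r == pytest.approx(-1.0, abs=1e-6)

    def test_resampling_attenuates_but_preserves_anticorrelation(self):
        # the full pipeline resamples the PET-grid rendering; tumor-rim
        # interpolation attenuates |r| but the association stays strong
        ph = generate_phantom(PhantomSpec(seed=2, rho=-1.0, pet_noise_sd=0.0, dwi_noise_sd=0.0))
        res = analyze_patient(ph.pet, ph.adc, ph.tumor_voi, ph.muscle)
        assert res.association.r < -0.85

    def test_null_correlation_unbiased(self):
        rs = []
        for seed in range(30):
            ph = generate_phantom(PhantomSpec(seed=seed, rho=0.0, target_mtv_ml=60.0))
            rs.append(analyze_patient(ph.pet, ph.adc, ph.tumor_voi, ph.muscle).association.r)
        assert abs(float(np.mean(rs))) < 0.05

    def test_mtv_calibrated_to_target(self, default_phantom):
        res = analyze_patient(
            default_phantom.pet,
            default_phantom.adc,
            default_phantom.tumor_voi,
            default_phantom.muscle,
        )
        target = default_phantom.spec.target_mtv_ml
        assert abs(res.metrics.mtv_ml - target) / target < 0.10

    def test_metric_magnitudes_plausible(self, default_phantom):
        res = analyze_patient(
            default_phantom.pet,
            default_phantom.adc,
            default_phantom.tumor_voi,
            default_phantom.muscle,
        )
        gm = res.metrics
        assert 8.0 < gm.suv_max < 18.0
        assert 700.0 < gm.adc_mean < 1200.0
        assert 0.5 < gm.adc_tm < 1.0
        assert gm.suv_mean <= gm.suv_max
        assert gm.adc_min <= gm.adc_mean

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            PhantomSpec(rho=1.5)
        with pytest.raises(ValueError, match="b_values"):
            PhantomSpec(b_values=(0.0, 100.0, 200.0))
        with pytest.raises(ValueError, match="field of view"):
            generate_phantom(PhantomSpec(target_mtv_ml=400.0))


class TestDWI:
    def test_monoexponential_closed_form(self):
        adc = ImageVolume(np.full((4, 4, 4), 1000.0), (3.4, 3.4, 5.0), modality="ADC")
        dwis = synthesize_dwi(adc, 1000.0, (0.0, 1000.0), noise_sd=0.0)
        assert dwis[0].data[0, 0, 0] == pytest.approx(1000.0)  # b = 0 -> S0
        assert dwis[1].data[0, 0, 0] == pytest.approx(1000.0 * np.exp(-1.0), rel=1e-12)

    def test_two_point_fit_closed_form(self, rng):
        truth = rng.uniform(400, 1500, (5, 5, 5))
        adc = ImageVolume(truth, (3.4, 3.4, 5.0), modality="ADC")
        dwis = synthesize_dwi(adc, 800.0, (50.0, 1000.0), noise_sd=0.0)
        fit, valid = fit_adc_map(dwis, (50.0, 1000.0))
        assert valid.all()
        expected = np.log(dwis[0].data / dwis[1].data) / 950.0 * 1e6
        np.testing.assert_allclose(fit.data, expected, rtol=1e-12)

    @pytest.mark.parametrize("scheme", B_VALUE_SCHEMES)
    def test_noise_free_roundtrip_exact(self, rng, scheme):
        truth = rng.uniform(300, 1600, (8, 8, 8))
        adc = ImageVolume(truth, (3.4, 3.4, 5.0), modality="ADC")
        fit, valid = fit_adc_map(synthesize_dwi(adc, 1000.0, scheme, 0.0), scheme)
        assert valid.all()
        np.testing.assert_allclose(fit.data, truth, rtol=1e-9)

    def test_one_percent_noise_small_relative_error(self):
        rng = np.random.default_rng(99)
        truth = np.full((22, 22, 22), 1000.0)  # ~10^4 voxels
        adc = ImageVolume(truth, (3.4, 3.4, 5.0), modality="ADC")
        scheme = B_VALUE_SCHEMES[0]
        dwis = synthesize_dwi(adc, 1000.0, scheme, noise_sd=10.0, rng=rng)
        fit, valid = fit_adc_map(dwis, scheme)
        rel_err = np.abs(fit.data[valid] - 1000.0) / 1000.0
        assert np.median(rel_err) <= 0.03

    def test_nonpositive_signal_flagged_invalid(self):
        adc = ImageVolume(np.full((3, 3, 3), 1000.0), (3.4, 3.4, 5.0), modality="ADC")
        dwis = synthesize_dwi(adc, 1000.0, (50.0, 1000.0), 0.0)
        dwis[1].data[0, 0, 0] = 0.0
        fit, valid = fit_adc_map(dwis, (50.0, 1000.0))
        assert not valid[0, 0, 0] and valid.sum() == 26
        assert fit.data[0, 0, 0] == 0.0

    def test_bad_inputs_rejected(self):
        adc = ImageVolume(np.full((3, 3, 3), 1000.0), (3.4, 3.4, 5.0), modality="ADC")
        with pytest.raises(ValueError, match="S0"):
            synthesize_dwi(adc, -1.0, (50.0, 1000.0), 0.0)
        with pytest.raises(ValueError, match="2 b-values"):
            fit_adc_map(synthesize_dwi(adc, 100.0, (50.0,), 0.0), (50.0,))


class TestCohortGeneration:
    def test_histology_mix_matches_spec(self):
        clinical = generate_cohort(CohortSpec(seed=1, imaging=False)).clinical
        counts = clinical["histology"].value_counts()
        assert counts["SCCA"] == 9 and counts["AdenoCA"] == 6
        assert counts["small_cell"] == 1 and counts["adenosquamous"] == 1
        grades = clinical["grade"].value_counts()
        assert grades["poor"] == 11 and grades["well"] == 3 and grades["moderate"] == 3
        assert (clinical["treatment"] == "chemoradiation").sum() == 14

    def test_deterministic_tables(self):
        a = generate_cohort(CohortSpec(seed=9, imaging=False))
        b = generate_cohort(CohortSpec(seed=9, imaging=False))
        assert a.clinical.equals(b.clinical)
        assert a.truth.equals(b.truth)

    def test_inconsistent_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to n"):
            CohortSpec(n=17, histology_counts={"SCCA": 5})

    def test_high_risk_is_low_rho_half(self):
        truth = generate_cohort(CohortSpec(seed=4, imaging=False)).truth
        med = truth["rho_requested"].median()
        np.testing.assert_array_equal(truth["high_risk"], truth["rho_requested"] <= med)

    def test_b_schemes_cycle(self):
        truth = generate_cohort(CohortSpec(seed=4, imaging=False)).truth
        assert set(truth["b_scheme"]) == {"50-500-1000", "50-500-800", "50-400-600"}

    def test_yaml_roundtrip(self, tmp_path):
        spec = CohortSpec(seed=21, imaging=False, dfs_log_hr=0.0)
        spec.to_yaml(tmp_path / "cohort.yaml")
        back = CohortSpec.from_yaml(tmp_path / "cohort.yaml")
        assert back == spec

    def test_write_cohort_files(self, tmp_path, analyzed_cohort):
        cohort, _ = analyzed_cohort
        write_cohort(cohort, tmp_path / "out")
        assert (tmp_path / "out" / "clinical.csv").exists()
        assert (tmp_path / "out" / "truth.csv").exists()
        assert (tmp_path / "out" / "P001_pet.nii.gz").exists()
        assert (tmp_path / "out" / "P017_muscle.nii.gz").exists()
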