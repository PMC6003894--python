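import numpy as np
import pytest

from petadc import (
    GlobalMetrics,
    ImageVolume,
    RegionMask,
    compute_adc_metrics,
    compute_pet_metrics,
    mask_volume_ml,
    segment_mtv,
)
from _oracles import flood_fill_threshold


def _vol(data, spacing=(1.0, 1.0, 1.0), modality="PET_SUV"):
    return ImageVolume(np.asarray(data, float), spacing, modality=modality)


def _mask(mask, spacing=(1.0, 1.0, 1.0), label="tumor_VOI"):
    return RegionMask(np.asarray(mask, bool), spacing, label=label)


def _two_blob_image(rng, shape=(24, 24, 16)):
    """Two Gaussian blobs (peaks ~10 and ~3) at random centres."""
    grids = np.indices(shape).astype(float)
    c1 = rng.uniform(4, 8, 3) * shape / 12.0 / 2.0 + 2
    c2 = shape - c1 - 2
    d1 = ((grids[0] - c1[0]) ** 2 + (grids[1] - c1[1]) ** 2 + (grids[2] - c1[2]) ** 2)
    d2 = ((grids[0] - c2[0]) ** 2 + (grids[1] - c2[1]) ** 2 + (grids[2] - c2[2]) ** 2)
    w1, w2 = rng.uniform(4, 9), rng.uniform(4, 9)
    return 10.0 * np.exp(-d1 / (2 * w1)) + 3.0 * np.exp(-d2 / (2 * w2))


class TestSegmentMTV:
    def test_single_hot_voxel(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 10.0
        seed = _mask(np.ones((7, 7, 7)))
        mtv = segment_mtv(_vol(data), seed, 0.4)
        assert mtv.n_voxels == 1 and mtv.mask[3, 3, 3]

    def test_uniform_image_returns_everything_with_warning(self):
        seed = _mask(np.ones((5, 5, 5)))
        with pytest.warns(UserWarning, match="constant"):
            mtv = segment_mtv(_vol(np.full((5, 5, 5), 3.0)), seed, 0.4)
        assert mtv.n_voxels == 125

    @pytest.mark.parametrize("seed_int", range(8))
    def test_two_blobs_match_flood_fill_oracle(self, seed_int):
        rng = np.random.default_rng(seed_int)
        data = _two_blob_image(rng)
        vol = _vol(data)
        seed_region = _mask(np.ones(data.shape))
        mtv = segment_mtv(vol, seed_region, 0.4)
        peak = np.unravel_index(np.argmax(data), data.shape)
        oracle = flood_fill_threshold(data, peak, 0.4 * data.max())
        np.testing.assert_array_equal(mtv.mask, oracle)
        # the trough between the blobs sits below 40% of the hot peak, so the
        # cold blob's own peak must be excluded
        cold = np.unravel_index(np.argmax(np.where(oracle, -np.inf, data)), data.shape)
        assert not mtv.mask[cold]

    def test_threshold_monotonicity(self, rng):
        data = _two_blob_image(rng)
        vol = _vol(data)
        seed = _mask(np.ones(data.shape))
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            m = segment_mtv(vol, seed, frac).mask
            if prev is not None:
                assert (m <= prev).all()  # higher threshold -> subset
            prev = m

    def test_suvmax_taken_within_seed_region(self):
        data = np.zeros((6, 6, 6))
        data[1, 1, 1] = 8.0   # inside seed
        data[5, 5, 5] = 20.0  # outside seed
        seed = np.zeros((6, 6, 6), bool)
        seed[:3, :3, :3] = True
        mtv = segment_mtv(_vol(data), _mask(seed), 0.4)
        assert mtv.mask[1, 1, 1] and not mtv.mask[5, 5, 5]

    def test_invalid_fraction(self):
        vol = _vol(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            segment_mtv(vol, _mask(np.ones((3, 3, 3))), 1.2)


class TestVolumes:
    def test_eight_voxels_at_5mm_is_one_ml(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2, :2, :2] = True
        assert mask_volume_ml(_mask(m, spacing=(5.0, 5.0, 5.0))) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self):
        assert mask_volume_ml(_mask(np.zeros((3, 3, 3), bool), label="muscle")) == 0.0

    def test_digitized_ellipsoid_close_to_analytic(self):
        # semi-axes (20, 15, 10) mm on a 1 mm grid vs (4/3) pi a b c
        ii, jj, kk = np.indices((45, 35, 25)).astype(float)
        r2 = ((ii - 22) / 20) ** 2 + ((jj - 17) / 15) ** 2 + ((kk - 12) / 10) ** 2
        vol = mask_volume_ml(_mask(r2 <= 1.0))
        analytic = 4.0 / 3.0 * np.pi * 20 * 15 * 10 / 1000.0
        assert abs(vol - analytic) / analytic < 0.02


class TestGlobalMetrics:
    def test_uniform_tumor_tlg(self):
        data = np.full((4, 4, 4), 10.0)
        m = np.zeros((4, 4, 4), bool)
        m[:2, :2, :2] = True  # 8 voxels
        mtv = _mask(m, spacing=(6.3, 6.3, 6.3), label="MTV")  # 8 * 250 mm3 = 2 mL
        gm = compute_pet_metrics(_vol(data, spacing=(6.3, 6.3, 6.3)), _mask(m, spacing=(6.3, 6.3, 6.3)), mtv)
        assert gm.suv_mean == pytest.approx(10.0)
        assert gm.tlg == pytest.approx(gm.mtv_ml * 10.0)

    def test_tumor_muscle_ratio(self):
        data = np.full((4, 4, 4), 1.25)
        data[:2, :2, :2] = 10.0
        tum = np.zeros((4, 4, 4), bool)
        tum[:2, :2, :2] = True
        mus = ~tum
        gm = compute_pet_metrics(
            _vol(data), _mask(tum), _mask(tum, label="MTV"), _mask(mus, label="muscle")
        )
        assert gm.suv_tm == pytest.approx(8.0)

    def test_adc_ratio_and_min(self):
        data = np.full((4, 4, 4), 1200.0)
        data[:2, :2, :2] = 900.0
        data[0, 0, 0] = 402.6
        tum = np.zeros((4, 4, 4), bool)
        tum[:2, :2, :2] = True
        gm = compute_adc_metrics(_vol(data, modality="ADC"), _mask(tum), _mask(~tum, label="muscle"))
        assert gm.adc_min == pytest.approx(402.6)
        assert gm.adc_tm == pytest.approx(gm.adc_mean / 1200.0)

    def test_masked_means_match_voxel_loop_oracle(self, rng):
        data = rng.uniform(0.5, 15.0, (10, 10, 10))
        tum = rng.random((10, 10, 10)) > 0.6
        gm = compute_pet_metrics(_vol(data), _mask(tum), _mask(tum, label="MTV"))
        acc, n = 0.0, 0
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    if tum[i, j, k]:
                        acc += data[i, j, k]
                        n += 1
        assert gm.suv_mean == pytest.approx(acc / n, rel=1e-12)
        adc = compute_adc_metrics(_vol(data * 100, modality="ADC"), _mask(tum))
        assert adc.adc_mean == pytest.approx(100 * acc / n, rel=1e-12)

    def test_nonpositive_adc_excluded_and_counted(self):
        data = np.full((3, 3, 3), 900.0)
        data[0, 0, 0] = 0.0
        data[0, 0, 1] = -5.0
        gm = compute_adc_metrics(_vol(data, modality="ADC"), _mask(np.ones((3, 3, 3))))
        assert gm.n_adc_excluded == 2
        assert gm.adc_min == pytest.approx(900.0)

    def test_all_nonpositive_adc_is_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_adc_metrics(_vol(np.zeros((3, 3, 3)), modality="ADC"), _mask(np.ones((3, 3, 3))))

    def test_empty_muscle_flags_ratio_absent(self):
        data = np.full((3, 3, 3), 5.0)
        with pytest.warns(UserWarning, match="muscle"):
            gm = compute_pet_metrics(
                _vol(data),
                _mask(np.ones((3, 3, 3))),
                _mask(np.ones((3, 3, 3)), label="MTV"),
                _mask(np.zeros((3, 3, 3), bool), label="muscle"),
            )
        assert gm.suv_tm is None

    def test_metrics_invariant_under_axis_permutation(self, rng):
        data = rng.uniform(1, 12, (6, 7, 8))
        tum = rng.random((6, 7, 8)) > 0.5
        sp = (2.0, 3.0, 4.0)
        gm = compute_pet_metrics(_vol(data, sp), _mask(tum, sp), _mask(tum, sp, label="MTV"))
        perm = (2, 0, 1)
        sp_p = tuple(sp[a] for a in perm)
        gm_p = compute_pet_metrics(
            _vol(data.transpose(perm), sp_p),
            _mask(tum.transpose(perm), sp_p),
            _mask(tum.transpose(perm), sp_p, label="MTV"),
        )
        for k, v in gm.as_dict().items():
            if v is not None:
                assert gm_p.as_dict()[k] == pytest.approx(v, rel=1e-12)

    def test_mean_above_max_rejected(self):
        with pytest.raises(ValueError, match="SUVmean"):
            GlobalMetrics(suv_max=5.0, suv_mean=6.0, mtv_ml=1.0)
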