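import numpy as np
import pytest

from rifm.features import (
    ColumnMeta,
    DyadicConfig,
    FeatureMatrix,
    dyadic_features,
    gabor_features,
    gabor_kernel,
    gaussian_features,
    glcm,
    glcm_features,
    texoff_features,
    texscale_features,
    wavelet_features,
    zscore_normalize,
)
from rifm.io import RetinalImage

from oracles import glcm_features_bruteforce


@pytest.fixture
def small_regions():
    """Whole-crop single region plus a two-region split for a 64x64 crop."""
    whole = np.ones((64, 64), bool)
    return {"whole": whole}


class TestGLCM:
    def test_hand_enumeration_two_rows(self):
        # 2x2 image with rows (0,0) and (1,1): the two horizontal pairs are
        # (0,0) and (1,1)
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        p = glcm(img, np.ones((2, 2), bool), d=1, levels=2,
                 orientations=((1, 0),), symmetric=False)
        assert p[0, 0] == pytest.approx(0.5)
        assert p[1, 1] == pytest.approx(0.5)
        assert p[0, 1] == 0 and p[1, 0] == 0

    def test_sums_to_one(self, rng):
        img = rng.random((32, 32))
        mask = rng.random((32, 32)) > 0.3
        p = glcm(img, mask, d=2)
        assert p.sum() == pytest.approx(1.0)

    def test_constant_region_all_mass_on_diagonal(self):
        p = glcm(np.full((8, 8), 0.3), np.ones((8, 8), bool), d=1)
        f = glcm_features(p)
        names = dict(zip(
            ("autocorrelation", "contrast", "correlation", "cluster_prominence",
             "cluster_shade", "dissimilarity", "energy", "entropy",
             "homogeneity", "max_probability", "sum_of_squares", "sum_average",
             "sum_variance", "sum_entropy", "difference_variance",
             "difference_entropy", "imc1", "imc2", "idn", "idmn"), f))
        assert names["contrast"] == 0.0
        assert names["energy"] == 1.0
        assert names["entropy"] == 0.0

    def test_pairs_restricted_to_region(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 1.0
        left = np.zeros((4, 4), bool)
        left[:, :2] = True
        p = glcm(img, left, d=1, levels=2)
        # region is constant zero; no (0,1) transitions may leak in
        assert p[0, 0] == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((4, 4)), np.zeros((4, 4), bool), d=1)


class TestGLCMFeatures:
    def test_hand_diagonal_matrix(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(p)
        assert f[1] == 0.0          # contrast
        assert f[6] == pytest.approx(0.5)   # energy
        assert f[7] == pytest.approx(1.0)   # entropy (bits)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(3):
            raw = rng.random((8, 8))
            p = raw / raw.sum()
            assert np.allclose(glcm_features(p), glcm_features_bruteforce(p),
                               atol=1e-10)


class TestBlocks:
    def test_gaussian_feature_values_match_masked_mean(self, region_fixture):
        crop, rmask = region_fixture
        from rifm.segmentation import FilterBank, gaussian_bank_maps

        bank = FilterBank()
        maps = gaussian_bank_maps(crop, bank, inpaint=False)
        vals, meta = gaussian_features(crop, rmask.region_masks(), bank,
                                       maps=maps)
        # first column: channel red, sigma 2, kernel N, region OD
        od = rmask.mask("OD")
        assert vals[0] == pytest.approx(maps[0][od].mean())
        assert meta[0].family == "g" and meta[0].region == "OD"

    def test_constant_crop_derivative_features_zero(self, small_regions):
        crop = RetinalImage(np.full((64, 64, 3), 0.4))
        vals, meta = gaussian_features(crop, small_regions)
        deriv = [v for v, m in zip(vals, meta) if not m.params.startswith("N,")]
        assert np.allclose(deriv, 0.0, atol=1e-4)

    def test_texoff_first_offset_consistency(self, small_regions):
        rng = np.random.default_rng(1)
        crop = RetinalImage(rng.random((64, 64, 3)))
        vals, meta = texoff_features(crop, small_regions)
        direct = glcm_features(glcm(crop.red, small_regions["whole"], 1))
        assert np.allclose(vals[:20], direct)

    def test_dyadic_constant_image_zero(self, small_regions):
        crop = RetinalImage(np.full((64, 64, 3), 0.6))
        vals, _ = dyadic_features(crop, small_regions)
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_dyadic_equal_channels_zero_opponent(self, small_regions, rng):
        px = np.zeros((64, 64, 3))
        px[:, :, 0] = px[:, :, 1] = rng.random((64, 64))
        vals, meta = dyadic_features(RetinalImage(px), small_regions)
        rg = [v for v, m in zip(vals, meta) if m.channel == "RG"]
        assert np.allclose(rg, 0.0, atol=1e-12)

    def test_gabor_orientation_selectivity(self, small_regions):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        from rifm.features import GaborConfig

        cfg = GaborConfig(sigmas=(4.0,), gammas=(0.5,), freqs=(0.25,),
                          thetas=(0.0, 45.0, 90.0, 135.0))
        for ang, wave in ((0.0, xx), (45.0, (xx + yy) / np.sqrt(2))):
            px = np.repeat((0.5 + 0.4 * np.sin(2 * np.pi * 0.25 * wave))
                           [:, :, None], 3, axis=2)
            vals, meta = gabor_features(RetinalImage(px), small_regions, cfg)
            red = [(m.params, v) for v, m in zip(vals, meta)
                   if m.channel == "red"]
            best = max(red, key=lambda kv: kv[1])[0]
            assert best.startswith(f"t{ang:g},")

    def test_wavelet_constant_region_detail_zero(self, small_regions):
        crop = RetinalImage(np.full((64, 64, 3), 0.7))
        vals, meta = wavelet_features(crop, small_regions)
        for v, m in zip(vals, meta):
            band = m.params.split(",")[1]
            if band in ("H", "V", "D") and "haar" in m.params:
                assert v == pytest.approx(0.0, abs=1e-10)

    def test_wavelet_energy_nonnegative(self, region_fixture):
        crop, rmask = region_fixture
        vals, meta = wavelet_features(crop, rmask.region_masks())
        en = [v for v, m in zip(vals, meta) if m.params.endswith("Energy")]
        assert np.all(np.array(en) >= 0.0)


class TestFeatureMatrix:
    def test_metadata_round_trip_csv(self, tmp_path, rng):
        cols = [ColumnMeta("g", "OD", "red", "N,s2"),
                ColumnMeta("wav", "I", "green", "haar,D,Avg")]
        fm = FeatureMatrix(rng.random((3, 2)), cols)
        p = tmp_path / "fm.csv"
        fm.to_csv(p)
        back = FeatureMatrix.from_csv(p)
        assert back.columns == cols
        assert np.allclose(back.values, fm.values)

    def test_identical_pixels_identical_rows(self, region_fixture):
        crop, rmask = region_fixture
        from rifm.features import extract_sample

        v1, _ = extract_sample(crop, rmask.region_masks())
        v2, _ = extract_sample(crop, rmask.region_masks())
        assert np.array_equal(v1, v2)


class TestZScore:
    def test_train_columns_standardised(self, rng):
        fm = FeatureMatrix(rng.random((20, 5)),
                           [ColumnMeta("g", "OD", "red", str(i)) for i in range(5)])
        z, stats = zscore_normalize(fm)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.values.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        vals = rng.random((10, 3))
        vals[:, 1] = 7.0
        fm = FeatureMatrix(vals, [ColumnMeta("g", "OD", "red", str(i))
                                  for i in range(3)])
        with pytest.warns(UserWarning, match="zero-variance"):
            z, stats = zscore_normalize(fm)
        assert z.n_features == 2

    def test_population_sd_hand_example(self):
        fm = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]),
                           [ColumnMeta("g", "OD", "red", "x")])
        z, _ = zscore_normalize(fm)
        assert np.allclose(z.values.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_test_rows_use_train_stats(self, rng):
        vals = rng.random((12, 4))
        fm = FeatureMatrix(vals, [ColumnMeta("g", "OD", "red", str(i))
                                  for i in range(4)])
        z, stats = zscore_normalize(fm, train_rows=np.arange(8))
        assert np.allclose(z.values[:8].mean(axis=0), 0.0, atol=1e-12)
        assert not np.allclose(z.values[8:].mean(axis=0), 0.0, atol=1e-3)
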