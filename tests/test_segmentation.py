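import numpy as np
import pytest

from rifm.io import RetinalImage
from rifm.segmentation import (
    DiscContour,
    FilterBank,
    build_profile_model,
    build_shape_model,
    contour_normals,
    dice,
    fit_contour,
    gaussian_bank_maps,
    inpaint_vessels,
    resample_contour,
    sample_normal_profiles,
    segment_vessels,
    shape_regularize,
)
from rifm.synthetic import SyntheticSpec, generate_eye


def _circle(cx, cy, r, n=64):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


class TestFilterBank:
    def test_derivative_of_constant_is_zero(self, flat_image):
        maps = gaussian_bank_maps(flat_image, FilterBank(sigmas=(2.0,)),
                                  inpaint=False)
        # order: N, Nx, Ny, Nxx, Nxy, Nyy per channel; derivatives vanish
        for c in range(2):
            base = 6 * c
            assert np.allclose(maps[base], 0.5)
            for k in range(1, 6):
                assert np.allclose(maps[base + k], 0.0, atol=1e-4)

    def test_delta_peak_matches_kernel_height(self):
        px = np.zeros((65, 65, 3))
        px[32, 32, :] = 1.0
        sigma = 4.0
        maps = gaussian_bank_maps(RetinalImage(px), FilterBank(sigmas=(sigma,)),
                                  inpaint=False)
        peak = maps[0][32, 32]
        assert peak == pytest.approx(1.0 / (2 * np.pi * sigma ** 2), rel=0.01)

    def test_noise_variance_decreases_with_scale(self, rng):
        px = rng.random((96, 96, 3))
        maps = gaussian_bank_maps(RetinalImage(px), FilterBank(), inpaint=False)
        variances = [maps[i].var() for i in range(0, 24, 6)]  # N at each scale
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_map_count(self, flat_image):
        bank = FilterBank()
        assert bank.n_maps == 48
        assert gaussian_bank_maps(flat_image, bank, inpaint=False).shape[0] == 48


class TestVessels:
    def test_synthetic_vessel_dice(self, normal_eye):
        img, gt = normal_eye
        mask = segment_vessels(img, sigma=2.0)
        assert dice(mask, gt.vessel_mask) >= 0.6

    def test_vessel_free_image_near_empty(self, rng):
        px = np.clip(0.5 + rng.normal(0, 0.02, (128, 128, 3)), 0, 1)
        assert segment_vessels(RetinalImage(px), sigma=2.0).mean() < 0.01

    def test_all_zero_image_empty(self):
        assert not segment_vessels(RetinalImage(np.zeros((96, 96, 3))),
                                   sigma=2.0).any()


class TestInpaint:
    def test_empty_mask_identity(self, rng):
        ch = rng.random((40, 40))
        out = inpaint_vessels(ch, np.zeros((40, 40), bool))
        assert np.array_equal(out, ch)

    def test_dark_line_restored_to_field(self):
        ch = np.full((40, 40), 0.8)
        ch[:, 19:22] = 0.1
        mask = ch < 0.5
        out = inpaint_vessels(ch, mask)
        assert np.allclose(out[mask], 0.8, rtol=0.01)

    def test_closing_is_extensive_on_vessels(self, rng):
        ch = rng.random((40, 40))
        mask = rng.random((40, 40)) > 0.8
        out = inpaint_vessels(ch, mask)
        assert np.all(out[mask] >= ch[mask] - 1e-12)
        assert np.array_equal(out[~mask], ch[~mask])


class TestProfiles:
    def _radial_maps(self, n=96):
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        r = np.hypot(xx - n / 2, yy - n / 2)
        return np.exp(-((r - 20) ** 2) / 50.0)[None, :, :]

    def test_radially_symmetric_profiles_equal(self):
        maps = self._radial_maps()
        cont = _circle(48, 48, 20)
        profs = sample_normal_profiles(maps, cont, L=5)
        assert np.allclose(profs - profs[0], 0.0, atol=0.02)

    def test_center_sample_equals_map_value(self):
        maps = self._radial_maps()
        cont = _circle(48, 48, 20, n=16)
        profs = sample_normal_profiles(maps, cont, L=3)
        from scipy.ndimage import map_coordinates

        direct = map_coordinates(maps[0], [cont[:, 1], cont[:, 0]], order=1)
        assert np.allclose(profs[:, 3], direct)

    def test_reversed_contour_flips_profiles(self):
        maps = self._radial_maps()
        cont = _circle(48, 48, 20, n=16)
        f = sample_normal_profiles(maps, cont, L=4)
        b = sample_normal_profiles(maps, cont[::-1], L=4)
        assert np.allclose(f[0], b[-1][::-1], atol=1e-9)


class TestProfileModel:
    def test_zero_distance_at_mean(self, rng):
        profs = rng.normal(size=(8, 4, 10))
        pm = build_profile_model(profs, L=2, n_maps=2)
        for n in range(4):
            d2 = pm.mahalanobis2(n, pm.mean[n][None, :])
            assert d2[0] == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_training_stays_finite(self):
        profs = np.tile(np.arange(10.0), (6, 4, 1))  # identical images
        pm = build_profile_model(profs, L=2, n_maps=2)
        d2 = pm.mahalanobis2(0, profs[0, 0][None, :] + 1.0)
        assert np.isfinite(d2[0]) and d2[0] > 0

    def test_far_profiles_score_higher(self, rng):
        profs = rng.normal(size=(20, 3, 8))
        pm = build_profile_model(profs, L=1, n_maps=2)
        near = pm.mean[0] + 0.1
        far = pm.mean[0] + 10.0
        d = pm.mahalanobis2(0, np.stack([near, far]))
        assert d[1] > d[0]


class TestShapeModel:
    def _ellipses(self, rng, k=12, n=32):
        conts = []
        for _ in range(k):
            rx = 20 + rng.normal(0, 2)
            ry = rx * (1.05 + rng.normal(0, 0.03))
            conts.append(_circle(0, 0, 1, n) * np.array([rx, ry]) + 50)
        return conts

    def test_mean_shape_is_fixed_point(self, rng):
        model = build_shape_model(self._ellipses(rng), n_points=32)
        pts = model.mean_shape * model.mean_scale + 100.0
        out = shape_regularize(pts, model)
        assert np.allclose(out, pts, atol=1e-6)

    def test_mode_weights_clamped(self, rng):
        model = build_shape_model(self._ellipses(rng), n_points=32)
        lam1 = model.eigvals[0]
        mode1 = model.components[0].reshape(-1, 2)
        wild = (model.mean_shape + 10 * np.sqrt(lam1) * mode1) * 100.0
        out = shape_regularize(wild, model)
        expect = (model.mean_shape + 3 * np.sqrt(lam1) * mode1)
        norm_out, _, _ = _normalise(out)
        assert np.allclose(norm_out, expect / np.linalg.norm(expect), atol=1e-6)

    def test_within_limit_perturbation_preserved(self, rng):
        model = build_shape_model(self._ellipses(rng), n_points=32)
        lam1 = model.eigvals[0]
        mode1 = model.components[0].reshape(-1, 2)
        shape = (model.mean_shape + 1.5 * np.sqrt(lam1) * mode1) * 80.0 + 10
        out = shape_regularize(shape, model)
        # exact up to the component of the perturbation outside the kept
        # modes (second order in the mode weight)
        assert np.allclose(out, shape, atol=0.01)

    def test_eigvals_descending(self, rng):
        model = build_shape_model(self._ellipses(rng), n_points=32)
        assert np.all(np.diff(model.eigvals) <= 1e-12)


def _normalise(pts):
    c = pts.mean(axis=0)
    x = pts - c
    s = np.linalg.norm(x)
    return x / s, c, s


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.flat[:100] = True
        b.flat[50:150] = True
        assert dice(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((5, 5), bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_union_denominator_variant(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        assert dice(a, a, union_denominator=True) == 2.0


class TestEq4Centroid:
    def test_square_centroid(self):
        sq = DiscContour(np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]]))
        assert sq.centroid == (1.0, 1.0)


@pytest.fixture(scope="module")
def trained():
    specs = [SyntheticSpec(seed=100 + i, cdr=0.35 + 0.02 * i) for i in range(8)]
    eyes = [generate_eye(s) for s in specs]
    bank = FilterBank()
    maps = [gaussian_bank_maps(img, bank, vessel_sigma=2.0) for img, _ in eyes]
    profs = [
        sample_normal_profiles(m, resample_contour(gt.disc_contour, 64), 8)
        for m, (_, gt) in zip(maps, eyes)
    ]
    pm = build_profile_model(np.stack(profs), L=8, n_maps=bank.n_maps)
    sm = build_shape_model([gt.disc_contour for _, gt in eyes], 64)
    return pm, sm


class TestFitContour:
    def test_recovers_disc_from_true_centre(self, trained):
        pm, sm = trained
        img, gt = generate_eye(SyntheticSpec(seed=200, cdr=0.4))
        cont = fit_contour(img, gt.disc_center, pm, sm, P=13, vessel_sigma=2.0)
        d = dice(cont.mask(img.shape), gt.disc_mask(img.shape))
        assert d >= 0.9

    def test_training_mean_profile_has_edge_signature(self, trained):
        pm, _ = trained
        # the first-derivative x-map of the red channel at sigma=2 is map 1;
        # its profile across the boundary must not be flat
        seg = pm.mean[:, (2 * 8 + 1) * 1 : (2 * 8 + 1) * 2]
        assert seg.std() > 1e-4

    def test_shuffling_training_order_is_invariant(self, rng):
        profs = rng.normal(size=(10, 4, 6))
        a = build_profile_model(profs, L=1, n_maps=2)
        b = build_profile_model(profs[::-1], L=1, n_maps=2)
        assert np.allclose(a.mean, b.mean)
        assert np.allclose(a.lam, b.lam)
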