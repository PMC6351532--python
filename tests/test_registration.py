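"""NGF distance, curvature regulariser, affine/nonparametric/patch registration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from episeg import registration as reg
from episeg import synthetic


def textured_image(shape=(96, 96), sigma=4.0, seed=0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), sigma)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture(scope="module")
def multimodal_pair():
    cfg = synthetic.SceneConfig(canvas=256, n_benign=3, n_small_malignant=5,
                                n_single_cell=6, benign_radius=(20.0, 30.0),
                                malignant_radius=(7.0, 12.0))
    scene = synthetic.generate_scene(cfg, seed=1)
    ihc = synthetic.render(scene, "IHC")
    he = synthetic.render(scene, "HE")
    warped_he, field = synthetic.deform_pair(he, 5.0, smoothness=20.0, seed=101)
    return ihc, warped_he, field


class TestGrayscale:
    def test_white_and_black(self):
        assert np.allclose(reg.to_grayscale(np.ones((3, 3, 3))), 1.0)
        assert np.allclose(reg.to_grayscale(np.zeros((3, 3, 3))), 0.0)

    def test_known_weighted_sum(self):
        px = np.array([[[0.2, 0.5, 0.8]]])
        # ITU-R 709 luma weights used by scikit-image
        expected = 0.2125 * 0.2 + 0.7154 * 0.5 + 0.0721 * 0.8
        assert reg.to_grayscale(px)[0, 0] == pytest.approx(expected, abs=1e-4)


class TestNgfDistance:
    def test_constant_images_give_distance_one(self):
        a = np.full((16, 16), 0.5)
        assert reg.ngf_distance(a, a, epsilon=0.01) == pytest.approx(1.0)

    def test_identical_textured_images_beat_translated_copy(self):
        img = textured_image()
        shifted = np.roll(img, 5, axis=1)
        d_same = reg.ngf_distance(img, img, 0.001)
        d_shift = reg.ngf_distance(img, shifted, 0.001)
        assert d_same < d_shift

    def test_intensity_scale_invariance_in_small_epsilon_limit(self):
        img = textured_image()
        scaled = 2.0 * img + 0.1
        d_self = reg.ngf_distance(img, img, 1e-8)
        d_scaled = reg.ngf_distance(img, scaled, 1e-8)
        assert abs(d_self - d_scaled) < 1e-6

    def test_symmetric_and_bounded(self):
        a, b = textured_image(seed=1), textured_image(seed=2)
        d_ab = reg.ngf_distance(a, b, 0.01)
        d_ba = reg.ngf_distance(b, a, 0.01)
        assert d_ab == pytest.approx(d_ba)
        assert 0.0 <= d_ab <= 1.0

    def test_shape_mismatch_and_bad_epsilon(self):
        with pytest.raises(ValueError):
            reg.ngf_distance(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            reg.ngf_distance(np.zeros((4, 4)), np.zeros((4, 4)), epsilon=0.0)


class TestCurvatureEnergy:
    def test_zero_field(self):
        assert reg.curvature_energy(np.zeros((10, 10, 2))) == 0.0

    def test_affine_fields_have_exactly_zero_curvature(self):
        params = np.array([1.02, 0.01, -0.03, 0.99, 2.0, -1.0])
        field = reg.field_from_affine(params, (20, 24))
        assert reg.curvature_energy(field) == pytest.approx(0.0, abs=1e-24)

    def test_gaussian_bump_matches_stencil_oracle(self):
        rr, cc = np.mgrid[0:32, 0:32].astype(float)
        bump = np.exp(-((rr - 16) ** 2 + (cc - 16) ** 2) / 30.0)
        field = np.stack([bump, np.zeros_like(bump)], axis=-1)
        # brute-force 5-point stencil with linear-extrapolation border
        pad = np.pad(bump, 1)
        pad[0, 1:-1] = 2 * bump[0] - bump[1]
        pad[-1, 1:-1] = 2 * bump[-1] - bump[-2]
        pad[1:-1, 0] = 2 * bump[:, 0] - bump[:, 1]
        pad[1:-1, -1] = 2 * bump[:, -1] - bump[:, -2]
        lap = np.zeros_like(bump)
        for r in range(32):
            for c in range(32):
                lap[r, c] = (pad[r, c + 1] + pad[r + 2, c + 1] + pad[r + 1, c]
                             + pad[r + 1, c + 2] - 4 * bump[r, c])
        expected = 0.5 * float(np.mean(lap**2))
        assert reg.curvature_energy(field) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        bad = np.zeros((4, 4, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            reg.curvature_energy(bad)


class TestWarp:
    def test_zero_field_identity(self, rng):
        img = rng.random((12, 12))
        field = np.zeros((12, 12, 2))
        assert np.allclose(reg.warp(img, field), img)

    def test_integer_shift_exact_for_masks(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 2:4] = True
        field = np.zeros((10, 10, 2))
        field[..., 1] = 3.0  # sample 3 columns to the right
        out = reg.warp(mask, field, "nearest")
        assert out.dtype == bool
        expected = np.zeros_like(mask)
        expected[4:6, 0:1] = False
        expected[4:6, max(2 - 3, 0):max(4 - 3, 0)] = True
        assert np.array_equal(out, expected)

    def test_out_of_domain_takes_background(self):
        img = np.ones((6, 6))
        field = np.zeros((6, 6, 2))
        field[..., 0] = 10.0
        out = reg.warp(img, field, "linear", background=0.25)
        assert np.allclose(out, 0.25)

    def test_invalid_interpolation(self):
        with pytest.raises(ValueError):
            reg.warp(np.zeros((4, 4)), np.zeros((4, 4, 2)), "cubic")


class TestAffineRegister:
    def test_identity_for_identical_images(self):
        img = textured_image((128, 128), sigma=5.0, seed=3)
        cfg = reg.RegistrationConfig(pyramid_levels=3, smoothing_sigma=0)
        params = reg.affine_register(img, img, cfg)
        field = reg.field_from_affine(params, img.shape)
        assert np.hypot(field[..., 0], field[..., 1]).max() < 0.5

    def test_recovers_rotation_and_translation(self):
        from scipy.ndimage import affine_transform

        img = textured_image((128, 128), sigma=5.0, seed=4)
        theta = np.deg2rad(3.0)
        a = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        centre = (np.array(img.shape) - 1) / 2
        offset = centre - a @ centre + np.array([4.0, -2.0])
        moving = affine_transform(img, a, offset=offset, order=1, mode="nearest")
        cfg = reg.RegistrationConfig(pyramid_levels=3, smoothing_sigma=0,
                                     affine_max_iterations=150)
        params = reg.affine_register(img, moving, cfg)
        # compose recovered map with ground truth: residual displacement on a
        # central patch must be subpixel
        field = reg.field_from_affine(params, img.shape)
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        sr = rr + field[..., 0]
        sc = cc + field[..., 1]
        tr = a[0, 0] * sr + a[0, 1] * sc + offset[0]
        tc = a[1, 0] * sr + a[1, 1] * sc + offset[1]
        residual = np.hypot(tr - rr, tc - cc)[32:96, 32:96]
        assert residual.max() < 0.5

    def test_multimodal_shift_recovered(self, multimodal_pair):
        ihc, _, _ = multimodal_pair
        he = synthetic.render(
            synthetic.generate_scene(synthetic.SceneConfig(
                canvas=256, n_benign=3, n_small_malignant=5, n_single_cell=6,
                benign_radius=(20.0, 30.0), malignant_radius=(7.0, 12.0)), seed=1),
            "HE")
        shifted = np.roll(he.image, (6, 0), axis=(0, 1))
        params = reg.affine_register(ihc.image, shifted,
                                     reg.RegistrationConfig(pyramid_levels=4))
        # rolling the moving image down by 6 rows means sampling it 6 rows
        # further down recovers the fixed image
        assert params[4] == pytest.approx(6.0, abs=1.0)


class TestNonparametricRegister:
    def test_identical_images_give_near_zero_field(self):
        img = textured_image((96, 96), sigma=5.0, seed=5)
        res = reg.nonparametric_register(img, img,
                                         config=reg.RegistrationConfig(pyramid_levels=3,
                                                                       smoothing_sigma=0))
        assert np.hypot(res.field[..., 0], res.field[..., 1]).mean() < 0.1

    def test_known_smooth_warp_recovered(self, multimodal_pair):
        ihc, warped_he, field = multimodal_pair
        cfg = reg.RegistrationConfig(pyramid_levels=4, max_iterations=150)
        res = reg.nonparametric_register(ihc.image, warped_he.image, config=cfg)
        truth = reg.invert_field(field)
        err = reg.displacement_error(res.field, truth, ihc.tissue_mask)
        assert err < 1.0

    def test_final_distance_not_worse_than_identity(self, multimodal_pair):
        ihc, warped_he, _ = multimodal_pair
        cfg = reg.RegistrationConfig(pyramid_levels=4, max_iterations=60)
        res = reg.nonparametric_register(ihc.image, warped_he.image, config=cfg)
        f = reg._preprocess(ihc.image, cfg)
        m = reg._preprocess(warped_he.image, cfg)
        eps = reg._epsilon_for(f, cfg)
        assert res.final_distance <= reg.ngf_distance(f, m, eps) + 1e-12

    def test_strong_regularisation_drives_curvature_down(self, multimodal_pair):
        ihc, warped_he, _ = multimodal_pair
        weak = reg.nonparametric_register(
            ihc.image, warped_he.image,
            config=reg.RegistrationConfig(pyramid_levels=3, max_iterations=40,
                                          curvature_weight=0.1))
        strong = reg.nonparametric_register(
            ihc.image, warped_he.image,
            config=reg.RegistrationConfig(pyramid_levels=3, max_iterations=40,
                                          curvature_weight=1000.0))
        assert reg.curvature_energy(strong.field) < reg.curvature_energy(weak.field)


class TestPatchRegisterMerge:
    def test_single_patch_equals_plain_nonparametric(self, multimodal_pair):
        ihc, warped_he, _ = multimodal_pair
        cfg = reg.RegistrationConfig(pyramid_levels=3, max_iterations=40,
                                     patch_size=512, patch_overlap=128)
        init = np.zeros((256, 256, 2))
        merged = reg.patch_register_merge(ihc.image, warped_he.image, init, cfg)
        single = reg.nonparametric_register(ihc.image, warped_he.image, init=init,
                                            config=cfg)
        assert np.array_equal(merged, single.field)

    def test_patch_too_small_raises(self, multimodal_pair):
        ihc, warped_he, _ = multimodal_pair
        with pytest.raises(ValueError, match="patch"):
            cfg = reg.RegistrationConfig(patch_size=16, patch_overlap=4)
            reg.patch_register_merge(ihc.image, warped_he.image,
                                     np.zeros((256, 256, 2)), cfg)

    def test_identical_patch_fields_merge_exactly(self, monkeypatch):
        """If every patch solve returns the same field, merging returns it."""
        img = textured_image((96, 96), sigma=4.0, seed=6)
        common = np.zeros((0,))  # placeholder, set below

        base = np.stack(np.meshgrid(np.linspace(0, 2, 96), np.linspace(-1, 1, 96),
                                    indexing="ij"), axis=-1)

        def fake_register(fixed, moving, init=None, config=None):
            r0, c0 = fake_register.calls.pop(0)
            sub = base[r0:r0 + fixed.shape[0], c0:c0 + fixed.shape[1]]
            return reg.RegistrationResult(affine=reg.IDENTITY_AFFINE, field=sub.copy(),
                                          final_distance=0.0)

        cfg = reg.RegistrationConfig(pyramid_levels=2, patch_size=64, patch_overlap=32,
                                     min_level_size=16)
        rows = reg._patch_grid(96, 64, 32)
        cols = reg._patch_grid(96, 64, 32)
        fake_register.calls = [(r0, c0) for r0, _ in rows for c0, _ in cols]
        monkeypatch.setattr(reg, "nonparametric_register", fake_register)
        merged = reg.patch_register_merge(img, img, np.zeros((96, 96, 2)), cfg)
        assert np.allclose(merged, base, atol=1e-9)

    def test_disagreeing_patches_blend_smoothly(self, monkeypatch):
        """Two patches differing by a constant offset: the merged field must
        transition with a smaller discrete Laplacian than a hard step."""
        img = textured_image((64, 96), sigma=4.0, seed=7)

        def fake_register(fixed, moving, init=None, config=None):
            val = fake_register.values.pop(0)
            field = np.full(fixed.shape + (2,), val)
            return reg.RegistrationResult(affine=reg.IDENTITY_AFFINE, field=field,
                                          final_distance=0.0)

        cfg = reg.RegistrationConfig(pyramid_levels=2, patch_size=64, patch_overlap=32,
                                     min_level_size=16, merge_weight=1.0)
        n_patches = len(reg._patch_grid(64, 64, 32)) * len(reg._patch_grid(96, 64, 32))
        assert n_patches == 2
        fake_register.values = [0.0, 2.0]
        monkeypatch.setattr(reg, "nonparametric_register", fake_register)
        merged = reg.patch_register_merge(img, img, np.zeros((64, 96, 2)), cfg)
        # hard step: 0 on the left, 2 on the right of the overlap midline
        step = np.zeros((64, 96, 2))
        step[:, 48:, 0] = 2.0
        lap_merged = max(np.abs(reg._laplacian(merged[..., k])).max() for k in range(2))
        lap_step = max(np.abs(reg._laplacian(step[..., k])).max() for k in range(2))
        assert lap_merged < lap_step
        # stays within the two patch values up to a tiny smoothing overshoot
        assert merged[..., 0].min() >= -0.01 and merged[..., 0].max() <= 2.01


class TestFullChain:
    def test_register_pair_recovers_synthetic_warp(self, multimodal_pair):
        ihc, warped_he, field = multimodal_pair
        cfg = reg.RegistrationConfig(pyramid_levels=4, max_iterations=150,
                                     patch_size=160, patch_overlap=48)
        res = reg.register_pair(ihc.image, warped_he.image, cfg)
        truth = reg.invert_field(field)
        err = reg.displacement_error(res.field, truth, ihc.tissue_mask)
        assert err < 1.0
        within = np.hypot(res.field[..., 0] - truth[..., 0],
                          res.field[..., 1] - truth[..., 1]) < 1.0
        assert within[ihc.tissue_mask].mean() >= 0.8
        warped_mask = reg.warp(warped_he.truth_mask, res.field, "nearest")
        inter = (warped_mask & ihc.truth_mask).sum()
        union = (warped_mask | ihc.truth_mask).sum()
        assert inter / union >= 0.95


class TestInvertField:
    def test_inverse_of_smooth_field_roundtrips(self):
        field = synthetic.random_smooth_field((64, 64), 4.0, smoothness=12.0, rng=3)
        inv = reg.invert_field(field)
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        from scipy.ndimage import map_coordinates

        # u(x + v(x)) + v(x) must be ~0
        comp = np.stack([
            map_coordinates(field[..., k], [rr + inv[..., 0], cc + inv[..., 1]],
                            order=1, mode="nearest")
            for k in range(2)], axis=-1) + inv
        assert np.abs(comp)[8:-8, 8:-8].max() < 0.05


def test_registration_config_validation():
    with pytest.raises(ValueError):
        reg.RegistrationConfig(patch_size=64, patch_overlap=64)
    with pytest.raises(ValueError):
        reg.RegistrationConfig(pyramid_levels=0)
    with pytest.raises(ValueError):
        reg.RegistrationConfig(curvature_weight=-1.0)
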