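import numpy as np
import pytest
import scipy.ndimage as ndi

from mle import phantoms, photostereo
from mle.frameio import ConfigurationError, LightSourceGeometry
from mle.photostereo import (
    compare_height,
    highpass_normals,
    inpaint_speculars,
    integrate_height,
    poisson_solve,
    render_relit,
    solve_normals,
)


class TestInpaintSpeculars:
    def test_clean_frame_untouched(self):
        frame = np.full((8, 8), 0.4)
        out, spec = inpaint_speculars(frame, 0.95)
        np.testing.assert_array_equal(out, frame)
        assert not spec.any()

    def test_single_hot_pixel_filled_with_surroundings(self):
        frame = np.full((9, 9), 0.3)
        frame[4, 4] = 1.0
        out, spec = inpaint_speculars(frame, 0.95, dilate=1)
        np.testing.assert_allclose(out, 0.3, atol=1e-10)
        assert spec[4, 4]

    def test_disk_on_ramp_harmonic_fill(self):
        h = w = 33
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ramp = 0.9 * xx / (w - 1)  # stays below the specular threshold
        frame = ramp.copy()
        disk = (xx - 16) ** 2 + (yy - 16) ** 2 < 16
        frame[disk] = 1.0
        out, spec = inpaint_speculars(frame, 0.95, dilate=1)
        # harmonic interpolation reproduces the linear ramp inside the disk
        assert np.abs(out[spec] - ramp[spec]).max() < 0.02 * ramp.max()

    def test_large_specular_area_warns(self):
        frame = np.ones((10, 10))
        frame[:2] = 0.1
        with pytest.warns(RuntimeWarning):
            inpaint_speculars(frame, 0.5, dilate=0)


class TestSolveNormals:
    def test_flat_plane_symmetric_lights(self):
        scene = phantoms.SurfaceScene(height_map=np.zeros((16, 16)))
        geom = phantoms.default_geometry(zenith_deg=30.0)
        imgs = np.stack(
            [phantoms.render_directional(scene, geom, i + 1) for i in range(3)]
        )
        model = solve_normals(imgs, geom)
        np.testing.assert_allclose(
            model.normals, np.broadcast_to([0, 0, 1.0], (16, 16, 3)), atol=1e-9
        )
        np.testing.assert_allclose(model.albedo, np.pi, atol=1e-9)

    def test_hemisphere_round_trip(self, hemisphere_bundle):
        scene, geom, imgs = hemisphere_bundle
        model = solve_normals(imgs, geom)
        truth = scene.normals()
        unshadowed = np.all(imgs > 1e-3, axis=0)
        dot = np.clip(np.sum(model.normals * truth, axis=-1), -1.0, 1.0)
        angles = np.degrees(np.arccos(dot))
        assert np.median(angles[unshadowed]) < 2.0

    def test_intensity_scaling_equivariance(self, hemisphere_bundle):
        _, geom, imgs = hemisphere_bundle
        m1 = solve_normals(imgs, geom)
        m2 = solve_normals(2.0 * imgs, geom)
        valid = m1.mask.valid & m2.mask.valid
        np.testing.assert_allclose(m2.normals[valid], m1.normals[valid], atol=1e-9)
        np.testing.assert_allclose(m2.albedo[valid], 2.0 * m1.albedo[valid], rtol=1e-9)

    def test_rank_deficient_geometry_rejected(self):
        geom = LightSourceGeometry(directions=[[0, 0, 1.0]] * 3)
        with pytest.raises(ConfigurationError):
            solve_normals(np.ones((3, 8, 8)), geom)

    def test_too_few_lights_rejected(self):
        geom = LightSourceGeometry(directions=[[0, 0, 1.0], [1.0, 0, 0]])
        with pytest.raises(ConfigurationError):
            solve_normals(np.ones((2, 8, 8)), geom)


class TestHighpassNormals:
    def test_planar_tilt_annihilated(self):
        # a pure low-frequency field (constant tilt) collapses to the axis
        n = np.zeros((32, 32, 3))
        n[:, :, 0] = 0.3
        n[:, :, 2] = np.sqrt(1 - 0.09)
        out = highpass_normals(n, sigma=1000.0)
        np.testing.assert_allclose(out[:, :, 0], 0.0, atol=0.02)
        np.testing.assert_allclose(out[:, :, 2], 1.0, atol=0.001)

    def test_output_unit_norm(self):
        rng = np.random.default_rng(6)
        n = rng.standard_normal((16, 16, 3))
        n[:, :, 2] = np.abs(n[:, :, 2]) + 1.0
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        out = highpass_normals(n, sigma=3.0)
        np.testing.assert_allclose(np.linalg.norm(out, axis=-1), 1.0, atol=1e-9)

    def test_high_frequency_content_preserved(self):
        # checkerboard-frequency perturbation survives a wide high-pass
        yy, xx = np.mgrid[0:64, 0:64]
        wiggle = 0.2 * np.cos(np.pi * xx)
        n = np.stack([wiggle, np.zeros_like(wiggle), np.ones_like(wiggle)], axis=-1)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        out = highpass_normals(n, sigma=20.0)
        in_energy = np.sum(n[:, :, 0] ** 2)
        out_energy = np.sum(out[:, :, 0] ** 2)
        assert out_energy > 0.95 * in_energy


class TestPoissonIntegration:
    def test_plane_exact(self):
        h, w = 40, 56
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        plane = 0.31 * xx - 0.17 * yy
        rec = poisson_solve(np.full((h, w), 0.31), np.full((h, w), -0.17))
        assert np.abs(rec - (plane - plane.mean())).max() < 1e-6

    def test_gaussian_bump_round_trip(self):
        h = w = 64
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        bump = np.exp(-(((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 8.0**2)))
        p = np.zeros((h, w))
        q = np.zeros((h, w))
        p[:, :-1] = np.diff(bump, axis=1)
        q[:-1, :] = np.diff(bump, axis=0)
        rec = poisson_solve(p, q)
        truth = bump - bump.mean()
        nrmse = np.sqrt(np.mean((rec - truth) ** 2)) / (truth.max() - truth.min())
        assert nrmse < 1e-3

    def test_rotational_perturbation_ignored(self):
        # discrete Helmholtz: a stream-function curl field lies in the
        # null space of the divergence, leaving the minimizer unchanged
        rng = np.random.default_rng(8)
        h = w = 32
        truth = ndi.gaussian_filter(rng.standard_normal((h, w)), 3.0)
        p = np.zeros((h, w))
        q = np.zeros((h, w))
        p[:, :-1] = np.diff(truth, axis=1)
        q[:-1, :] = np.diff(truth, axis=0)
        base = poisson_solve(p, q)

        psi = rng.standard_normal((h - 1, w - 1))
        pad_y = np.zeros((h + 1, w - 1))
        pad_y[1:h] = psi
        pad_x = np.zeros((h - 1, w + 1))
        pad_x[:, 1:w] = psi
        p2, q2 = p.copy(), q.copy()
        p2[:, :-1] += pad_y[1:] - pad_y[:-1]
        q2[:-1, :] -= pad_x[:, 1:] - pad_x[:, :-1]
        pert = poisson_solve(p2, q2)
        assert np.abs(pert - base).max() < 1e-10

    def test_integrate_height_zero_mean(self, hemisphere_bundle):
        scene, geom, imgs = hemisphere_bundle
        model = solve_normals(imgs, geom)
        height = integrate_height(model.normals)
        assert abs(height.mean()) < 1e-9

    def test_all_masked_rejected(self):
        from mle.frameio import PixelMask

        mask = PixelMask.empty((4, 4))
        mask.flag("out_of_fov", np.ones((4, 4), bool))
        n = np.broadcast_to([0, 0, 1.0], (4, 4, 3)).copy()
        with pytest.raises(ConfigurationError):
            integrate_height(n, mask)


class TestCompareHeight:
    def test_identical_maps_zero_error(self):
        h = np.random.default_rng(9).random((16, 16))
        assert compare_height(h, h, filter_sigma=2.0) == 0.0

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(10)
        h = ndi.gaussian_filter(rng.standard_normal((32, 32)), 2.0)
        hp = h - ndi.gaussian_filter(h, 4.0, mode="nearest")
        hp = hp / np.abs(hp).max()
        expected = 2.0 * np.abs(hp).mean()
        assert compare_height(h, -h, filter_sigma=4.0) == pytest.approx(expected)

    def test_end_to_end_phantom_error_bounded(self, hemisphere_bundle):
        scene, geom, imgs = hemisphere_bundle
        model = solve_normals(imgs, geom)
        height = integrate_height(model.normals)
        mae = compare_height(height, scene.height_map)
        # noiseless phantom pipeline: error well under the 0.1 scale of
        # normalized height units
        assert mae < 0.1


class TestRenderRelit:
    def test_flat_height_uniform_shading(self):
        img = render_relit(np.zeros((8, 8)), np.array([0, 0, 1.0]))
        assert np.allclose(img, img[0, 0])

    def test_lambert_cosine_ordering(self):
        # the slope descending toward the light faces it and shades brighter
        xx = np.arange(32, dtype=float)[None, :] * 0.2
        ramp_up = np.broadcast_to(xx, (32, 32))
        kwargs = dict(albedo=0.8, specular=0.0)
        img_up = render_relit(ramp_up, np.array([1.0, 0, 1.0]), **kwargs)
        img_down = render_relit(-ramp_up, np.array([1.0, 0, 1.0]), **kwargs)
        assert img_down[10:20, 10:20].mean() > img_up[10:20, 10:20].mean()

    def test_output_clamped(self):
        rng = np.random.default_rng(11)
        img = render_relit(
            rng.standard_normal((16, 16)) * 5, np.array([1.0, 1.0, 0.5]),
            albedo=3.0,
        )
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_color_overlay_modulates(self):
        overlay = np.zeros((8, 8, 3))
        overlay[:, :, 0] = 1.0
        img = render_relit(np.zeros((8, 8)), np.array([0, 0, 1.0]), color_overlay=overlay)
        assert img.shape == (8, 8, 3)
        assert img[:, :, 0].mean() > 0
        np.testing.assert_allclose(img[:, :, 1], 0.0)


class TestFullRoundTrip:
    def test_render_solve_integrate_correlation(self, hemisphere_bundle):
        scene, geom, imgs = hemisphere_bundle
        model = solve_normals(imgs, geom)
        height = integrate_height(model.normals)
        sigma = photostereo.scaled_sigma(imgs.shape[2])

        def hp(x):
            return x - ndi.gaussian_filter(x, sigma, mode="nearest")

        a, b = hp(height), hp(scene.height_map)
        corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert corr > 0.99
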