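import numpy as np
import pytest

from mle import phantoms, spectral
from mle.frameio import ConfigurationError, FrameStack, SpectralCube
from mle.phantoms import TissueScene, make_spectral_phantom
from mle.spectral import (
    SystemResponse,
    absorbance,
    denoise_spectral,
    km_absorption,
    normalize_cube,
    sto2_timeseries,
    to_reflectance,
    unmix_chromophores,
)


def _constant_scene(level, n=16, c_total=0.05):
    return TissueScene(
        n, n,
        c_hbo2_map=np.full((n, n), c_total * level),
        c_hb_map=np.full((n, n), c_total * (1 - level)),
        pathlength=2.0,
        offset_map=np.full((n, n), 0.1),
    )


class TestDenoise:
    def test_constant_preserved(self):
        np.testing.assert_allclose(denoise_spectral(np.full((9, 9), 0.4)), 0.4)

    def test_impulse_response_matches_gaussian_kernel(self):
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = denoise_spectral(img)
        x = np.arange(-2, 3)
        g = np.exp(-(x**2) / (2 * 0.5**2))
        g /= g.sum()
        kernel = np.outer(g, g)
        np.testing.assert_allclose(out[3:8, 3:8], kernel, atol=1e-12)
        assert out[5, 5] == pytest.approx(kernel[2, 2])

    def test_interior_sum_conserved(self):
        rng = np.random.default_rng(4)
        img = np.zeros((32, 32))
        img[8:24, 8:24] = rng.random((16, 16))
        assert denoise_spectral(img).sum() == pytest.approx(img.sum(), rel=1e-12)


class TestToReflectance:
    def _stack_from_cube(self, cube, gains, duty):
        frames, labels = [], []
        for i, w in enumerate(cube.wavelengths):
            frames.append(cube.reflectance[:, :, i] * gains[i] * duty[i])
            labels.append(str(w))
        return FrameStack(frames=np.stack(frames), labels=labels)

    def test_intensity_equal_to_response_gives_unit_reflectance(self):
        wl = (406, 446, 468)
        gains = np.array([0.5, 1.0, 2.0])
        duty = np.array([1.0, 0.5, 0.25])
        frames = np.stack([np.full((8, 8), g * d) for g, d in zip(gains, duty)])
        stack = FrameStack(frames=frames, labels=[str(w) for w in wl])
        cube = to_reflectance(stack, SystemResponse(wl, gains, duty))
        np.testing.assert_allclose(cube.reflectance, 1.0)

    def test_reference_equal_to_sample_gives_unit_reflectance(self):
        stack = FrameStack(
            frames=np.stack([np.full((4, 4), 0.3), np.full((4, 4), 0.6)]),
            labels=["406", "446"],
        )
        cube = to_reflectance(stack, reference={406: 0.3, 446: 0.6})
        np.testing.assert_allclose(cube.reflectance, 1.0)

    def test_round_trip_with_known_gains(self, library, tissue_scene):
        truth = make_spectral_phantom(tissue_scene, library)
        gains = np.linspace(0.5, 2.0, truth.n_bands)
        duty = np.linspace(1.0, 0.25, truth.n_bands)
        stack = self._stack_from_cube(truth, gains, duty)
        cube = to_reflectance(
            stack, SystemResponse(truth.wavelengths, gains, duty)
        )
        np.testing.assert_allclose(cube.reflectance, truth.reflectance, atol=1e-12)

    def test_missing_band_rejected(self):
        stack = FrameStack(frames=np.zeros((1, 4, 4)), labels=["406"])
        with pytest.raises(ConfigurationError):
            to_reflectance(stack, reference={446: 1.0})


class TestAbsorbanceAndKM:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 0.0), (0.01, 2.0), (0.501187, 0.3)]
    )
    def test_absorbance_values(self, r, expected):
        cube = SpectralCube(np.full((2, 2, 8), r))
        a, _ = absorbance(cube)
        np.testing.assert_allclose(a, expected, atol=1e-6)

    @pytest.mark.parametrize(
        "r,s,expected", [(1.0, 1.0, 0.0), (0.5, 1.0, 0.25), (0.2, 2.0, 3.2)]
    )
    def test_kubelka_munk_values(self, r, s, expected):
        cube = SpectralCube(np.full((2, 2, 3), r), wavelengths=(406, 446, 468))
        k, _ = km_absorption(cube, np.full(3, s))
        np.testing.assert_allclose(k, expected, atol=1e-12)

    def test_zero_reflectance_masked_not_raised(self):
        refl = np.full((2, 2, 3), 0.5)
        refl[0, 0, :] = 0.0
        cube = SpectralCube(refl, wavelengths=(406, 446, 468))
        _, mask = absorbance(cube)
        assert mask.invalid[0, 0]
        assert not mask.invalid[1, 1]


class TestNormalizeCube:
    def test_max_plus_eps_zero_eps(self):
        cube = SpectralCube(np.full((2, 2, 3), 0.5), wavelengths=(406, 446, 468))
        out = normalize_cube(cube, eps=0.0)
        assert out.reflectance.max() == pytest.approx(1.0)

    def test_strictly_below_one_with_positive_eps(self):
        cube = SpectralCube(
            np.random.default_rng(0).random((4, 4, 3)), wavelengths=(406, 446, 468)
        )
        out = normalize_cube(cube, eps=1e-3)
        assert out.reflectance.max() < 1.0

    def test_band_657_mode_unit_red_channel(self, library, tissue_scene):
        cube = make_spectral_phantom(tissue_scene, library)
        out = normalize_cube(cube, mode="band_657")
        np.testing.assert_allclose(out.band(657), 1.0)

    def test_band_mode_without_657_rejected(self):
        cube = SpectralCube(np.full((2, 2, 3), 0.5), wavelengths=(406, 446, 468))
        with pytest.raises(ConfigurationError):
            normalize_cube(cube, mode="band_657")


class TestUnmix:
    def test_exact_recovery_of_mixture(self, library):
        scene = _constant_scene(0.6)
        cube = make_spectral_phantom(scene, library)
        a, mask = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library, mask=mask)
        np.testing.assert_allclose(cm.sto2, 0.6, atol=1e-9)
        assert cm.residual.max() < 1e-9

    def test_pure_deoxy_gives_zero_sto2(self, library):
        scene = _constant_scene(0.0)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library)
        np.testing.assert_allclose(cm.sto2, 0.0, atol=1e-12)

    def test_sto2_bounded_under_heavy_noise(self, library):
        scene = _constant_scene(0.5, n=24)
        cube = make_spectral_phantom(scene, library, noise_sd=0.2, seed=9)
        a, _ = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library)
        assert np.all(cm.sto2 >= 0.0) and np.all(cm.sto2 <= 1.0)
        assert np.all(cm.c_hbo2 >= 0.0) and np.all(cm.c_hb >= 0.0)

    def test_scale_equivariance(self, library):
        scene = _constant_scene(0.7)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        cm1 = unmix_chromophores(a, cube.wavelengths, library)
        cm2 = unmix_chromophores(3.0 * a, cube.wavelengths, library)
        np.testing.assert_allclose(cm2.c_hbo2, 3.0 * cm1.c_hbo2, rtol=1e-8)
        np.testing.assert_allclose(cm2.sto2, cm1.sto2, atol=1e-9)

    def test_band_permutation_invariance(self, library):
        scene = _constant_scene(0.4, n=8)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        perm = np.array([3, 0, 6, 1, 7, 2, 5, 4])
        wl_perm = tuple(np.array(cube.wavelengths)[perm])
        cm1 = unmix_chromophores(a, cube.wavelengths, library)
        cm2 = unmix_chromophores(a[:, :, perm], wl_perm, library)
        np.testing.assert_allclose(cm1.sto2, cm2.sto2, atol=1e-9)

    def test_melanin_column_in_km_pathway(self, library):
        # forward: KM absorption built from hemoglobin + melanin spectra
        lib = library.at((406, 446, 468, 522, 543, 562, 635, 657))
        n = 8
        c_o, c_d, c_m = 0.3, 0.2, 0.1
        k_true = c_o * lib.epsilon_hbo2 + c_d * lib.epsilon_hb + c_m * lib.epsilon_melanin
        absorb = np.broadcast_to(k_true, (n, n, 8)).copy()
        cm = unmix_chromophores(absorb, lib.wavelengths, library, include_melanin=True)
        np.testing.assert_allclose(cm.c_melanin, c_m, atol=1e-8)
        np.testing.assert_allclose(cm.sto2, c_o / (c_o + c_d), atol=1e-8)

    def test_too_few_bands_rejected(self, library):
        with pytest.raises(ConfigurationError):
            unmix_chromophores(np.zeros((4, 4, 2)), (406, 446), library)


class TestTimeseries:
    def test_constant_field_mean_and_sd(self, library):
        scene = _constant_scene(0.6)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library)
        means, sds = sto2_timeseries([cm], (2, 10, 2, 10))
        assert means[0] == pytest.approx(0.6, abs=1e-9)
        assert sds[0] == pytest.approx(0.0, abs=1e-9)

    def test_occlusion_sequence_tracked(self, library):
        # baseline -> occlusion -> reperfusion, as in a cuff occlusion trial
        truth = [0.60, 0.33, 0.60]
        maps = []
        for level in truth:
            scene = _constant_scene(level, n=16)
            cube = make_spectral_phantom(scene, library, noise_sd=0.01, seed=21)
            a, mask = absorbance(cube)
            maps.append(unmix_chromophores(a, cube.wavelengths, library, mask=mask))
        means, _ = sto2_timeseries(maps, (2, 14, 2, 14))
        np.testing.assert_allclose(means, truth, atol=0.02)

    def test_single_pixel_roi(self, library):
        scene = _constant_scene(0.25, n=8)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library)
        means, sds = sto2_timeseries([cm], (3, 4, 5, 6))
        assert means[0] == pytest.approx(cm.sto2[3, 5])
        assert sds[0] == 0.0

    def test_roi_out_of_bounds_rejected(self, library):
        scene = _constant_scene(0.5, n=8)
        cube = make_spectral_phantom(scene, library)
        a, _ = absorbance(cube)
        cm = unmix_chromophores(a, cube.wavelengths, library)
        with pytest.raises(ConfigurationError):
            sto2_timeseries([cm], (0, 9, 0, 4))
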