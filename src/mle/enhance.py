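"""Spectral contrast enhancement: simulate RGB images from reflectance
cubes and optimize per-band weights to maximize the CIEDE2000 color
difference between lesion and normal tissue samples.

Color images are simulated as ``channel_c = sum_lambda R(., lambda) *
w_c(lambda)`` — the per-band weights playing the role of the camera
transmission times illumination spectrum.  Scores are computed after
per-pixel brightness normalization (maximum channel fixed at 0.8) in
CIE-Lab via a linear-RGB -> XYZ (D65) -> Lab path; the clinical video
processor's gamma is unknown, so no display nonlinearity is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frameio import BAND_WAVELENGTHS, ConfigurationError, SpectralCube

__all__ = [
    "SpectralWeights",
    "LabeledPixelSet",
    "wle_preset",
    "nbi_preset",
    "simulate_color",
    "normalize_pixels",
    "rgb_to_lab",
    "ciede2000",
    "color_difference_score",
    "optimize_weights",
    "dataset_rescale",
]


@dataclass
class SpectralWeights:
    """Non-negative per-band weights for each output color channel."""

    wavelengths: tuple[int, ...]
    weights: np.ndarray  # (B, 3) columns R, G, B

    def __post_init__(self) -> None:
        self.wavelengths = tuple(int(w) for w in self.wavelengths)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.wavelengths), 3):
            raise ConfigurationError("weights must be (n_bands, 3)")
        if np.any(self.weights < 0):
            raise ConfigurationError("weights must be non-negative")
        if np.any(self.weights.sum(axis=0) <= 0):
            raise ConfigurationError("each channel needs at least one nonzero weight")

    def normalized(self) -> "SpectralWeights":
        w = self.weights / self.weights.sum(axis=0, keepdims=True)
        return SpectralWeights(self.wavelengths, w)


@dataclass
class LabeledPixelSet:
    """Sampled pixel coordinates for the normal and lesion tissue classes."""

    normal: np.ndarray  # (n, 2) row, col
    lesion: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=int)
        self.lesion = np.asarray(self.lesion, dtype=int)
        if self.normal.ndim != 2 or self.normal.shape[1] != 2:
            raise ConfigurationError("pixel lists must be (n, 2)")
        if self.lesion.ndim != 2 or self.lesion.shape[1] != 2:
            raise ConfigurationError("pixel lists must be (n, 2)")
        a = {tuple(p) for p in self.normal}
        b = {tuple(p) for p in self.lesion}
        if a & b:
            raise ConfigurationError("normal and lesion samples must be disjoint")

    @classmethod
    def sample(
        cls,
        normal_mask: np.ndarray,
        lesion_mask: np.ndarray,
        n_sample: int = 100,
        seed: int = 0,
    ) -> "LabeledPixelSet":
        """Draw ``n_sample`` pixels per class from annotated region masks."""
        rng = np.random.default_rng(seed)

        def draw(mask_arr: np.ndarray) -> np.ndarray:
            coords = np.argwhere(mask_arr)
            if coords.shape[0] == 0:
                raise ConfigurationError("empty class region")
            idx = rng.choice(coords.shape[0], size=min(n_sample, coords.shape[0]),
                             replace=False)
            return coords[idx]

        if (np.asarray(normal_mask, bool) & np.asarray(lesion_mask, bool)).any():
            raise ConfigurationError("class regions must be disjoint")
        return cls(normal=draw(normal_mask), lesion=draw(lesion_mask))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _gauss(bands: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((bands - center) / sigma) ** 2)


def wle_preset(wavelengths=BAND_WAVELENGTHS) -> SpectralWeights:
    """Broadband white-light preset: smooth Gaussian RGB band responses."""
    bands = np.asarray(wavelengths, dtype=float)
    w = np.column_stack(
        [
            _gauss(bands, 610.0, 50.0),
            _gauss(bands, 540.0, 45.0),
            _gauss(bands, 450.0, 40.0),
        ]
    )
    return SpectralWeights(tuple(wavelengths), w).normalized()


def nbi_preset(wavelengths=BAND_WAVELENGTHS) -> SpectralWeights:
    """Narrow-band-imaging preset.

    The 415 nm hemoglobin band (nearest system bands 406/446 nm) feeds the
    display blue and green channels and the 540 nm band (522/543/562 nm)
    feeds the red channel, following the conventional NBI display mapping.
    """
    bands = np.asarray(wavelengths, dtype=float)
    blue_band = _gauss(bands, 415.0, 15.0)
    green_band = _gauss(bands, 540.0, 15.0)
    w = np.column_stack([green_band, blue_band, blue_band])
    return SpectralWeights(tuple(wavelengths), w).normalized()


# ---------------------------------------------------------------------------
# Simulation and normalization
# ---------------------------------------------------------------------------

def simulate_color(cube: SpectralCube, weights: SpectralWeights) -> np.ndarray:
    """Weighted sum of reflectance bands per output channel."""
    if tuple(weights.wavelengths) != tuple(cube.wavelengths):
        raise ConfigurationError("weights do not cover the cube bands")
    return cube.reflectance @ weights.weights


def normalize_pixels(
    image: np.ndarray, mode: str = "brightness", chroma_max: float = 0.8,
    display_mean: float = 0.4,
) -> np.ndarray:
    """Brightness or display normalization of a 3-channel image.

    ``brightness`` rescales each pixel so its maximum channel equals
    ``chroma_max`` (0.8), removing intensity before color-difference
    computation; ``display`` rescales the whole image to mean intensity
    ``display_mean`` (0.4).  Zero pixels are left at zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ConfigurationError("image must be non-negative")
    if mode == "brightness":
        peak = image.max(axis=-1, keepdims=True)
        return np.where(peak > 0, image * (chroma_max / np.maximum(peak, 1e-300)), 0.0)
    if mode == "display":
        mean = image.mean()
        if mean == 0:
            return image.copy()
        return image * (display_mean / mean)
    raise ConfigurationError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Color space and CIEDE2000
# ---------------------------------------------------------------------------

_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65 = np.array([0.95047, 1.0, 1.08883])


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB (no gamma) -> XYZ under D65 -> CIE-Lab."""
    rgb = np.asarray(rgb, dtype=np.float64)
    xyz = rgb @ _RGB_TO_XYZ.T
    t = xyz / _D65
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """CIEDE2000 color difference (kL = kC = kH = 1), vectorized.

    Full formula with the lightness, chroma, and hue weighting functions
    and the blue-region rotation term.
    """
    lab1 = np.asarray(lab1, dtype=np.float64)
    lab2 = np.asarray(lab2, dtype=np.float64)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    def hue(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        h = np.degrees(np.arctan2(b, a))
        h = np.where(h < 0, h + 360.0, h)
        return np.where((a == 0) & (b == 0), 0.0, h)

    h1p = hue(a1p, b1)
    h2p = hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hdiff = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            hdiff <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    return np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )


# ---------------------------------------------------------------------------
# Scores and optimization
# ---------------------------------------------------------------------------

def _score_from_spectra(
    spectra_normal: np.ndarray,
    spectra_lesion: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Mean pairwise CIEDE2000 between the two sampled classes."""
    rgb_n = normalize_pixels(spectra_normal @ weights)
    rgb_l = normalize_pixels(spectra_lesion @ weights)
    lab_n = rgb_to_lab(rgb_n)
    lab_l = rgb_to_lab(rgb_l)
    de = ciede2000(lab_n[:, None, :], lab_l[None, :, :])
    return float(de.mean())


def color_difference_score(
    image_or_cube: np.ndarray | SpectralCube,
    pixels: LabeledPixelSet,
    weights: SpectralWeights | None = None,
) -> float:
    """Mean CIEDE2000 over all normal x lesion pixel pairs.

    Accepts either a brightness-normalized 3-channel image, or a
    :class:`SpectralCube` plus weights (simulated then normalized here).
    """
    if pixels.normal.size == 0 or pixels.lesion.size == 0:
        raise ConfigurationError("both classes need sampled pixels")
    if isinstance(image_or_cube, SpectralCube):
        if weights is None:
            raise ConfigurationError("weights required with a spectral cube")
        image = normalize_pixels(simulate_color(image_or_cube, weights))
    else:
        image = np.asarray(image_or_cube, dtype=np.float64)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ConfigurationError("expected a 3-channel image")
    rgb_n = image[pixels.normal[:, 0], pixels.normal[:, 1]]
    rgb_l = image[pixels.lesion[:, 0], pixels.lesion[:, 1]]
    lab_n = rgb_to_lab(rgb_n)
    lab_l = rgb_to_lab(rgb_l)
    return float(ciede2000(lab_n[:, None, :], lab_l[None, :, :]).mean())


def optimize_weights(
    cube: SpectralCube,
    pixels: LabeledPixelSet,
    init: SpectralWeights | None = None,
    max_iter: int = 200,
    step: float = 1e-2,
    grad_eps: float = 1e-4,
    tol: float = 1e-8,
) -> tuple[SpectralWeights, np.ndarray]:
    """Projected gradient ascent on the lesion/normal CIEDE2000 score.

    Numerical central-difference gradients with backtracking on the step,
    non-negativity projection, and per-channel sum normalization after each
    step.  Returns the best weights seen and the best-so-far score trace
    (non-decreasing by construction).  Deterministic given the inputs.
    """
    if init is None:
        init = wle_preset(cube.wavelengths)
    if tuple(init.wavelengths) != tuple(cube.wavelengths):
        raise ConfigurationError("init weights do not cover the cube bands")
    spectra_n = cube.reflectance[pixels.normal[:, 0], pixels.normal[:, 1]]
    spectra_l = cube.reflectance[pixels.lesion[:, 0], pixels.lesion[:, 1]]

    def project(w: np.ndarray) -> np.ndarray:
        w = np.maximum(w, 0.0)
        sums = w.sum(axis=0, keepdims=True)
        fallback = np.full_like(w, 1.0 / w.shape[0])
        return np.where(sums > 0, w / np.maximum(sums, 1e-300), fallback)

    w = project(init.weights.copy())
    score = _score_from_spectra(spectra_n, spectra_l, w)
    best_w, best_score = w.copy(), score
    trace = [best_score]
    cur_step = step
    for _ in range(max_iter):
        grad = np.zeros_like(w)
        for i in range(w.shape[0]):
            for c in range(3):
                e = np.zeros_like(w)
                e[i, c] = grad_eps
                up = _score_from_spectra(spectra_n, spectra_l, project(w + e))
                dn = _score_from_spectra(spectra_n, spectra_l, project(w - e))
                grad[i, c] = (up - dn) / (2 * grad_eps)
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break
        improved = False
        while cur_step > 1e-7:
            cand = project(w + cur_step * grad / gnorm)
            cand_score = _score_from_spectra(spectra_n, spectra_l, cand)
            if cand_score > score:
                gain = cand_score - score
                w, score = cand, cand_score
                cur_step *= 1.5
                improved = True
                break
            cur_step *= 0.5
        if score > best_score:
            best_w, best_score = w.copy(), score
        trace.append(best_score)
        if not improved or (len(trace) > 1 and trace[-1] - trace[-2] < tol):
            break
    return SpectralWeights(cube.wavelengths, best_w), np.asarray(trace)


def dataset_rescale(cubes: list[SpectralCube]) -> list[SpectralCube]:
    """Rescale each band to the across-dataset mean intensity of that band.

    Each cube's band is divided by its own mean and multiplied by the mean
    of the band means over the dataset.  This equalizes illumination across
    acquisitions before color simulation; it is never applied before
    chromophore unmixing, which consumes raw reflectance.
    """
    if not cubes:
        raise ConfigurationError("need at least one cube")
    wavelengths = cubes[0].wavelengths
    for c in cubes:
        if tuple(c.wavelengths) != tuple(wavelengths):
            raise ConfigurationError("cubes must share band structure")
    band_means = np.array([c.reflectance.mean(axis=(0, 1)) for c in cubes])
    dataset_mean = band_means.mean(axis=0)
    out = []
    for c, means in zip(cubes, band_means):
        mask = c.mask.copy()
        scale = np.where(means > 0, dataset_mean / np.maximum(means, 1e-300), 0.0)
        zero_bands = means <= 0
        if zero_bands.any():
            mask.flag("underexposed", np.ones(c.shape, dtype=bool))
        out.append(
            SpectralCube(c.reflectance * scale[None, None, :], wavelengths, mask=mask)
        )
    return out
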