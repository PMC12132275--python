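"""Digital phantoms emulating the benchtop validation targets.

Four generator families stand in for the endoscope hardware:

* Beer-Lambert tissue phantoms — spectral reflectance cubes rendered from
  spatial oxy/deoxy-hemoglobin concentration maps,
* dynamic speckle sequences — fully developed speckle whose temporal
  decorrelation rate encodes flow velocity inside a channel mask,
* directionally lit renderings of known height maps (Lambertian, three
  point sources around the optical axis),
* affine-jittered stacks emulating scope motion, and a Macbeth-style
  multi-patch reflectance chart.

Every generator is deterministic given its seed and retains its ground truth
so downstream estimators can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .frameio import (
    BAND_WAVELENGTHS,
    ChromophoreLibrary,
    ConfigurationError,
    FrameStack,
    LightSourceGeometry,
    PixelMask,
    SpectralCube,
)

__all__ = [
    "TissueScene",
    "FlowScene",
    "SurfaceScene",
    "make_spectral_phantom",
    "make_speckle_sequence",
    "render_directional",
    "make_jittered_stack",
    "make_color_chart",
    "default_tissue_scene",
    "default_flow_scene",
    "hemisphere_scene",
    "default_geometry",
]


# ---------------------------------------------------------------------------
# Scene descriptions
# ---------------------------------------------------------------------------

@dataclass
class TissueScene:
    """Spatial chromophore maps feeding the Beer-Lambert forward model.

    Concentrations are in relative units (nominally mM when paired with the
    bundled extinction spectra in mm^-1 mM^-1), ``pathlength`` in mm, and
    ``offset_map`` is the wavelength-independent attenuation offset covering
    scattering loss and other absorbers.
    """

    width: int
    height: int
    c_hbo2_map: np.ndarray
    c_hb_map: np.ndarray
    pathlength: float = 1.0
    offset_map: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.height, self.width)
        self.c_hbo2_map = np.asarray(self.c_hbo2_map, dtype=np.float64)
        self.c_hb_map = np.asarray(self.c_hb_map, dtype=np.float64)
        if self.offset_map is None:
            self.offset_map = np.zeros(shape)
        self.offset_map = np.asarray(self.offset_map, dtype=np.float64)
        if self.lesion_mask is None:
            self.lesion_mask = np.zeros(shape, dtype=bool)
        if self.vessel_mask is None:
            self.vessel_mask = np.zeros(shape, dtype=bool)
        for name in ("c_hbo2_map", "c_hb_map", "offset_map", "lesion_mask", "vessel_mask"):
            if getattr(self, name).shape != shape:
                raise ConfigurationError(f"{name} must have shape {shape}")
        if self.pathlength <= 0:
            raise ConfigurationError("pathlength must be positive")
        if np.any(self.c_hbo2_map < 0) or np.any(self.c_hb_map < 0):
            raise ConfigurationError("concentration maps must be non-negative")

    @property
    def sto2(self) -> np.ndarray:
        total = self.c_hbo2_map + self.c_hb_map
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(total > 0, self.c_hbo2_map / np.maximum(total, 1e-300), np.nan)
        return s


@dataclass
class FlowScene:
    """Flow-channel geometry and temporal decorrelation for speckle synthesis.

    ``velocity`` (mm/s) maps to a per-region decorrelation time (frames) via
    ``decorrelation_time = tau_scale / velocity``; the static background has
    infinite decorrelation time.  Only the monotone velocity->decorrelation
    relationship matters to the contrast estimators, mirroring the
    microvascular range 0.4-2.2 mm/s probed on the microfluidic phantom.
    """

    width: int
    height: int
    channel_mask: np.ndarray
    velocity: float = 1.1
    tau_scale: float = 2.0
    n_frames: int = 1
    speckle_grain: float = 2.0
    exposure_substeps: int = 8
    mean_intensity: float = 0.2
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        if self.channel_mask.shape != (self.height, self.width):
            raise ConfigurationError("channel_mask shape mismatch")
        if self.velocity < 0:
            raise ConfigurationError("velocity must be non-negative")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.speckle_grain < 1.0:
            raise ConfigurationError("speckle_grain < 1 px undersamples the speckle")

    @property
    def decorrelation_time(self) -> float:
        """Channel decorrelation time in frames (inf for zero velocity)."""
        if self.velocity == 0:
            return np.inf
        return self.tau_scale / self.velocity


@dataclass
class SurfaceScene:
    """Known height map with albedo and optional specular sites."""

    height_map: np.ndarray  # (H, W), mm (relative)
    albedo_map: np.ndarray | None = None
    specular_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.height_map = np.asarray(self.height_map, dtype=np.float64)
        if not np.all(np.isfinite(self.height_map)):
            raise ConfigurationError("height_map must be finite")
        if self.albedo_map is None:
            self.albedo_map = np.full(self.height_map.shape, np.pi)
        self.albedo_map = np.asarray(self.albedo_map, dtype=np.float64)
        if np.any(self.albedo_map < 0):
            raise ConfigurationError("albedo_map must be non-negative")
        if self.specular_mask is None:
            self.specular_mask = np.zeros(self.height_map.shape, dtype=bool)
        for name in ("albedo_map", "specular_mask"):
            if getattr(self, name).shape != self.height_map.shape:
                raise ConfigurationError(f"{name} shape mismatch")

    def normals(self) -> np.ndarray:
        """Unit surface normals from central differences (replicate borders).

        Matches the discrete gradient convention of the height integrator so
        render -> solve round trips are exact away from the boundary rows.
        """
        hy, hx = np.gradient(self.height_map)
        n = np.stack([-hx, -hy, np.ones_like(hx)], axis=-1)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        return n


# ---------------------------------------------------------------------------
# Spectral phantom
# ---------------------------------------------------------------------------

def make_spectral_phantom(
    scene: TissueScene,
    library: ChromophoreLibrary,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: tuple[int, ...] = BAND_WAVELENGTHS,
) -> SpectralCube:
    """Render a reflectance cube with the modified Beer-Lambert forward model.

    Per pixel and band, ``R = 10**-((eps_hbo2*c_hbo2 + eps_hb*c_hb)*L + O)``,
    followed by multiplicative Gaussian noise of standard deviation
    ``noise_sd`` and clipping to ``(0, 1]``.
    """
    lib = library.at(wavelengths)  # raises ConfigurationError if uncovered
    absorbance = (
        scene.c_hbo2_map[:, :, None] * lib.epsilon_hbo2[None, None, :]
        + scene.c_hb_map[:, :, None] * lib.epsilon_hb[None, None, :]
    ) * scene.pathlength + scene.offset_map[:, :, None]
    reflectance = np.power(10.0, -absorbance)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        reflectance = reflectance * (
            1.0 + noise_sd * rng.standard_normal(reflectance.shape)
        )
    reflectance = np.clip(reflectance, np.finfo(float).tiny, 1.0)
    return SpectralCube(reflectance=reflectance, wavelengths=wavelengths)


def default_tissue_scene(
    width: int = 64,
    height: int = 64,
    sto2_background: float = 0.6,
    sto2_lesion: float = 0.8,
    total_hb: float = 0.05,
    pathlength: float = 2.0,
    offset: float = 0.1,
) -> TissueScene:
    """Homogeneous mucosa with a circular lesion of elevated oxygenation.

    Defaults emulate colonic mucosa: ~0.05 mM total hemoglobin over a ~2 mm
    effective pathlength with a small scattering offset, background StO2 of
    0.6 against a lesion at 0.8.
    """
    yy, xx = np.mgrid[0:height, 0:width]
    r = min(width, height) / 5.0
    lesion = (xx - width / 2) ** 2 + (yy - height / 2) ** 2 < r**2
    sto2 = np.where(lesion, sto2_lesion, sto2_background)
    return TissueScene(
        width=width,
        height=height,
        c_hbo2_map=total_hb * sto2,
        c_hb_map=total_hb * (1.0 - sto2),
        pathlength=pathlength,
        offset_map=np.full((height, width), offset),
        lesion_mask=lesion,
    )


# ---------------------------------------------------------------------------
# Dynamic speckle
# ---------------------------------------------------------------------------

def _speckle_filter(shape: tuple[int, int], grain: float) -> np.ndarray:
    """Fourier-domain Gaussian low-pass giving correlation length ~grain px."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    # Gaussian aperture: speckle grain ~ 1/(2*cutoff); sigma_f chosen so the
    # intensity autocorrelation width is approximately `grain` pixels.
    sigma_f = 1.0 / (2.0 * np.pi * grain / 2.355)
    return np.exp(-(fx**2 + fy**2) / (2.0 * sigma_f**2))


def make_speckle_sequence(scene: FlowScene, seed: int = 0) -> FrameStack:
    """Synthesize a fully developed dynamic speckle sequence.

    The instantaneous speckle field is a low-pass-filtered circular complex
    Gaussian field (negative-exponential intensity marginal, global contrast
    ~1).  The underlying white field evolves in time by Ornstein-Uhlenbeck
    steps with per-region correlation ``rho = exp(-dt / decorrelation_time)``
    — the channel decorrelates at the rate set by its velocity while the
    background stays frozen.  Each output frame integrates the intensity
    over ``exposure_substeps`` sub-exposures spanning one frame period, so
    motion blurs the speckle within the exposure: local contrast K falls,
    and flow contrast V = 1/K^2 rises, with velocity — the mechanism laser
    speckle contrast imaging reads out.  Filtering is linear, so the
    filtered field inherits the temporal correlation of the white field.
    """
    rng = np.random.default_rng(seed)
    shape = (scene.height, scene.width)
    tau = scene.decorrelation_time
    n_sub = max(int(scene.exposure_substeps), 1)
    dt = 1.0 / n_sub
    if np.isfinite(tau):
        rho = 0.0 if tau == 0 else float(np.exp(-dt / tau))
    else:
        rho = 1.0
    rho_map = np.where(scene.channel_mask, rho, 1.0)
    mix = np.sqrt(1.0 - rho_map**2)
    filt = _speckle_filter(shape, scene.speckle_grain)

    def draw_white() -> np.ndarray:
        return (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        ) / np.sqrt(2.0)

    def speckle_intensity(white_field: np.ndarray) -> np.ndarray:
        field = np.fft.ifft2(np.fft.fft2(white_field) * filt)
        return np.abs(field) ** 2

    white = draw_white()
    static = rho == 1.0 or not scene.channel_mask.any()
    frames = np.empty((scene.n_frames,) + shape)
    norm = None
    for t in range(scene.n_frames):
        if static:
            intensity = speckle_intensity(white)
        else:
            intensity = np.zeros(shape)
            for _ in range(n_sub):
                white = rho_map * white + mix * draw_white()
                intensity += speckle_intensity(white)
            intensity /= n_sub
        if norm is None:
            norm = scene.mean_intensity / intensity.mean()
        intensity = intensity * norm
        if scene.sensor_noise_sd > 0:
            intensity = intensity + scene.sensor_noise_sd * rng.standard_normal(shape)
        frames[t] = np.clip(intensity, 0.0, 1.0)
    return FrameStack(
        frames=frames,
        labels=["speckle"] * scene.n_frames,
        extra={
            "velocity_mm_s": scene.velocity,
            "decorrelation_time_frames": None if not np.isfinite(tau) else tau,
            "speckle_grain_px": scene.speckle_grain,
            "seed": seed,
        },
    )


def default_flow_scene(
    width: int = 128,
    height: int = 128,
    velocity: float = 1.1,
    n_frames: int = 1,
    channel_width_frac: float = 0.25,
    seed_band: str = "horizontal",
) -> FlowScene:
    """Flow channel through a static scattering background.

    The default 1.1 mm/s velocity sits mid-range of microvascular flow
    (0.4-2.2 mm/s); the channel is a horizontal band across the field.
    """
    yy = np.arange(height)[:, None]
    half = channel_width_frac / 2.0
    channel = (yy > height * (0.5 - half)) & (yy < height * (0.5 + half))
    channel = np.broadcast_to(channel, (height, width)).copy()
    return FlowScene(
        width=width,
        height=height,
        channel_mask=channel,
        velocity=velocity,
        n_frames=n_frames,
    )


# ---------------------------------------------------------------------------
# Directional rendering
# ---------------------------------------------------------------------------

def default_geometry(zenith_deg: float = 30.0) -> LightSourceGeometry:
    """Three point sources at 120 degree azimuthal spacing around the axis."""
    z = np.cos(np.deg2rad(zenith_deg))
    s = np.sin(np.deg2rad(zenith_deg))
    dirs = []
    for k in range(3):
        az = np.deg2rad(90.0 + 120.0 * k)
        dirs.append([s * np.cos(az), s * np.sin(az), z])
    return LightSourceGeometry(directions=np.asarray(dirs))


def render_directional(
    scene: SurfaceScene,
    geometry: LightSourceGeometry,
    light_index: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render one directionally illuminated Lambertian image.

    ``I = (rho_d / pi) * max(s_hat . n_hat, 0)`` with normals from central
    differences of the height map.  ``light_index`` is 1-based to match the
    source numbering on the scope tip.  Optional saturating specular blobs
    are added on ``specular_mask`` and Gaussian sensor noise on top.
    """
    if not (1 <= light_index <= geometry.n_lights):
        raise ConfigurationError(
            f"light_index must be in [1, {geometry.n_lights}]"
        )
    n = scene.normals()
    s_hat = geometry.directions[light_index - 1]
    shade = np.clip(n @ s_hat, 0.0, None)
    img = (scene.albedo_map / np.pi) * shade
    if scene.specular_mask.any():
        blob = ndi.gaussian_filter(scene.specular_mask.astype(float), 1.0)
        img = img + 5.0 * blob
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def hemisphere_scene(
    size: int = 96, radius_frac: float = 0.35, bump_height: float = 12.0
) -> SurfaceScene:
    """Smooth hemisphere-like bump on a flat plane (specular-free)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    r = radius_frac * size
    d2 = (xx - c) ** 2 + (yy - c) ** 2
    cap = np.maximum(1.0 - d2 / r**2, 0.0)
    height = bump_height * cap**1.5  # smooth roll-off at the rim
    return SurfaceScene(height_map=height)


# ---------------------------------------------------------------------------
# Affine jitter
# ---------------------------------------------------------------------------

def make_jittered_stack(
    base: np.ndarray,
    transforms: list[dict],
    seed: int = 0,
    labels: list[str] | None = None,
) -> FrameStack:
    """Resample ``base`` under small ground-truth affines (scope motion).

    Each entry of ``transforms`` is a dict with any of ``tx``, ``ty`` (px),
    ``rotation_deg``, ``scale``, ``shear``; translations must stay within
    10 px of identity.  The ground-truth parameters are retained in
    ``extra["transforms"]`` for registration oracles.
    """
    from .preprocess import params_to_matrix, warp_affine

    base = np.asarray(base, dtype=np.float64)
    frames = []
    for params in transforms:
        if abs(params.get("tx", 0.0)) > 10 or abs(params.get("ty", 0.0)) > 10:
            raise ConfigurationError("jitter translations must be <= 10 px")
        frames.append(warp_affine(base, params_to_matrix(params)))
    if labels is None:
        labels = ["white"] * len(frames)
    return FrameStack(
        frames=np.stack(frames),
        labels=labels,
        extra={"transforms": [dict(p) for p in transforms], "seed": seed},
    )


# ---------------------------------------------------------------------------
# Macbeth-style chart
# ---------------------------------------------------------------------------

def make_color_chart(
    n_patches: int = 18,
    seed: int = 0,
    patch_size: int = 16,
    wavelengths: tuple[int, ...] = BAND_WAVELENGTHS,
) -> tuple[SpectralCube, np.ndarray, np.ndarray]:
    """Piecewise-constant reflectance chart with smooth random patch spectra.

    Returns ``(cube, patch_labels, true_spectra)`` where ``patch_labels`` is
    an integer map assigning each pixel its patch index and ``true_spectra``
    is the ``(n_patches, B)`` ground truth in ``(0, 1)``.
    """
    if n_patches < 2:
        raise ConfigurationError("need at least 2 patches")
    rng = np.random.default_rng(seed)
    n_bands = len(wavelengths)
    # smooth spectra: random low-order cosine series squashed into (0.05, 0.95)
    x = np.linspace(0.0, 1.0, n_bands)
    coeffs = rng.normal(size=(n_patches, 3))
    raw = (
        coeffs[:, [0]]
        + coeffs[:, [1]] * np.cos(np.pi * x)[None, :]
        + coeffs[:, [2]] * np.cos(2 * np.pi * x)[None, :]
    )
    spectra = 0.05 + 0.9 / (1.0 + np.exp(-raw))

    n_cols = int(np.ceil(np.sqrt(n_patches)))
    n_rows = int(np.ceil(n_patches / n_cols))
    h, w = n_rows * patch_size, n_cols * patch_size
    labels = np.zeros((h, w), dtype=int)
    cube = np.zeros((h, w, n_bands))
    for cell in range(n_rows * n_cols):
        p = min(cell, n_patches - 1)  # spare cells repeat the final patch
        r, c = divmod(cell, n_cols)
        sl = (slice(r * patch_size, (r + 1) * patch_size),
              slice(c * patch_size, (c + 1) * patch_size))
        labels[sl] = p
        cube[sl[0], sl[1], :] = spectra[p]
    return SpectralCube(reflectance=cube, wavelengths=wavelengths), labels, spectra
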