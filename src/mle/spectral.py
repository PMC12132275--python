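"""Reflectance calibration and chromophore unmixing to StO2 maps.

The core model is the modified Beer-Lambert law: per-pixel absorbance at
wavelength ``lambda`` is

    A(u, v, lambda) = -log10 R(u, v, lambda)
                    = (eps_HbO2(lambda) c_HbO2 + eps_Hb(lambda) c_Hb) L + O

with a wavelength-independent optical pathlength ``L`` and an offset ``O``
absorbing scattering loss and residual absorbers.  Non-negative least
squares recovers the pathlength-scaled concentrations and the offset per
pixel, and total oxygen saturation follows as
``StO2 = c_HbO2 / (c_HbO2 + c_Hb)``.  A Kubelka-Munk pathway converts
reflectance to absorption as ``K = S (1 - R)^2 / (2 R)`` with an explicit
reduced-scattering spectrum, optionally adding a melanin column to the
unmixing design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import nnls

from .frameio import (
    ChromophoreLibrary,
    ConfigurationError,
    FrameStack,
    PixelMask,
    SpectralCube,
)
from .preprocess import register_mi

__all__ = [
    "ChromophoreMap",
    "SystemResponse",
    "denoise_spectral",
    "to_reflectance",
    "absorbance",
    "km_absorption",
    "normalize_cube",
    "unmix_chromophores",
    "sto2_timeseries",
]

#: Reference band (nm) to which the other spectral frames are registered.
REGISTRATION_BAND = 562


@dataclass
class SystemResponse:
    """Per-band system gain and duty cycle.

    ``gains`` aggregates diode output power, Bayer transmissivity, and
    sensor quantum efficiency per band; ``duty_cycles`` the relative diode
    pulse-width lengths.  Both must be strictly positive.
    """

    wavelengths: tuple[int, ...]
    gains: np.ndarray
    duty_cycles: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = tuple(int(w) for w in self.wavelengths)
        self.gains = np.asarray(self.gains, dtype=np.float64)
        self.duty_cycles = np.asarray(self.duty_cycles, dtype=np.float64)
        if self.gains.shape != (len(self.wavelengths),) or self.duty_cycles.shape != (
            len(self.wavelengths),
        ):
            raise ConfigurationError("per-band gains/duty cycles required")
        if np.any(self.gains <= 0) or np.any(self.duty_cycles <= 0):
            raise ConfigurationError("system response must be strictly positive")

    @classmethod
    def flat(cls, wavelengths) -> "SystemResponse":
        n = len(wavelengths)
        return cls(tuple(wavelengths), np.ones(n), np.ones(n))


@dataclass
class ChromophoreMap:
    """Per-pixel unmixing result: concentrations, offset, and StO2."""

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    ls_offset: np.ndarray
    sto2: np.ndarray
    mask: PixelMask
    c_melanin: np.ndarray | None = None
    residual: np.ndarray | None = None


def denoise_spectral(frame: np.ndarray) -> np.ndarray:
    """Suppress electronic and residual speckle noise.

    5x5 Gaussian smoothing with sigma = 0.5 px and replicate borders; the
    kernel is truncated at the 5x5 support.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ConfigurationError("denoise_spectral expects a single-channel frame")
    # truncate = radius / sigma -> radius 2 px gives the 5x5 support
    return ndi.gaussian_filter(frame, sigma=0.5, truncate=4.0, mode="nearest")


def to_reflectance(
    stack: FrameStack,
    response: SystemResponse | None = None,
    reference: dict[int, float] | None = None,
    register: bool = False,
    denoise: bool = False,
) -> SpectralCube:
    """Assemble one spectral cycle of frames into a reflectance cube.

    Intensities are converted to reflectance either by dividing by the
    per-band system response times duty cycle, or by per-band white-reference
    means when ``reference`` is supplied.  With ``register=True`` every band
    is aligned to the 562 nm frame with the mutual-information estimator
    before assembly.  ``denoise`` applies :func:`denoise_spectral` per band.
    """
    wavelengths = sorted({int(lab) for lab in stack.labels if lab.isdigit()})
    if not wavelengths:
        raise ConfigurationError("stack contains no spectral band frames")
    frames: dict[int, np.ndarray] = {}
    for i, lab in enumerate(stack.labels):
        if lab.isdigit():
            frames[int(lab)] = stack.frames[i]
    missing = [w for w in wavelengths if w not in frames]
    if missing:
        raise ConfigurationError(f"missing band frames: {missing}")
    if response is not None:
        for w in wavelengths:
            if w not in response.wavelengths:
                raise ConfigurationError(f"system response missing band {w}")
    if register:
        if REGISTRATION_BAND not in frames:
            raise ConfigurationError(
                f"registration reference band {REGISTRATION_BAND} nm absent"
            )
        ref_frame = frames[REGISTRATION_BAND]
        for w in wavelengths:
            if w == REGISTRATION_BAND:
                continue
            transform = register_mi(frames[w], ref_frame)
            frames[w] = transform.apply(frames[w])

    bands = []
    for w in wavelengths:
        img = frames[w]
        if denoise:
            img = denoise_spectral(img)
        if reference is not None:
            if w not in reference:
                raise ConfigurationError(f"reference means missing band {w}")
            bands.append(img / reference[w])
        elif response is not None:
            i = response.wavelengths.index(w)
            bands.append(img / (response.gains[i] * response.duty_cycles[i]))
        else:
            bands.append(img)
    cube = np.stack(bands, axis=-1)
    return SpectralCube(
        reflectance=np.clip(cube, 0.0, None),
        wavelengths=tuple(wavelengths),
        mask=stack.mask.copy(),
    )


def absorbance(cube: SpectralCube) -> tuple[np.ndarray, PixelMask]:
    """Absorbance ``A = -log10 R``; non-positive reflectance is masked."""
    mask = cube.mask.copy()
    bad = np.any(cube.reflectance <= 0, axis=-1)
    mask.flag("underexposed", bad)
    with np.errstate(divide="ignore"):
        a = -np.log10(np.where(cube.reflectance > 0, cube.reflectance, 1.0))
    return a, mask


def km_absorption(
    cube: SpectralCube, scattering_mu_s: np.ndarray
) -> tuple[np.ndarray, PixelMask]:
    """Kubelka-Munk absorption ``K = S (1 - R)^2 / (2 R)`` per band."""
    s = np.asarray(scattering_mu_s, dtype=np.float64)
    if s.shape != (cube.n_bands,):
        raise ConfigurationError("one scattering coefficient per band required")
    mask = cube.mask.copy()
    r = cube.reflectance
    bad = np.any(r <= 0, axis=-1)
    mask.flag("underexposed", bad)
    safe_r = np.where(r > 0, r, 1.0)
    k = s[None, None, :] * (1.0 - safe_r) ** 2 / (2.0 * safe_r)
    return k, mask


def normalize_cube(
    cube: SpectralCube, mode: str = "max_plus_eps", eps: float = 1e-3
) -> SpectralCube:
    """Keep reflectance within (0, 1).

    ``max_plus_eps`` divides the whole cube by its global maximum plus a
    small constant; ``band_657`` divides each pixel's spectrum by that
    pixel's 657 nm reflectance (the red normalization channel).
    """
    if cube.reflectance.size == 0:
        raise ConfigurationError("empty cube")
    mask = cube.mask.copy()
    if mode == "max_plus_eps":
        scale = cube.reflectance.max() + eps
        out = cube.reflectance / scale
    elif mode == "band_657":
        red = cube.band(657)
        bad = red <= 0
        mask.flag("underexposed", bad)
        out = cube.reflectance / np.where(bad, 1.0, red)[:, :, None]
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    return SpectralCube(out, cube.wavelengths, mask=mask)


def _design_matrix(
    library: ChromophoreLibrary,
    wavelengths,
    include_melanin: bool,
) -> np.ndarray:
    bands = [float(w) for w in wavelengths]
    ordered = sorted(set(bands))
    lib = library.at(ordered)
    idx = [ordered.index(w) for w in bands]  # band order is free
    cols = [lib.epsilon_hbo2[idx], lib.epsilon_hb[idx], np.ones(len(bands))]
    if include_melanin:
        if lib.epsilon_melanin is None:
            raise ConfigurationError("library has no melanin spectrum")
        cols.append(lib.epsilon_melanin[idx])
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigurationError("rank-deficient unmixing design matrix")
    return design


def unmix_chromophores(
    absorption: np.ndarray,
    wavelengths,
    library: ChromophoreLibrary,
    include_melanin: bool = False,
    mask: PixelMask | None = None,
) -> ChromophoreMap:
    """Per-pixel non-negative least squares unmixing.

    The design matrix columns are the oxy- and deoxy-hemoglobin extinction
    spectra, a constant offset column (the pathlength-scaled scattering /
    other-absorber term), and optionally a melanin spectrum.  Pixels are
    solved independently; concentrations are non-negative by construction,
    so StO2 lands in [0, 1] wherever total hemoglobin is positive.  Pixels
    with zero total hemoglobin are masked underexposed.
    """
    absorption = np.asarray(absorption, dtype=np.float64)
    if absorption.ndim != 3:
        raise ConfigurationError("absorption must be (H, W, B)")
    h, w, b = absorption.shape
    if b < 3:
        raise ConfigurationError("need at least 3 bands to unmix")
    design = _design_matrix(library, wavelengths, include_melanin)
    if design.shape[0] != b:
        raise ConfigurationError("band count does not match design matrix")
    mask = mask.copy() if mask is not None else PixelMask.empty((h, w))

    flat = absorption.reshape(-1, b)
    n_coef = design.shape[1]
    coeffs = np.empty((flat.shape[0], n_coef))
    resid = np.empty(flat.shape[0])
    # fast path: unconstrained least squares, valid when already non-negative
    pinv = np.linalg.pinv(design)
    lstsq = flat @ pinv.T
    ok = np.all(lstsq >= 0, axis=1)
    coeffs[ok] = lstsq[ok]
    resid[ok] = np.linalg.norm(lstsq[ok] @ design.T - flat[ok], axis=1)
    for i in np.flatnonzero(~ok):
        coeffs[i], resid[i] = nnls(design, flat[i])

    c_hbo2 = coeffs[:, 0].reshape(h, w)
    c_hb = coeffs[:, 1].reshape(h, w)
    offset = coeffs[:, 2].reshape(h, w)
    c_mel = coeffs[:, 3].reshape(h, w) if include_melanin else None
    total = c_hbo2 + c_hb
    empty = total <= 0
    mask.flag("underexposed", empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(empty, 0.0, c_hbo2 / np.maximum(total, 1e-300))
    return ChromophoreMap(
        c_hbo2=c_hbo2,
        c_hb=c_hb,
        ls_offset=offset,
        sto2=sto2,
        mask=mask,
        c_melanin=c_mel,
        residual=resid.reshape(h, w),
    )


def sto2_timeseries(
    maps: list[ChromophoreMap], roi: tuple[int, int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of StO2 over an ROI for an ordered series of maps.

    ``roi`` is ``(row0, row1, col0, col1)`` (half-open).  Samples with no
    unmasked ROI pixels are returned as NaN.
    """
    r0, r1, c0, c1 = roi
    means, sds = [], []
    for m in maps:
        if not (0 <= r0 < r1 <= m.sto2.shape[0] and 0 <= c0 < c1 <= m.sto2.shape[1]):
            raise ConfigurationError("roi outside map bounds")
        sub = m.sto2[r0:r1, c0:c1]
        valid = m.mask.valid[r0:r1, c0:c1]
        if not valid.any():
            means.append(np.nan)
            sds.append(np.nan)
        else:
            means.append(float(sub[valid].mean()))
            sds.append(float(sub[valid].std()))
    return np.asarray(means), np.asarray(sds)
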