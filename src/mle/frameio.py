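"""Data model and I/O for frame stacks, spectral cubes, spectra, and masks.

All pixel data is stored as floating point in ``[0, 1]``, normalized from the
native bit depth at read time.  The coordinate convention is row-major with
the origin at the top-left corner: ``x`` increases rightward (columns), ``y``
downward (rows), and the camera looks along ``+z``.  Indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "BAND_WAVELENGTHS",
    "ILLUMINATION_LABELS",
    "FormatError",
    "ConfigurationError",
    "FrameStack",
    "SpectralCube",
    "ChromophoreLibrary",
    "LightSourceGeometry",
    "CameraIntrinsics",
    "PixelMask",
    "read_stack",
    "write_stack",
    "read_spectra_csv",
    "default_library",
    "read_geometry",
    "write_geometry",
    "read_intrinsics",
    "build_masks",
]

#: Canonical narrowband illumination wavelengths of the system, in nm.  The
#: red normalization channel is nominally 657-659 nm; it is carried under the
#: single name 657 throughout.
BAND_WAVELENGTHS: tuple[int, ...] = (406, 446, 468, 522, 543, 562, 635, 657)

#: Vocabulary of per-frame illumination labels (the pre-programmed modes).
ILLUMINATION_LABELS: frozenset[str] = frozenset(
    {"white", "directional-1", "directional-2", "directional-3", "speckle"}
    | {str(w) for w in BAND_WAVELENGTHS}
)

MASK_REASONS: tuple[str, ...] = ("saturated", "underexposed", "out_of_fov", "specular")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid parameterization of an operation."""


@dataclass
class PixelMask:
    """Per-pixel validity with reason codes.

    Each reason is an independent boolean field; a pixel is invalid when any
    reason flags it.  Reasons combine, and every map-producing operation is
    expected to propagate the mask rather than drop it.
    """

    shape: tuple[int, int]
    reasons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.reasons.items():
            if name not in MASK_REASONS:
                raise FormatError(f"unknown mask reason {name!r}")
            if arr.shape != tuple(self.shape):
                raise FormatError("mask reason shape mismatch")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(shape=tuple(shape), reasons={})

    def flag(self, reason: str, where: np.ndarray) -> None:
        if reason not in MASK_REASONS:
            raise FormatError(f"unknown mask reason {reason!r}")
        where = np.asarray(where, dtype=bool)
        if where.shape != tuple(self.shape):
            raise FormatError("mask shape mismatch")
        if reason in self.reasons:
            self.reasons[reason] = self.reasons[reason] | where
        else:
            self.reasons[reason] = where.copy()

    @property
    def invalid(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for arr in self.reasons.values():
            out |= arr
        return out

    @property
    def valid(self) -> np.ndarray:
        return ~self.invalid

    def union(self, other: "PixelMask") -> "PixelMask":
        if tuple(other.shape) != tuple(self.shape):
            raise FormatError("mask shape mismatch")
        merged = PixelMask.empty(self.shape)
        for src in (self, other):
            for name, arr in src.reasons.items():
                merged.flag(name, arr)
        return merged

    def copy(self) -> "PixelMask":
        return PixelMask(self.shape, {k: v.copy() for k, v in self.reasons.items()})


@dataclass
class FrameStack:
    """Ordered image frames with per-frame acquisition metadata.

    Parameters
    ----------
    frames : (T, H, W) or (T, H, W, 3) float array
        Intensities in ``[0, 1]``.
    labels : sequence of str
        Illumination label per frame, drawn from :data:`ILLUMINATION_LABELS`.
    parities : sequence of str or None
        Field parity per frame (``"odd"``/``"even"``), for interlaced modes.
    timestamps : sequence of int
        Acquisition index per frame.
    mask : PixelMask
        Shared validity mask (frame-shaped).
    extra : dict
        Free-form metadata (e.g. phantom ground truth), JSON-serializable.
    """

    frames: np.ndarray
    labels: list[str]
    parities: list[str | None] | None = None
    timestamps: list[int] | None = None
    mask: PixelMask | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim not in (3, 4):
            raise FormatError("frames must be (T, H, W) or (T, H, W, 3)")
        n = self.frames.shape[0]
        if len(self.labels) != n:
            raise FormatError("one illumination label per frame required")
        for lab in self.labels:
            if lab not in ILLUMINATION_LABELS:
                raise FormatError(f"unknown illumination label {lab!r}")
        if self.parities is None:
            self.parities = [None] * n
        if self.timestamps is None:
            self.timestamps = list(range(n))
        if self.mask is None:
            self.mask = PixelMask.empty(self.frame_shape)
        if tuple(self.mask.shape) != self.frame_shape:
            raise FormatError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:3])

    def __len__(self) -> int:
        return self.n_frames

    def select(self, indices: Sequence[int]) -> "FrameStack":
        idx = list(indices)
        return FrameStack(
            frames=self.frames[idx],
            labels=[self.labels[i] for i in idx],
            parities=[self.parities[i] for i in idx],
            timestamps=[self.timestamps[i] for i in idx],
            mask=self.mask.copy(),
            extra=dict(self.extra),
        )


@dataclass
class SpectralCube:
    """Per-pixel reflectance at named narrowband wavelengths."""

    reflectance: np.ndarray  # (H, W, B)
    wavelengths: tuple[int, ...] = BAND_WAVELENGTHS
    mask: PixelMask | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise FormatError("reflectance must be (H, W, B)")
        self.wavelengths = tuple(int(w) for w in self.wavelengths)
        if self.reflectance.shape[2] != len(self.wavelengths):
            raise FormatError("band count does not match wavelength list")
        if not np.all(np.isfinite(self.reflectance)):
            raise FormatError("reflectance must be finite")
        if np.any(self.reflectance < 0):
            raise FormatError("reflectance must be non-negative")
        if self.mask is None:
            self.mask = PixelMask.empty(self.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.reflectance.shape[:2])

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    def band(self, wavelength: int) -> np.ndarray:
        try:
            i = self.wavelengths.index(int(wavelength))
        except ValueError as exc:
            raise ConfigurationError(
                f"band {wavelength} nm not present in cube"
            ) from exc
        return self.reflectance[:, :, i]


@dataclass
class ChromophoreLibrary:
    """Extinction/absorption spectra of the tissue chromophores.

    ``epsilon_hbo2``/``epsilon_hb`` are molar extinction coefficients of oxy-
    and deoxy-hemoglobin on the ``wavelengths`` grid (here mm^-1 mM^-1; the
    pipeline only uses relative concentrations, so any consistent unit works).
    Optional melanin absorption and reduced scattering spectra support the
    Kubelka-Munk pathway.
    """

    wavelengths: np.ndarray
    epsilon_hbo2: np.ndarray
    epsilon_hb: np.ndarray
    epsilon_melanin: np.ndarray | None = None
    scattering_mu_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 1:
            raise FormatError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelength grid must be strictly increasing")
        for name in ("epsilon_hbo2", "epsilon_hb"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != self.wavelengths.shape:
                raise FormatError(f"{name} must match the wavelength grid")
            if np.any(arr <= 0):
                raise FormatError(f"{name} must be strictly positive")
            setattr(self, name, arr)
        for name in ("epsilon_melanin", "scattering_mu_s"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != self.wavelengths.shape:
                    raise FormatError(f"{name} must match the wavelength grid")
                setattr(self, name, arr)

    def _interp(self, values: np.ndarray, bands: Sequence[float]) -> np.ndarray:
        bands = np.asarray(bands, dtype=np.float64)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(bands < lo) or np.any(bands > hi):
            raise ConfigurationError(
                f"requested band outside spectral grid [{lo}, {hi}] nm"
            )
        return np.interp(bands, self.wavelengths, values)

    def at(self, bands: Sequence[float]) -> "ChromophoreLibrary":
        """Linearly interpolate every spectrum onto ``bands``."""
        return ChromophoreLibrary(
            wavelengths=np.asarray(bands, dtype=np.float64),
            epsilon_hbo2=self._interp(self.epsilon_hbo2, bands),
            epsilon_hb=self._interp(self.epsilon_hb, bands),
            epsilon_melanin=(
                None
                if self.epsilon_melanin is None
                else self._interp(self.epsilon_melanin, bands)
            ),
            scattering_mu_s=(
                None
                if self.scattering_mu_s is None
                else self._interp(self.scattering_mu_s, bands)
            ),
        )


@dataclass
class LightSourceGeometry:
    """Pre-calibrated unit direction vectors of the point sources.

    Directions point from the surface toward each light, in camera
    coordinates (x right, y down, z toward the camera/light plane).
    """

    directions: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=np.float64)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise FormatError("directions must be (N, 3)")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise FormatError("light directions must be unit vectors")

    @property
    def n_lights(self) -> int:
        return self.directions.shape[0]


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics with radial/tangential distortion coefficients."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0


# ---------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "labels": stack.labels,
        "parities": stack.parities,
        "timestamps": stack.timestamps,
        "mask_reasons": {
            k: np.flatnonzero(v.ravel()).tolist() for k, v in stack.mask.reasons.items()
        },
        "extra": stack.extra,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF stack with its JSON sidecar.

    Integer TIFFs are normalized to ``[0, 1]`` by the full range of their bit
    depth (e.g. ``1/65535`` for 16-bit); float TIFFs are taken as-is.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    shape = tuple(data.shape[1:3])
    mask = PixelMask.empty(shape)
    for reason, flat_idx in meta.get("mask_reasons", {}).items():
        arr = np.zeros(shape, dtype=bool)
        if flat_idx:
            arr.ravel()[np.asarray(flat_idx, dtype=int)] = True
        mask.flag(reason, arr)
    return FrameStack(
        frames=data,
        labels=list(meta["labels"]),
        parities=list(meta.get("parities") or [None] * data.shape[0]),
        timestamps=list(meta.get("timestamps") or range(data.shape[0])),
        mask=mask,
        extra=meta.get("extra", {}),
    )


# ---------------------------------------------------------------------------
# Spectra and geometry I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> ChromophoreLibrary:
    """Read a chromophore spectra CSV.

    Required columns: ``wavelength_nm``, ``eps_hbo2``, ``eps_hb``; optional:
    ``eps_melanin``, ``mu_s_prime``.
    """
    df = pd.read_csv(path)
    required = {"wavelength_nm", "eps_hbo2", "eps_hb"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"spectra CSV missing columns {sorted(missing)}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError("wavelength column must be strictly increasing")
    return ChromophoreLibrary(
        wavelengths=wl,
        epsilon_hbo2=df["eps_hbo2"].to_numpy(dtype=float),
        epsilon_hb=df["eps_hb"].to_numpy(dtype=float),
        epsilon_melanin=(
            df["eps_melanin"].to_numpy(dtype=float) if "eps_melanin" in df else None
        ),
        scattering_mu_s=(
            df["mu_s_prime"].to_numpy(dtype=float) if "mu_s_prime" in df else None
        ),
    )


def default_library() -> ChromophoreLibrary:
    """Bundled hemoglobin/melanin/scattering spectra (mm^-1 mM^-1, mm^-1)."""
    from importlib.resources import files

    return read_spectra_csv(files("mle.data") / "hemoglobin_extinction.csv")


def write_geometry(geometry: LightSourceGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"directions": geometry.directions.tolist()}))


def read_geometry(path: str | Path) -> LightSourceGeometry:
    meta = json.loads(Path(path).read_text())
    return LightSourceGeometry(directions=np.asarray(meta["directions"], dtype=float))


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    meta = json.loads(Path(path).read_text())
    return CameraIntrinsics(**meta)


# ---------------------------------------------------------------------------
# Exposure masks
# ---------------------------------------------------------------------------

def build_masks(
    frame: np.ndarray,
    sat_threshold: float = 0.98,
    under_threshold: float = 0.02,
) -> PixelMask:
    """Flag saturated (``>= sat_threshold``) and underexposed pixels.

    Defaults follow the convention that pixel values live in ``[0, 1]``.
    """
    if not (0.0 < under_threshold < sat_threshold < 1.0 or
            (0.0 < under_threshold and under_threshold < sat_threshold <= 1.0)):
        raise ConfigurationError("thresholds must satisfy 0 < under < sat <= 1")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:
        level = frame.max(axis=-1)
        low = frame.max(axis=-1)
    else:
        level = frame
        low = frame
    mask = PixelMask.empty(level.shape)
    mask.flag("saturated", level >= sat_threshold)
    mask.flag("underexposed", low <= under_threshold)
    return mask
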