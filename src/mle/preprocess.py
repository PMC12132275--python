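"""Frame preprocessing: dark subtraction, deinterlacing, undistortion,
inter-frame affine registration, and the auto-exposure update rule.

Registration conventions
------------------------
Affine transforms act about the image center on ``(x, y)`` pixel coordinates
(x rightward, y downward) and map the *moving* image into the frame of the
*fixed* image.  The parameterization is ``(tx, ty, rotation_deg, scale,
shear)``.  Two estimators are provided: a mutual-information criterion
(64-bin soft joint histogram, coarse-to-fine pyramid) used to align
multispectral bands, and a mean-square-error criterion (gradient descent
with step halving) used for speckle-mode white-light frames and directional
triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import interp1d
from scipy.optimize import minimize

from .frameio import CameraIntrinsics, ConfigurationError, PixelMask

__all__ = [
    "AffineTransform",
    "dark_subtract",
    "deinterlace",
    "undistort",
    "register_mi",
    "register_mse",
    "autoexposure_update",
]


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("tx", "ty", "rotation_deg", "scale", "shear")
# characteristic scales used to condition the optimizers
_PARAM_SCALES = np.array([1.0, 1.0, 0.5, 0.005, 0.005])


def params_to_matrix(params: dict) -> np.ndarray:
    """2x3 matrix from (tx, ty, rotation_deg, scale, shear)."""
    tx = float(params.get("tx", 0.0))
    ty = float(params.get("ty", 0.0))
    rot = np.deg2rad(float(params.get("rotation_deg", 0.0)))
    scale = float(params.get("scale", 1.0))
    shear = float(params.get("shear", 0.0))
    c, s = np.cos(rot), np.sin(rot)
    lin = scale * np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]])
    return np.hstack([lin, np.array([[tx], [ty]])])


@dataclass
class AffineTransform:
    """2x3 affine in pixel coordinates, acting about the image center."""

    matrix: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (2, 3):
            raise ConfigurationError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) <= 1e-8:
            raise ConfigurationError("affine linear part must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @classmethod
    def from_params(cls, **params: float) -> "AffineTransform":
        unknown = set(params) - set(_PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown affine parameters {sorted(unknown)}")
        return cls(params_to_matrix(params))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2].copy()

    @property
    def rotation_deg(self) -> float:
        lin = self.matrix[:, :2]
        return float(np.rad2deg(np.arctan2(lin[1, 0], lin[0, 0])))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        a, b = self.matrix, other.matrix
        lin = a[:, :2] @ b[:, :2]
        t = a[:, :2] @ b[:, 2] + a[:, 2]
        return AffineTransform(np.hstack([lin, t[:, None]]))

    def inverse(self) -> "AffineTransform":
        lin = np.linalg.inv(self.matrix[:, :2])
        t = -lin @ self.matrix[:, 2]
        return AffineTransform(np.hstack([lin, t[:, None]]))

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``image`` under this transform (inverse mapping)."""
        return warp_affine(image, self.matrix, order=order)

    def warp_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean field of output pixels whose source lies inside ``shape``."""
        h, w = shape
        src_y, src_x = _source_coords(shape, self.matrix)
        return (src_x >= 0) & (src_x <= w - 1) & (src_y >= 0) & (src_y <= h - 1)


def _source_coords(shape: tuple[int, int], matrix: np.ndarray):
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    inv_lin = np.linalg.inv(matrix[:, :2])
    t = matrix[:, 2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx = xx - cx - t[0]
    dy = yy - cy - t[1]
    src_x = inv_lin[0, 0] * dx + inv_lin[0, 1] * dy + cx
    src_y = inv_lin[1, 0] * dx + inv_lin[1, 1] * dy + cy
    return src_y, src_x


def warp_affine(image: np.ndarray, matrix: np.ndarray, order: int = 1) -> np.ndarray:
    """Apply a 2x3 forward affine about the image center, bilinear sampling."""
    image = np.asarray(image, dtype=np.float64)
    src_y, src_x = _source_coords(image.shape[:2], matrix)
    if image.ndim == 2:
        return ndi.map_coordinates(image, [src_y, src_x], order=order, mode="nearest")
    out = np.empty_like(image)
    for b in range(image.shape[2]):
        out[:, :, b] = ndi.map_coordinates(
            image[:, :, b], [src_y, src_x], order=order, mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# Elementary preprocessing
# ---------------------------------------------------------------------------

def dark_subtract(frame: np.ndarray, dark_frame: np.ndarray) -> np.ndarray:
    """Remove the dark-current contribution: ``clip(frame - dark, 0, 1)``."""
    frame = np.asarray(frame, dtype=np.float64)
    dark_frame = np.asarray(dark_frame, dtype=np.float64)
    if frame.shape != dark_frame.shape:
        raise ConfigurationError("frame and dark frame shapes differ")
    return np.clip(frame - dark_frame, 0.0, 1.0)


def deinterlace(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split odd and even scan-line fields and resize each to full height.

    Row indices are 0-based; rows 0, 2, 4, ... carry the odd field in the
    1-based video convention and rows 1, 3, ... the even field.  Each field
    is vertically interpolated back to the original height (linear, edge
    replication), so decimating an output at its own parity recovers the
    original field rows exactly.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h = frame.shape[0]
    if h < 2:
        raise ConfigurationError("need at least 2 rows to deinterlace")
    rows = np.arange(h)

    def expand(start: int) -> np.ndarray:
        known = np.arange(start, h, 2)
        f = interp1d(
            known,
            frame[known],
            axis=0,
            bounds_error=False,
            fill_value=(frame[known[0]], frame[known[-1]]),
        )
        return f(rows)

    return expand(0), expand(1)


def undistort(
    frame: np.ndarray, intrinsics: CameraIntrinsics
) -> tuple[np.ndarray, PixelMask]:
    """Remove radial/tangential lens distortion by inverse mapping.

    For each undistorted output pixel the corresponding distorted source
    location is computed with the standard Brown-Conrady model and sampled
    bilinearly; output pixels whose source falls outside the frame are
    flagged ``out_of_fov``.
    """
    if intrinsics is None:
        raise ConfigurationError("camera intrinsics are required")
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    x = (xx - intrinsics.cx) / intrinsics.fx
    y = (yy - intrinsics.cy) / intrinsics.fy
    r2 = x**2 + y**2
    radial = 1.0 + intrinsics.k1 * r2 + intrinsics.k2 * r2**2 + intrinsics.k3 * r2**3
    x_d = x * radial + 2 * intrinsics.p1 * x * y + intrinsics.p2 * (r2 + 2 * x**2)
    y_d = y * radial + intrinsics.p1 * (r2 + 2 * y**2) + 2 * intrinsics.p2 * x * y
    src_x = x_d * intrinsics.fx + intrinsics.cx
    src_y = y_d * intrinsics.fy + intrinsics.cy
    eps = 1e-6  # tolerate round-off at the exact frame border
    inside = (
        (src_x >= -eps) & (src_x <= w - 1 + eps)
        & (src_y >= -eps) & (src_y <= h - 1 + eps)
    )
    if frame.ndim == 2:
        out = ndi.map_coordinates(frame, [src_y, src_x], order=1, mode="nearest")
    else:
        out = np.stack(
            [
                ndi.map_coordinates(frame[:, :, b], [src_y, src_x], order=1, mode="nearest")
                for b in range(frame.shape[2])
            ],
            axis=-1,
        )
    mask = PixelMask.empty((h, w))
    mask.flag("out_of_fov", ~inside)
    return out, mask


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "pyramid_levels": 3,
    "max_iter": 200,
    "bins": 64,
    "margin": 8,
    "estimate": ("tx", "ty", "rotation_deg", "scale"),
}


def _pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    out = [image]
    for _ in range(levels - 1):
        smoothed = ndi.gaussian_filter(out[-1], 1.0)
        out.append(smoothed[::2, ::2])
    return out[::-1]  # coarse to fine


def _crop(image: np.ndarray, margin: int) -> np.ndarray:
    m = max(min(margin, (min(image.shape) - 4) // 2), 0)
    return image[m : image.shape[0] - m, m : image.shape[1] - m] if m else image


def _mse_metric(moving: np.ndarray, fixed: np.ndarray, matrix: np.ndarray,
                margin: int) -> float:
    warped = warp_affine(moving, matrix)
    diff = _crop(warped - fixed, margin)
    return float(np.mean(diff**2))


def _soft_hist2d(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray:
    """Joint histogram with bilinear (partial-volume) binning.

    Soft binning makes the histogram - hence mutual information - vary
    continuously with subpixel warps.
    """
    a = np.clip(a.ravel(), 0.0, 1.0) * (bins - 1)
    b = np.clip(b.ravel(), 0.0, 1.0) * (bins - 1)
    ia, ib = np.floor(a).astype(int), np.floor(b).astype(int)
    fa, fb = a - ia, b - ib
    ia1 = np.minimum(ia + 1, bins - 1)
    ib1 = np.minimum(ib + 1, bins - 1)
    hist = np.zeros((bins, bins))
    np.add.at(hist, (ia, ib), (1 - fa) * (1 - fb))
    np.add.at(hist, (ia, ib1), (1 - fa) * fb)
    np.add.at(hist, (ia1, ib), fa * (1 - fb))
    np.add.at(hist, (ia1, ib1), fa * fb)
    return hist


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    hist = _soft_hist2d(a, b, bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _vector_to_params(vec: np.ndarray, names: tuple[str, ...]) -> dict:
    params = {}
    for name, value in zip(names, vec):
        params[name] = value + (1.0 if name == "scale" else 0.0)
    return params


def _params_to_vector(params: dict, names: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [params.get(n, 0.0) - (1.0 if n == "scale" else 0.0) for n in names]
    )


def _register(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: dict | None,
    metric: str,
) -> AffineTransform:
    cfg = dict(_DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    names = tuple(cfg["estimate"])
    scales = np.array([_PARAM_SCALES[_PARAM_NAMES.index(n)] for n in names])
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.ndim != 2 or fixed.ndim != 2:
        raise ConfigurationError("registration expects single-channel images")

    levels = int(cfg["pyramid_levels"])
    pyr_m = _pyramid(moving, levels)
    pyr_f = _pyramid(fixed, levels)
    vec = np.zeros(len(names))  # offsets from identity, full-resolution units
    diagnostics: dict = {"metric": metric, "converged": True}

    for level, (m_img, f_img) in enumerate(zip(pyr_m, pyr_f)):
        down = 2 ** (levels - 1 - level)
        margin = max(int(cfg["margin"]) // down, 2)

        def level_vec(v: np.ndarray) -> np.ndarray:
            out = v.copy()
            for i, n in enumerate(names):
                if n in ("tx", "ty"):
                    out[i] = v[i] / down
            return out

        def objective(scaled: np.ndarray) -> float:
            v = np.atleast_1d(scaled) * scales_level
            params = _vector_to_params(v, names)
            matrix = params_to_matrix(params)
            if metric == "mse":
                return _mse_metric(m_img, f_img, matrix, margin)
            warped = warp_affine(m_img, matrix)
            return -_mutual_information(
                _crop(warped, margin), _crop(f_img, margin), int(cfg["bins"])
            )

        scales_level = scales.copy()
        x0 = level_vec(vec) / scales_level

        if metric == "mse":
            x, info = _gradient_descent(objective, x0, int(cfg["max_iter"]))
            diagnostics[f"level_{level}"] = info
            if not info["converged"]:
                diagnostics["converged"] = False
        else:
            res = minimize(
                objective,
                x0,
                method="Powell",
                options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": int(cfg["max_iter"])},
            )
            x = res.x
            diagnostics[f"level_{level}"] = {
                "fun": float(res.fun),
                "nfev": int(res.nfev),
                "converged": bool(res.success),
            }
            if not res.success:
                diagnostics["converged"] = False

        v = np.atleast_1d(x) * scales_level
        for i, n in enumerate(names):
            if n in ("tx", "ty"):
                v[i] *= down
        vec = v

    params = _vector_to_params(vec, names)
    diagnostics["params"] = params
    return AffineTransform(params_to_matrix(params), diagnostics=diagnostics)


def _gradient_descent(objective, x0: np.ndarray, max_iter: int) -> tuple[np.ndarray, dict]:
    """Plain descent on a numerical gradient with step-halving line search."""
    x = np.asarray(x0, dtype=float).copy()
    f = objective(x)
    step = 1.0
    eps = 1e-3
    converged = False
    it = 0
    for it in range(max_iter):
        grad = np.zeros_like(x)
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = eps
            grad[i] = (objective(x + e) - objective(x - e)) / (2 * eps)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            converged = True
            break
        direction = -grad / gnorm
        improved = False
        while step > 1e-6:
            cand = x + step * direction
            fc = objective(cand)
            if fc < f:
                rel = (f - fc) / max(abs(f), 1e-300)
                x, f = cand, fc
                step *= 1.5
                improved = True
                if rel < 1e-6:
                    converged = True
                break
            step *= 0.5
        if not improved or converged:
            converged = converged or not improved
            break
    return x, {"fun": float(f), "iterations": it + 1, "converged": bool(converged)}


def register_mse(
    moving: np.ndarray, fixed: np.ndarray, config: dict | None = None
) -> AffineTransform:
    """Affine registration minimizing mean square error.

    Gradient descent with step halving on a coarse-to-fine pyramid; returns
    the transform mapping ``moving`` into the frame of ``fixed``.  A
    non-converged optimization is flagged in ``diagnostics["converged"]``,
    never raised.
    """
    return _register(moving, fixed, config, metric="mse")


def register_mi(
    moving: np.ndarray, fixed: np.ndarray, config: dict | None = None
) -> AffineTransform:
    """Affine registration maximizing a 64-bin mutual-information criterion.

    Suited to aligning bands with band-dependent contrast (the multispectral
    cycle is aligned to its 562 nm frame with this estimator).
    """
    return _register(moving, fixed, config, metric="mi")


# ---------------------------------------------------------------------------
# Auto-exposure
# ---------------------------------------------------------------------------

def autoexposure_update(
    history: list[tuple[float, float]],
    target_intensity: float,
    bounds: tuple[float, float] = (1e-4, 1.0),
    tolerance: float = 0.01,
) -> float:
    """Next laser pulse width from a secant root-solving step.

    Solves ``observed(pw) = target`` using the last two (pulse_width,
    observed_mean_intensity) samples.  When the two observations coincide
    (flat response), falls back to a proportional step that rescales the
    pulse width by ``target/observed``.  The result is clipped to ``bounds``.
    """
    if len(history) < 2:
        raise ConfigurationError("need at least 2 history points")
    if not (0.0 < target_intensity < 1.0):
        raise ConfigurationError("target intensity must be in (0, 1)")
    (pw0, obs0), (pw1, obs1) = history[-2], history[-1]
    if pw0 == pw1:
        distinct = [(p, o) for p, o in history[:-1] if p != pw1]
        if not distinct:
            raise ConfigurationError("history must contain distinct pulse widths")
        pw0, obs0 = distinct[-1]
    if abs(obs1 - target_intensity) <= tolerance:
        return float(np.clip(pw1, *bounds))
    f0 = obs0 - target_intensity
    f1 = obs1 - target_intensity
    if abs(f1 - f0) < 1e-9:
        if obs1 <= 0:
            return float(bounds[1])
        pw_next = pw1 * target_intensity / obs1
    else:
        pw_next = pw1 - f1 * (pw1 - pw0) / (f1 - f0)
    return float(np.clip(pw_next, *bounds))
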