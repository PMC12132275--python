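"""Photometric-stereo surface recovery from directionally illuminated frames.

Under a distant-light Lambertian model each measured intensity is
``I_n = (rho_d / pi) * (s_hat_n . n_hat)``, so the N intensities at a pixel
form a linear system ``I = S n_vec`` whose least-squares solution gives a
non-unit normal ``n_vec`` with direction ``n_hat`` and magnitude
``rho_d / pi``.  Near-camera anisotropic sources violate the distant-light
assumption at low spatial frequencies; that error is suppressed by
subtracting a large-sigma Gaussian low-pass from the normal field before
projecting to gradients and integrating the height with a Poisson solve
(Neumann boundaries, zero-mean gauge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.fft import dctn, idctn

from .frameio import ConfigurationError, LightSourceGeometry, PixelMask
from .preprocess import register_mse

__all__ = [
    "SurfaceModel",
    "inpaint_speculars",
    "solve_normals",
    "highpass_normals",
    "poisson_solve",
    "integrate_height",
    "compare_height",
    "render_relit",
]

#: High-pass sigma (px) at the native 1350 px frame width; it scales
#: proportionally with image width for smaller inputs.
SIGMA_FULL_FRAME = 150.0
NATIVE_WIDTH = 1350.0


def scaled_sigma(width: int, sigma_full: float = SIGMA_FULL_FRAME) -> float:
    """Equivalent high-pass sigma for an image of the given width."""
    return sigma_full * width / NATIVE_WIDTH


@dataclass
class SurfaceModel:
    """Per-pixel unit normals, albedo, and (optionally) integrated height."""

    normals: np.ndarray  # (H, W, 3), unit vectors
    albedo: np.ndarray  # (H, W), rho_d
    mask: PixelMask
    height: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Specular inpainting
# ---------------------------------------------------------------------------

def inpaint_speculars(
    frame: np.ndarray, mask_threshold: float = 0.95, dilate: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Replace specular highlights by harmonic interpolation.

    Pixels above ``mask_threshold`` (after ``dilate``-pixel dilation of the
    thresholded set) are filled with the solution of the Laplace equation
    with the surrounding pixels as Dirichlet boundary.  Returns the filled
    frame and the specular mask.  A warning diagnostic is emitted when more
    than 20% of the frame is specular.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ConfigurationError("inpaint_speculars expects a single-channel frame")
    spec = frame > mask_threshold
    if dilate > 0 and spec.any():
        spec = ndi.binary_dilation(spec, iterations=dilate)
    if not spec.any():
        return frame.copy(), spec
    if spec.mean() > 0.2:
        warnings.warn(
            f"{spec.mean():.0%} of pixels flagged specular; inpainting may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    out = frame.copy()
    h, w = frame.shape
    idx = -np.ones((h, w), dtype=int)
    holes = np.flatnonzero(spec.ravel())
    idx.ravel()[holes] = np.arange(holes.size)
    rows, cols, data = [], [], []
    rhs = np.zeros(holes.size)
    hy, hx = np.unravel_index(holes, (h, w))
    for k, (i, j) in enumerate(zip(hy, hx)):
        deg = 0
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < h and 0 <= nj < w):
                continue  # Neumann at the image border
            deg += 1
            if spec[ni, nj]:
                rows.append(k)
                cols.append(idx[ni, nj])
                data.append(-1.0)
            else:
                rhs[k] += frame[ni, nj]
        rows.append(k)
        cols.append(k)
        data.append(float(deg))
    lap = sp.csr_matrix((data, (rows, cols)), shape=(holes.size, holes.size))
    fill = spla.spsolve(lap.tocsc(), rhs)
    out.ravel()[holes] = fill
    return out, spec


# ---------------------------------------------------------------------------
# Normal estimation
# ---------------------------------------------------------------------------

def solve_normals(
    images: np.ndarray,
    geometry: LightSourceGeometry,
    register: bool = False,
    inpaint: bool = False,
    specular_threshold: float = 0.95,
    config: dict | None = None,
) -> SurfaceModel:
    """Per-pixel least-squares photometric stereo.

    ``images`` is ``(N, H, W)`` with one frame per light source.  With
    ``register=True`` frames 2..N are MSE-registered to the first; with
    ``inpaint=True`` speculars are harmonically filled first.  Albedo is
    ``pi * |n_vec|``; pixels with vanishing ``|n_vec|`` are masked.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ConfigurationError("images must be (N, H, W)")
    n_img = images.shape[0]
    if n_img < 3:
        raise ConfigurationError("photometric stereo needs at least 3 lights")
    if geometry.n_lights != n_img:
        raise ConfigurationError("one light direction per image required")
    s_mat = geometry.directions
    if np.linalg.matrix_rank(s_mat) < 3:
        raise ConfigurationError("light directions must span 3 dimensions")

    mask = PixelMask.empty(images.shape[1:])
    processed = []
    for i in range(n_img):
        img = images[i]
        if inpaint:
            img, spec = inpaint_speculars(img, specular_threshold)
            mask.flag("specular", spec)
        processed.append(img)
    if register:
        for i in range(1, n_img):
            t = register_mse(processed[i], processed[0], config)
            processed[i] = t.apply(processed[i])
            mask.flag("out_of_fov", ~t.warp_mask(processed[i].shape))
    stack = np.stack(processed)

    h, w = stack.shape[1:]
    pinv = np.linalg.pinv(s_mat)  # (3, N)
    n_vec = np.einsum("kn,nhw->hwk", pinv, stack)
    mag = np.linalg.norm(n_vec, axis=-1)
    degenerate = mag < 1e-8
    mask.flag("underexposed", degenerate)
    normals = n_vec / np.maximum(mag, 1e-8)[:, :, None]
    normals[degenerate] = (0.0, 0.0, 1.0)
    albedo = np.pi * mag
    return SurfaceModel(normals=normals, albedo=albedo, mask=mask)


def _masked_lowpass(field: np.ndarray, sigma: float, valid: np.ndarray) -> np.ndarray:
    """Gaussian low-pass excluding masked pixels (normalized convolution)."""
    weights = ndi.gaussian_filter(valid.astype(float), sigma, mode="nearest")
    blurred = ndi.gaussian_filter(np.where(valid, field, 0.0), sigma, mode="nearest")
    return blurred / np.maximum(weights, 1e-12)


def highpass_normals(
    normals: np.ndarray, sigma: float | None = None, mask: PixelMask | None = None
) -> np.ndarray:
    """Remove low-spatial-frequency error from a normal field.

    Each component is convolved with a Gaussian of the given sigma and the
    result subtracted.  The residual field is recentered about the optical
    axis by adding back a unit z-component and renormalizing, so the output
    is a unit normal field describing only high-frequency relief.  When
    ``sigma`` is omitted the full-frame default (150 px at 1350 px width)
    is scaled to the image width.
    """
    normals = np.asarray(normals, dtype=np.float64)
    if normals.ndim != 3 or normals.shape[2] != 3:
        raise ConfigurationError("normals must be (H, W, 3)")
    if sigma is None:
        sigma = scaled_sigma(normals.shape[1])
    valid = mask.valid if mask is not None else np.ones(normals.shape[:2], dtype=bool)
    out = np.empty_like(normals)
    for c in range(3):
        low = _masked_lowpass(normals[:, :, c], sigma, valid)
        out[:, :, c] = normals[:, :, c] - low
    out[:, :, 2] += 1.0
    norm = np.linalg.norm(out, axis=-1)
    out /= np.maximum(norm, 1e-12)[:, :, None]
    return out


# ---------------------------------------------------------------------------
# Height integration
# ---------------------------------------------------------------------------

def poisson_solve(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least-squares integration of a gradient field (Poisson equation).

    Finds the zero-mean height minimizing ``||Dx h - p||^2 + ||Dy h - q||^2``
    where ``Dx``/``Dy`` are forward differences (``p[i, j]`` is interpreted
    as ``h[i, j+1] - h[i, j]``; the last column of ``p`` and last row of
    ``q`` are unused).  The normal equations form a Neumann Laplacian,
    solved exactly with a type-II discrete cosine transform — spectrally
    equivalent to a multigrid Poisson solve.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 2:
        raise ConfigurationError("p and q must be matching 2-D fields")
    h, w = p.shape
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ConfigurationError("gradient field must be finite")
    px = p[:, : w - 1]
    qy = q[: h - 1, :]
    # rhs = Dx^T px + Dy^T qy (adjoint of forward differences, zero-padded)
    rhs = np.zeros((h, w))
    rhs[:, :-1] -= px
    rhs[:, 1:] += px
    rhs[:-1, :] -= qy
    rhs[1:, :] += qy
    rhs = -rhs  # normal equations: L h = -div g with L = D^T D
    lam_x = 2.0 - 2.0 * np.cos(np.pi * np.arange(w) / w)
    lam_y = 2.0 - 2.0 * np.cos(np.pi * np.arange(h) / h)
    denom = lam_y[:, None] + lam_x[None, :]
    denom[0, 0] = 1.0
    coeff = dctn(rhs, type=2, norm="ortho")
    coeff = -coeff / denom
    coeff[0, 0] = 0.0  # zero-mean gauge
    height = idctn(coeff, type=2, norm="ortho")
    return height - height.mean()


def integrate_height(
    normals: np.ndarray, mask: PixelMask | None = None, z_floor: float = 1e-3
) -> np.ndarray:
    """Integrate a unit-normal field into a zero-mean height map.

    Normals are projected to gradient space, ``p = -n_x / n_z`` and
    ``q = -n_y / n_z`` (z clamped at ``z_floor`` to keep gradients finite),
    masked pixels contribute zero gradient, and the field is integrated
    with :func:`poisson_solve`.
    """
    normals = np.asarray(normals, dtype=np.float64)
    if normals.ndim != 3 or normals.shape[2] != 3:
        raise ConfigurationError("normals must be (H, W, 3)")
    valid = mask.valid if mask is not None else np.ones(normals.shape[:2], dtype=bool)
    if not valid.any():
        raise ConfigurationError("all pixels masked")
    nz = np.maximum(normals[:, :, 2], z_floor)
    p = np.where(valid, -normals[:, :, 0] / nz, 0.0)
    q = np.where(valid, -normals[:, :, 1] / nz, 0.0)
    return poisson_solve(p, q)


def compare_height(
    measured: np.ndarray,
    truth: np.ndarray,
    filter_sigma: float | None = None,
    mask: PixelMask | None = None,
) -> float:
    """Mean absolute height error after matched high-pass filtering.

    Both maps receive the same Gaussian high-pass (sigma defaulting to the
    width-scaled full-frame value), are normalized to unit maximum absolute
    value, and the mean absolute difference over unmasked pixels is
    returned — the protocol used to score reconstructions against ground
    truth when absolute scale is unknown.
    """
    measured = np.asarray(measured, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if measured.shape != truth.shape:
        raise ConfigurationError("height map shapes differ")
    if filter_sigma is None:
        filter_sigma = scaled_sigma(measured.shape[1])

    def prep(x: np.ndarray) -> np.ndarray:
        if filter_sigma > 0:
            x = x - ndi.gaussian_filter(x, filter_sigma, mode="nearest")
        peak = np.abs(x).max()
        return x / peak if peak > 0 else x

    a, b = prep(measured), prep(truth)
    valid = mask.valid if mask is not None else np.ones(measured.shape, dtype=bool)
    return float(np.abs(a - b)[valid].mean())


# ---------------------------------------------------------------------------
# Relighting
# ---------------------------------------------------------------------------

def render_relit(
    height: np.ndarray,
    light: np.ndarray,
    albedo: np.ndarray | float = 1.0,
    color_overlay: np.ndarray | None = None,
    ambient: float = 0.1,
    specular: float = 0.3,
    shininess: float = 16.0,
) -> np.ndarray:
    """Phong-shade a height map under a virtual directional light.

    Normals are recomputed from the height map; the view direction is the
    optical axis.  Output is clamped to [0, 1]; an optional color overlay
    modulates the shading per channel.
    """
    height = np.asarray(height, dtype=np.float64)
    light = np.asarray(light, dtype=np.float64)
    light = light / np.linalg.norm(light)
    hy, hx = np.gradient(height)
    n = np.stack([-hx, -hy, np.ones_like(hx)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    ndotl = np.clip(n @ light, 0.0, None)
    view = np.array([0.0, 0.0, 1.0])
    halfway = light + view
    halfway /= np.linalg.norm(halfway)
    spec = np.clip(n @ halfway, 0.0, None) ** shininess
    shading = ambient + np.asarray(albedo) * ndotl + specular * spec
    if color_overlay is not None:
        color_overlay = np.asarray(color_overlay, dtype=np.float64)
        if color_overlay.shape[:2] != height.shape:
            raise ConfigurationError("color overlay shape mismatch")
        out = color_overlay * shading[:, :, None]
    else:
        out = shading
    return np.clip(out, 0.0, 1.0)
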