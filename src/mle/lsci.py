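"""Laser speckle contrast imaging: K maps, flow contrast, registered
temporal averaging, and the between-ROI RMS contrast metric.

Speckle contrast is ``K = sigma / <I>`` computed in a sliding 5x5 window
(population standard deviation); motion during the exposure blurs the
speckle and lowers K, so the flow contrast ``V = 1 / K^2`` rises with
velocity.  Units are arbitrary: no absolute velocity calibration is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .frameio import ConfigurationError, FormatError, FrameStack, PixelMask
from .preprocess import AffineTransform, deinterlace, register_mse

__all__ = [
    "FlowContrastMap",
    "speckle_contrast",
    "flow_contrast",
    "split_interlaced_modes",
    "average_flow",
    "rms_contrast",
    "contrast_to_noise",
    "median_filter_for_display",
]


@dataclass
class FlowContrastMap:
    """Speckle contrast K and flow contrast V with a validity mask."""

    k_map: np.ndarray
    v_map: np.ndarray
    n_averaged: int
    mask: PixelMask


def speckle_contrast(
    frame: np.ndarray, window: int = 5
) -> tuple[np.ndarray, PixelMask]:
    """Local speckle contrast ``K = sigma / <I>`` in a sliding window.

    Uses the population (1/n) standard deviation.  Border pixels whose
    window is incomplete are masked out_of_fov; windows with zero mean are
    masked underexposed.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ConfigurationError("speckle_contrast expects a single-channel frame")
    if window < 2 or window % 2 == 0:
        raise ConfigurationError("window must be an odd integer >= 3")
    mean = ndi.uniform_filter(frame, size=window, mode="nearest")
    mean_sq = ndi.uniform_filter(frame**2, size=window, mode="nearest")
    var = np.maximum(mean_sq - mean**2, 0.0)
    mask = PixelMask.empty(frame.shape)
    border = np.ones(frame.shape, dtype=bool)
    r = window // 2
    border[r : frame.shape[0] - r, r : frame.shape[1] - r] = False
    mask.flag("out_of_fov", border)
    zero_mean = mean <= 0
    mask.flag("underexposed", zero_mean)
    k = np.where(zero_mean, 0.0, np.sqrt(var) / np.maximum(mean, 1e-300))
    return k, mask


def flow_contrast(
    k_map: np.ndarray, mask: PixelMask | None = None
) -> tuple[np.ndarray, PixelMask]:
    """Flow contrast ``V = 1 / K^2``; pixels with K = 0 are masked."""
    k_map = np.asarray(k_map, dtype=np.float64)
    mask = mask.copy() if mask is not None else PixelMask.empty(k_map.shape)
    zero = k_map <= 0
    mask.flag("underexposed", zero)
    v = np.where(zero, 0.0, 1.0 / np.maximum(k_map, 1e-150) ** 2)
    return v, mask


def split_interlaced_modes(stack: FrameStack) -> tuple[FrameStack, FrameStack]:
    """Deinterlace a speckle/white-light alternating stack into two stacks.

    Each acquired frame interlaces a speckle-illuminated field (odd rows,
    1-based) with a white-light field (even rows).  Per-frame parity labels
    declare which field carries the speckle illumination; both output
    stacks keep full frame height via vertical interpolation and retain
    pairing order for downstream registration.
    """
    speckle_frames, color_frames = [], []
    for i in range(stack.n_frames):
        parity = stack.parities[i]
        if parity not in ("odd", "even"):
            raise FormatError("per-frame field parity labels are required")
        odd_img, even_img = deinterlace(stack.frames[i])
        if parity == "odd":
            speckle_frames.append(odd_img)
            color_frames.append(even_img)
        else:
            speckle_frames.append(even_img)
            color_frames.append(odd_img)
    speckle_stack = FrameStack(
        frames=np.stack(speckle_frames),
        labels=["speckle"] * len(speckle_frames),
        mask=stack.mask.copy(),
        extra=dict(stack.extra),
    )
    color_stack = FrameStack(
        frames=np.stack(color_frames),
        labels=["white"] * len(color_frames),
        mask=stack.mask.copy(),
        extra=dict(stack.extra),
    )
    return speckle_stack, color_stack


def average_flow(
    v_frames: np.ndarray,
    color_frames: np.ndarray | None = None,
    window: int = 15,
    transforms: list[AffineTransform] | None = None,
    config: dict | None = None,
) -> FlowContrastMap:
    """Temporal rolling average of flow-contrast frames with registration.

    Produces the averaged map for the central window of the sequence: the
    window-center frame is the registration reference; every paired
    white-light frame is registered to it with the MSE estimator, the same
    transform is applied to its V frame, and the valid (in field-of-view)
    pixels are averaged.  Ground-truth ``transforms`` may be supplied to
    bypass estimation (phantom oracles).  Frames whose registration does
    not converge are excluded rather than aborting the average.
    """
    v_frames = np.asarray(v_frames, dtype=np.float64)
    if v_frames.ndim != 3:
        raise ConfigurationError("v_frames must be (T, H, W)")
    n = v_frames.shape[0]
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    window = min(window, n)
    start = (n - window) // 2
    idx = list(range(start, start + window))
    center = idx[len(idx) // 2]

    shape = v_frames.shape[1:]
    acc = np.zeros(shape)
    count = np.zeros(shape)
    n_used = 0
    for i in idx:
        if i == center:
            warped_v = v_frames[i]
            valid = np.ones(shape, dtype=bool)
        else:
            if transforms is not None:
                t = transforms[i]
            elif color_frames is not None:
                t = register_mse(color_frames[i], color_frames[center], config)
                if not t.diagnostics.get("converged", True):
                    continue
            else:
                t = AffineTransform.identity()
            warped_v = t.apply(v_frames[i])
            valid = t.warp_mask(shape)
        acc[valid] += warped_v[valid]
        count[valid] += 1
        n_used += 1
    mask = PixelMask.empty(shape)
    never = count == 0
    mask.flag("out_of_fov", never)
    v_mean = np.where(never, 0.0, acc / np.maximum(count, 1))
    with np.errstate(divide="ignore"):
        k_equiv = np.where(v_mean > 0, 1.0 / np.sqrt(v_mean), 0.0)
    return FlowContrastMap(k_map=k_equiv, v_map=v_mean, n_averaged=n_used, mask=mask)


def _check_rois(image, roi_a, roi_b):
    image = np.asarray(image, dtype=np.float64)
    roi_a = np.asarray(roi_a, dtype=bool)
    roi_b = np.asarray(roi_b, dtype=bool)
    if not roi_a.any() or not roi_b.any():
        raise ConfigurationError("ROIs must be non-empty")
    if (roi_a & roi_b).any():
        raise ConfigurationError("ROIs must be disjoint")
    return image, roi_a, roi_b


def rms_contrast(image: np.ndarray, roi_a: np.ndarray, roi_b: np.ndarray) -> float:
    """Between-ROI RMS contrast.

    With ``U`` the union of the two disjoint ROIs, returns
    ``std_U(I) / mean_U(I)`` (population std) — symmetric in the ROIs and
    invariant to positive rescaling of the image.  Returns NaN when the
    union mean is zero.  Used to compare lesion/background contrast across
    imaging modalities on a single map.
    """
    image, roi_a, roi_b = _check_rois(image, roi_a, roi_b)
    values = image[roi_a | roi_b]
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std() / mean)


def contrast_to_noise(
    image: np.ndarray, roi_a: np.ndarray, roi_b: np.ndarray
) -> float:
    """Between-ROI contrast-to-noise ratio.

    ``|mean_a - mean_b| / sqrt((var_a + var_b) / 2)`` — the separation of
    the two region means relative to the pooled within-region fluctuation.
    This is the quantity temporal averaging improves: linear averaging of
    decorrelated flow-contrast frames leaves the region means fixed while
    shrinking the within-region noise, so the vasculature emerges from the
    background as frames accumulate.  (The mean-relative
    :func:`rms_contrast` is blind to that effect by construction: averaging
    preserves the union mean and only removes variance.)
    """
    image, roi_a, roi_b = _check_rois(image, roi_a, roi_b)
    a = image[roi_a]
    b = image[roi_b]
    noise = np.sqrt(0.5 * (a.var() + b.var()))
    if noise == 0:
        return float("nan")
    return float(abs(a.mean() - b.mean()) / noise)


def median_filter_for_display(image: np.ndarray, size: int = 9) -> np.ndarray:
    """9x9 median filter used only for visualization, never quantification."""
    return ndi.median_filter(np.asarray(image, dtype=np.float64), size=size)
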