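"""dF/F0 pipeline: bleach correction, baseline, trial averaging, filtering,
masking and colour-scale rendering.

The processing order used throughout is: (optional offline binning) ->
blank-trial bleach correction -> F0 estimation from pre-stimulus frames ->
dF/F0 -> trial averaging -> spatial filtering -> dark-pixel masking ->
colour-scale rendering.

Bleach correction subtracts the Savitzky-Golay-smoothed time course of a
trial acquired without stimulation, then adds back that smoothed blank's
pre-stimulus mean so that the corrected stack keeps the original F0 scale.
Smoothing the blank first avoids injecting a second helping of photon noise
into the corrected record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .binning import FrameStack, average_stacks, sliding_window_sum

__all__ = [
    "DffStack",
    "compute_f0",
    "bleach_correct",
    "dff",
    "trial_average",
    "adaptive_wiener",
    "dark_pixel_mask",
    "median_mask_render",
    "RENDER_PRESETS",
]

# colour-scale display windows (lo, hi) in dF/F0 per scene type
RENDER_PRESETS = {"wave": (0.007, 0.028), "dendrite": (0.01, 0.04), "ais": (0.02, 0.08)}


@dataclass
class DffStack:
    """T x H x W fractional-fluorescence-change movie with its baseline map.

    Masked-out pixels hold NaN and are excluded from statistics and display.
    """

    data: np.ndarray
    f0_map: np.ndarray
    mask: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("dF/F0 data must be T x H x W")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match the frame shape")
        if not np.isfinite(self.data[:, self.mask]).all():
            raise ValueError("dF/F0 must be finite wherever the mask is true")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval

    def site_trace(self, roi: tuple[int, int, int, int]) -> np.ndarray:
        """Mean dF/F0 over a rectangular ROI (half-open intervals)."""
        r0, r1, c0, c1 = roi
        return np.nanmean(self.data[:, r0:r1, c0:c1], axis=(1, 2))


def compute_f0(
    stack: FrameStack,
    baseline_window: tuple[int, int],
    stim_onset: float | None = None,
) -> np.ndarray:
    """Per-pixel baseline fluorescence: temporal mean over pre-stimulus frames.

    ``baseline_window`` is a half-open frame-index range. If the stimulus
    onset time is known (e.g. from scene truth) and the window reaches past
    it, a warning is raised — F0 would then be contaminated by the response.
    """
    lo, hi = baseline_window
    t = stack.data.shape[0]
    lo, hi = max(lo, 0), min(hi, t)
    if hi <= lo:
        raise ValueError(f"empty baseline window {baseline_window}")
    if stim_onset is not None and hi * stack.frame_interval > stim_onset:
        warnings.warn(
            "baseline window extends past the stimulus onset; F0 may be biased",
            stacklevel=2,
        )
    return stack.data[lo:hi].mean(axis=0, dtype=np.float64)


def bleach_correct(
    stack: FrameStack,
    blank: FrameStack,
    sg_window: int = 21,
    sg_order: int = 3,
    baseline_window: tuple[int, int] | None = None,
) -> FrameStack:
    """Subtract the smoothed blank-trial time course, preserving the F0 scale.

    Per pixel, with ``b(t)`` the Savitzky-Golay-filtered blank and ``<b>`` its
    mean over ``baseline_window`` (default: the first 20% of frames):

        corrected(t) = (stack(t) - b(t)) / g(t) + <b>

    where ``g(t)`` is the *spatially pooled* relative bleach factor, the
    frame-mean of ``b`` normalised to its own baseline mean. Subtraction alone
    removes the baseline trend but leaves the evoked component attenuated by
    the bleach (dye that has bleached no longer reports the stimulus), so the
    difference is rescaled before the baseline mean is added back. Pooling
    ``g`` over all pixels reflects the spatially uniform bleaching model and
    keeps its noise negligible (a per-pixel ratio would bias the late frames
    upward through the noisy denominator). For a bleach-free blank ``g = 1``
    and this is a pure subtraction; the corrected stack keeps the original F0
    scale in every case.
    """
    if stack.data.shape != blank.data.shape:
        raise ValueError("stack and blank must have identical T x H x W shape")
    t = stack.data.shape[0]
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if sg_window >= t:
        raise ValueError("sg_window must be smaller than the number of frames")
    if baseline_window is None:
        baseline_window = (0, max(1, t // 5))
    lo, hi = baseline_window
    if not (0 <= lo < hi <= t):
        raise ValueError(f"invalid baseline window {baseline_window}")

    smooth = signal.savgol_filter(
        blank.data.astype(np.float64), sg_window, sg_order, axis=0
    )
    smooth_mean = smooth[lo:hi].mean(axis=0)
    course = smooth.mean(axis=(1, 2))
    course_base = course[lo:hi].mean()
    if course_base > 0:
        g = np.clip(course / course_base, 0.05, None)
    else:
        g = np.ones(t)
    corrected = (stack.data.astype(np.float64) - smooth) / g[:, None, None] + smooth_mean
    return FrameStack(
        data=corrected,
        frame_interval=stack.frame_interval,
        bit_depth=stack.bit_depth,
        provenance=f"{stack.provenance}>bleach_corrected",
        extra=dict(stack.extra),
    )


def dff(
    corrected: FrameStack,
    f0_map: np.ndarray,
    mask: np.ndarray | None = None,
) -> DffStack:
    """(F(t) - F0) / F0 per pixel; masked-out pixels become NaN."""
    f0_map = np.asarray(f0_map, dtype=np.float64)
    if mask is None:
        mask = np.ones(f0_map.shape, dtype=bool)
    if (f0_map[mask] <= 0).any():
        raise ValueError("F0 must be positive on every unmasked pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (corrected.data.astype(np.float64) - f0_map) / f0_map
    out[:, ~mask] = np.nan
    return DffStack(
        data=out,
        f0_map=f0_map,
        mask=np.asarray(mask, dtype=bool),
        frame_interval=corrected.frame_interval,
    )


def trial_average(stacks: list[FrameStack]) -> FrameStack:
    """Frame-wise mean of 3-9 (or any k >= 1) congruent trials.

    Relative photon noise of the averaged record scales as 1/sqrt(k).
    """
    return average_stacks(stacks)


def adaptive_wiener(frame: np.ndarray, window: int = 9, passes: int = 1) -> np.ndarray:
    """Local-mean / local-variance adaptive (Wiener2-style) smoothing.

    For each pixel, with local mean ``mu`` and local variance ``var`` over the
    ``window x window`` neighbourhood (intersected with the frame at borders)
    and noise power ``nu`` estimated as the frame-average local variance:

        out = mu + max(var - nu, 0) / max(var, nu) * (in - mu)

    Nearly flat regions collapse to the local mean; strong features are left
    intact. Applied ``passes`` times.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("adaptive_wiener operates on a single 2-D frame")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(frame.shape):
        raise ValueError("window larger than the frame")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    out = frame
    for _ in range(passes):
        s1, counts = sliding_window_sum(out, window)
        s2, _ = sliding_window_sum(out * out, window)
        mu = s1 / counts
        var = s2 / counts - mu * mu
        var = np.maximum(var, 0.0)
        nu = var.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(var > 0, np.maximum(var - nu, 0.0) / np.maximum(var, nu), 0.0)
        out = mu + gain * (out - mu)
    return out


def dark_pixel_mask(f0_map: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Mask of displayable pixels: F0 at least ``fraction`` of the robust
    (99th-percentile) maximum. Dark pixels carry no usable signal and are
    excluded from dF/F0 statistics and rendering."""
    f0_map = np.asarray(f0_map, dtype=np.float64)
    threshold = fraction * np.percentile(f0_map, 99)
    return f0_map >= threshold


def median_mask_render(
    dff_stack: DffStack,
    median_kernel: int = 8,
    lo: float = 0.01,
    hi: float = 0.04,
    background: np.ndarray | None = None,
    colormap: str = "jet",
) -> np.ndarray:
    """Colour-scale rendering of a dF/F0 movie over a background image.

    Each frame is median-filtered (``median_kernel`` square window, same
    top-left-biased anchor as binning for even sizes), then mapped linearly
    onto the colour scale over [lo, hi]: values below ``lo`` are transparent
    (the background shows through), values above ``hi`` saturate at the top
    colour. Returns a (T, H, W, 3) uint8 RGB movie.
    """
    if lo >= hi:
        raise ValueError("require lo < hi for the colour scale")
    from matplotlib import colormaps

    cmap = colormaps[colormap]
    t, h, w = dff_stack.data.shape
    if background is None:
        background = np.zeros((h, w))
    bg = np.asarray(background, dtype=np.float64)
    span = bg.max() - bg.min()
    bg8 = ((bg - bg.min()) / span * 255.0).astype(np.uint8) if span > 0 else np.zeros((h, w), np.uint8)
    bg_rgb = np.repeat(bg8[..., None], 3, axis=-1)

    out = np.empty((t, h, w, 3), dtype=np.uint8)
    filled = np.nan_to_num(dff_stack.data, nan=-np.inf)
    for k in range(t):
        med = ndimage.median_filter(filled[k], size=median_kernel, mode="nearest")
        pos = np.clip((med - lo) / (hi - lo), 0.0, 1.0)
        rgb = (cmap(pos)[..., :3] * 255.0).astype(np.uint8)
        show = (med >= lo) & dff_stack.mask
        frame = bg_rgb.copy()
        frame[show] = rgb[show]
        out[k] = frame
    return out
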