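"""N x N offline binning of digital-number frame stacks.

Offline binning assigns to each pixel the *sum* of the digital values over the
N x N rectangle surrounding it, after acquisition. Summing k = N^2 8-bit values
yields a value that needs 8 + 2*ceil(log2 N) bits (2 x 2 -> 10 bit,
4 x 4 -> 12 bit), so binning raises both the effective photon count of a pixel
and its effective digital depth. A rectangular ROI sum over the same window is
arithmetically identical, which is why ROI averaging of raw data is treated as
equivalent to binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["FrameStack", "offline_bin", "roi_trace", "sliding_window_sum"]


@dataclass
class FrameStack:
    """A T x H x W movie of digital numbers plus acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Digital numbers. Integer dtype for raw/binned stacks; float stacks
        arise only from trial averaging or bleach correction.
    frame_interval : float
        Seconds between consecutive frames.
    bit_depth : int
        Bits of the per-pixel representation; all values are < 2**bit_depth
        for integer data.
    provenance : str
        Free-form processing history, e.g. ``"raw"``, ``"raw>binned(n=5,sliding)"``.
    """

    data: np.ndarray
    frame_interval: float
    bit_depth: int
    provenance: str = "raw"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be T x H x W, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("stack must have T, H, W >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.issubdtype(self.data.dtype, np.integer):
            if self.data.min() < 0:
                raise ValueError("digital numbers must be non-negative")
            if self.data.max() >= 2 ** self.bit_depth:
                raise ValueError(
                    f"values exceed the stated bit depth of {self.bit_depth} bits"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


def _window_bounds(n: int) -> tuple[int, int]:
    # rows covered by a window anchored at i: [i - n//2, i + ceil(n/2) - 1],
    # i.e. top-left biased for even n.
    lo = n // 2
    hi = (n + 1) // 2 - 1
    return lo, hi


def sliding_window_sum(frames: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum each frame over the n x n window around every pixel.

    Windows are intersected with the frame at the borders. Returns
    ``(sums, counts)`` where ``counts[i, j]`` is the number of in-frame pixels
    contributing to ``sums[..., i, j]`` (== n*n in the interior).

    Integer input is accumulated exactly in int64 via a 2-D integral image.
    """
    frames = np.asarray(frames)
    squeeze = frames.ndim == 2
    if squeeze:
        frames = frames[None]
    t, h, w = frames.shape
    if n < 1:
        raise ValueError("window size must be >= 1")
    if n > min(h, w):
        raise ValueError(f"window size {n} exceeds frame dimensions {h}x{w}")

    acc_dtype = np.int64 if np.issubdtype(frames.dtype, np.integer) else np.float64
    integral = np.zeros((t, h + 1, w + 1), dtype=acc_dtype)
    integral[:, 1:, 1:] = frames.astype(acc_dtype).cumsum(axis=1).cumsum(axis=2)

    lo, hi = _window_bounds(n)
    rows = np.arange(h)
    cols = np.arange(w)
    r1 = np.clip(rows - lo, 0, h)
    r2 = np.clip(rows + hi + 1, 0, h)
    c1 = np.clip(cols - lo, 0, w)
    c2 = np.clip(cols + hi + 1, 0, w)

    # inclusion-exclusion on the integral image, broadcast over rows x cols
    s = (
        integral[:, r2[:, None], c2[None, :]]
        - integral[:, r1[:, None], c2[None, :]]
        - integral[:, r2[:, None], c1[None, :]]
        + integral[:, r1[:, None], c1[None, :]]
    )
    counts = (r2 - r1)[:, None] * (c2 - c1)[None, :]
    if squeeze:
        s = s[0]
    return s, counts


def offline_bin(
    stack: FrameStack, n: int, mode: Literal["sliding", "block"] = "sliding"
) -> FrameStack:
    """Apply N x N offline binning to every frame of a stack.

    ``sliding`` assigns to each pixel the sum over the N x N window centred on
    it (window clipped at the frame borders; the per-pixel contributing count
    is stored in ``result.extra["effective_counts"]``). ``block`` sums
    non-overlapping N x N tiles, shrinking the frame to (H//N, W//N).

    The output bit depth grows to ``bit_depth + 2*ceil(log2 n)``; accumulation
    is int64 regardless, so no overflow can occur for any 8/16-bit input.
    """
    t, h, w = stack.data.shape
    if n < 1:
        raise ValueError("binning size must be >= 1")
    if n > min(h, w):
        raise ValueError(f"binning size {n} exceeds frame dimensions {h}x{w}")

    extra = dict(stack.extra)
    if mode == "sliding":
        out, counts = sliding_window_sum(stack.data, n)
        extra["effective_counts"] = counts
    elif mode == "block":
        hb, wb = h // n, w // n
        trimmed = stack.data[:, : hb * n, : wb * n]
        out = (
            trimmed.reshape(t, hb, n, wb, n)
            .astype(np.int64 if np.issubdtype(stack.data.dtype, np.integer) else np.float64)
            .sum(axis=(2, 4))
        )
        extra.pop("effective_counts", None)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")

    new_depth = stack.bit_depth + 2 * math.ceil(math.log2(n)) if n > 1 else stack.bit_depth
    return FrameStack(
        data=out,
        frame_interval=stack.frame_interval,
        bit_depth=new_depth,
        provenance=f"{stack.provenance}>binned(n={n},{mode})",
        extra=extra,
    )


def roi_trace(
    stack: FrameStack,
    roi: tuple[int, int, int, int],
    statistic: Literal["sum", "mean"] = "sum",
) -> np.ndarray:
    """Per-frame sum or mean of digital values over a rectangular ROI.

    ``roi`` is ``(row_start, row_stop, col_start, col_stop)`` with half-open
    pixel intervals, matching numpy slicing.
    """
    r0, r1, c0, c1 = roi
    t, h, w = stack.data.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} is empty or outside the {h}x{w} frame")
    patch = stack.data[:, r0:r1, c0:c1]
    acc = np.int64 if np.issubdtype(stack.data.dtype, np.integer) else np.float64
    if statistic == "sum":
        return patch.sum(axis=(1, 2), dtype=acc)
    if statistic == "mean":
        return patch.mean(axis=(1, 2), dtype=np.float64)
    raise ValueError(f"unknown statistic {statistic!r}")


def average_stacks(stacks: list[FrameStack]) -> FrameStack:
    """Frame-wise arithmetic mean of congruent stacks (trial averaging).

    Photon noise in the average falls as 1/sqrt(k) for k independent trials.
    """
    if not stacks:
        raise ValueError("need at least one stack to average")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.data.shape != ref.data.shape:
            raise ValueError("stacks to average must share shape")
        if not math.isclose(s.frame_interval, ref.frame_interval, rel_tol=1e-12):
            raise ValueError("stacks to average must share frame timing")
    mean = np.mean([s.data for s in stacks], axis=0, dtype=np.float64)
    return replace(
        ref,
        data=mean,
        provenance=f"{ref.provenance}>averaged(k={len(stacks)})",
        extra=dict(ref.extra),
    )
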