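import numpy as np
import pytest

from photonbin import CameraConfig, SceneSpec


@pytest.fixture
def photon_cam() -> CameraConfig:
    """8-bit photon-counting mode: 1 digital unit = 1 photoelectron."""
    return CameraConfig.photon_counting_8bit()


@pytest.fixture
def uniform_scene():
    """Factory for spatially uniform, temporally stationary scenes."""

    def make(gamma: float, n_frames: int = 500, side: int = 21, frame_interval: float = 1e-3) -> SceneSpec:
        return SceneSpec(
            rate_movie=np.full((n_frames, side, side), float(gamma)),
            frame_interval=frame_interval,
            baseline_map=np.full((side, side), float(gamma)),
        )

    return make


def brute_force_sliding_sum(frame: np.ndarray, n: int) -> np.ndarray:
    """Reference double-loop implementation of the N x N window sum, clipped
    at frame borders, with the top-left-biased anchor for even N."""
    h, w = frame.shape
    lo, hi = n // 2, (n + 1) // 2 - 1
    out = np.zeros((h, w), dtype=np.int64 if np.issubdtype(frame.dtype, np.integer) else np.float64)
    for i in range(h):
        for j in range(w):
            out[i, j] = frame[
                max(0, i - lo) : min(h, i + hi + 1), max(0, j - lo) : min(w, j + hi + 1)
            ].sum(dtype=out.dtype)
    return out
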