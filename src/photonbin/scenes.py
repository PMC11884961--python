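"""Synthetic ground-truth scenes for low-bit-depth functional imaging.

Each generator returns a :class:`SceneSpec`: a noiseless movie of expected
photoelectron rates per pixel per frame, together with a ``truth`` record of
the underlying dF/F0 waveforms, so that every downstream stage (binning,
bleach correction, dF/F0, sigmoid fitting, velocity estimation) can be tested
against a known answer without any experimental data.

Three scenes emulate the proof-of-principle experiments of wide-field
8-bit imaging in brain slices:

* a stimulus-locked Ca2+ wave spreading from an electrode through a
  hippocampal slice at 2 kHz (population Fluo-4 signal, 100-200
  photoelectrons per pixel, dF/F0 of a few percent at most);
* seven Ca2+ transients along the apical dendrite of a layer-5 pyramidal
  neuron at 10 kHz, progressively delayed by back-propagation at a defined
  velocity (ROIs collecting > 100,000 photoelectrons per frame);
* membrane-potential transients at three axon initial segment sites at
  40 kHz, with site-dependent rise slopes and the distal site peaking first
  (ROIs collecting > 25,000 photoelectrons per frame).

Photobleaching is modelled as a single spatially uniform exponential; a blank
(no-stimulus) trial shares the bleach and baseline of its parent scene, which
is what makes blank-trial subtraction an exact correction in expectation.

All randomness lives in :func:`photonbin.camera.acquire`; scenes themselves
are deterministic functions of their parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .waveforms import SigmoidParams, three_sigmoid

__all__ = [
    "SceneSpec",
    "SigmoidParams",
    "make_wave_scene",
    "make_dendrite_scene",
    "make_ais_scene",
    "make_blank_trial",
    "DEFAULT_DENDRITE_SIGMOID",
]


@dataclass
class SceneSpec:
    """Ground-truth photoelectron-rate movie plus the record that produced it.

    ``rate_movie[t, i, j]`` is the expected number of photoelectrons detected
    by pixel (i, j) during frame t and satisfies

        rate = baseline_map * (1 + dff_true) * exp(-t / bleach_tau).

    ``truth`` carries the per-site dF/F0 waveforms, site ROIs, sigmoid
    parameters, stimulus times and propagation velocity as applicable, and the
    full noiseless ``dff_movie``.
    """

    rate_movie: np.ndarray
    frame_interval: float
    baseline_map: np.ndarray
    truth: dict = field(default_factory=dict)
    bleach_tau: float = math.inf

    def __post_init__(self) -> None:
        self.rate_movie = np.asarray(self.rate_movie, dtype=np.float64)
        self.baseline_map = np.asarray(self.baseline_map, dtype=np.float64)
        if self.rate_movie.ndim != 3:
            raise ValueError("rate_movie must be T x H x W")
        if not np.isfinite(self.rate_movie).all() or self.rate_movie.min() < 0:
            raise ValueError("rate_movie must be finite and non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.rate_movie.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.rate_movie.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def is_blank(self) -> bool:
        return bool(self.truth.get("blank", False))

    def bleach_factor(self) -> np.ndarray:
        """exp(-t / bleach_tau) per frame (1.0 everywhere for tau = inf)."""
        if math.isinf(self.bleach_tau):
            return np.ones(self.n_frames)
        return np.exp(-self.times / self.bleach_tau)


def _assemble(
    dff_movie: np.ndarray,
    baseline_map: np.ndarray,
    frame_interval: float,
    truth: dict,
    bleach_tau: float,
) -> SceneSpec:
    t = dff_movie.shape[0]
    bleach = (
        np.ones(t)
        if math.isinf(bleach_tau)
        else np.exp(-np.arange(t) * frame_interval / bleach_tau)
    )
    rate = baseline_map[None] * (1.0 + dff_movie) * bleach[:, None, None]
    truth = dict(truth)
    truth["dff_movie"] = dff_movie
    return SceneSpec(
        rate_movie=rate,
        frame_interval=frame_interval,
        baseline_map=baseline_map,
        truth=truth,
        bleach_tau=bleach_tau,
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def make_wave_scene(
    origin: tuple[int, int] = (32, 8),
    n_pulses: int = 6,
    pulse_interval: float = 0.010,
    speed: float = 0.02,
    spatial_extent: float = 250.0,
    peak_dff: float = 0.028,
    baseline_gamma: float = 150.0,
    height: int = 64,
    width: int = 96,
    frame_rate: float = 2000.0,
    duration: float = 0.15,
    stim_onset: float = 0.02,
    um_per_px: float = 4.0,
    rise_ms: float = 2.0,
    decay_tau: float = 0.08,
    bleach_tau: float = math.inf,
) -> SceneSpec:
    """Stimulus-locked Ca2+ wave spreading from an electrode position.

    Each of ``n_pulses`` current pulses (default six at 100 Hz) adds a
    sigmoidal dF/F0 increment that then decays exponentially; a pixel at
    distance d (um) from the origin sees every increment delayed by
    ``d / speed`` (speed in um/ms == m/s) and attenuated by ``2**(-d /
    spatial_extent)``, so the response at ``spatial_extent`` is exactly half
    the near-electrode peak. ``peak_dff`` is the maximum dF/F0 at the origin.
    """
    if not (0 <= origin[0] < height and 0 <= origin[1] < width):
        raise ValueError(f"origin {origin} outside {height}x{width} frame")
    if speed <= 0:
        raise ValueError("propagation speed must be positive")
    n_frames = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    times = np.arange(n_frames) * dt
    pulse_times = stim_onset + np.arange(n_pulses) * pulse_interval

    rows, cols = np.mgrid[0:height, 0:width]
    dist_um = np.hypot(rows - origin[0], cols - origin[1]) * um_per_px

    # per-pulse unit increment: logistic rise (time constant rise_ms) with
    # exponential recovery; normalised below so the origin peaks at peak_dff
    rise_s = rise_ms * 1e-3
    delay = dist_um / (speed * 1e6)  # s; speed in m/s = 1e6 um/s
    rel = times[:, None, None] - delay[None]  # time since wave arrival
    u = np.zeros((n_frames, height, width))
    for tk in pulse_times - stim_onset:  # pulse times relative to arrival
        x = rel - tk
        u += _logistic(x / rise_s) * np.exp(-np.maximum(x, 0.0) / decay_tau)

    # normalise at the origin so the true origin peak equals peak_dff
    origin_course = u[:, origin[0], origin[1]]
    norm = origin_course.max()
    amp = peak_dff * np.power(2.0, -dist_um / spatial_extent)
    dff = (u / norm if norm > 0 else u) * amp[None]

    baseline = np.full((height, width), float(baseline_gamma))
    truth = {
        "kind": "wave",
        "origin": tuple(origin),
        "pulse_times_s": pulse_times.tolist(),
        "stim_onset_s": stim_onset,
        "speed_m_per_s": speed,
        "spatial_extent_um": spatial_extent,
        "peak_dff": peak_dff,
        "um_per_px": um_per_px,
    }
    return _assemble(dff, baseline, dt, truth, bleach_tau)


DEFAULT_DENDRITE_SIGMOID = SigmoidParams(
    amplitudes=(0.018, 0.008, 0.006),
    midpoints=(0.0105, 0.0115, 0.0135),
    slopes=(0.00025, 0.00060, 0.00120),
)
"""Default 3-sigmoid dF/F0 rise at the most proximal dendritic site: a ~3%
plateau after a somatic action potential at t ~ 10 ms (within-trace seconds).
The dominant first component is sub-millisecond — the Ca2+ current driven by
the brief AP depolarisation — followed by two smaller, slower components of
residual channel activation, so the derivative has one sharp, well-defined
peak as in AP-evoked dendritic recordings."""


def make_dendrite_scene(
    site_distances: Sequence[float] = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
    velocity: float = 0.141,
    sigmoid: SigmoidParams = DEFAULT_DENDRITE_SIGMOID,
    photons_per_site: float = 120_000.0,
    frame_rate: float = 10_000.0,
    duration: float = 0.060,
    um_per_px: float = 3.0,
    roi_height: int = 40,
    roi_width: int = 24,
    height: int = 56,
    background_gamma: float = 10.0,
    bleach_tau: float = math.inf,
) -> SceneSpec:
    """Back-propagating AP Ca2+ transients at sites along an apical dendrite.

    Site i (distance d_i um from the soma, increasing) carries the 3-sigmoid
    dF/F0 waveform delayed by ``d_i / velocity`` (velocity in m/s == um/ms ==
    um * 1e-3 / s... i.e. d um / v m/s = d / (1000 v) ms). Each site is a
    rectangular ROI whose summed baseline photon budget is
    ``photons_per_site`` per frame. The truth record stores the exact per-site
    delays, so derivative-peak times lie on the line t = d / velocity before
    any noise is added.
    """
    distances = np.asarray(site_distances, dtype=float)
    if len(distances) < 3:
        raise ValueError("need at least three sites")
    if np.any(np.diff(distances) <= 0):
        raise ValueError("site distances must be strictly increasing")
    if velocity <= 0:
        raise ValueError("velocity must be positive")

    n_frames = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    times = np.arange(n_frames) * dt
    # delay in seconds: d [um] / (v [m/s] * 1e6 [um/m]) * ... v m/s = 1e6 um/s
    delays = distances / (velocity * 1e6)

    cols = np.round(distances / um_per_px).astype(int)
    width = int(cols.max()) + roi_width + 4
    gamma_px = photons_per_site / (roi_height * roi_width)

    baseline = np.full((height, int(width)), float(background_gamma))
    dff = np.zeros((n_frames, height, int(width)))
    rois = []
    site_dff = np.zeros((len(distances), n_frames))
    r0 = (height - roi_height) // 2
    for i, (c, d) in enumerate(zip(cols, delays)):
        roi = (r0, r0 + roi_height, int(c), int(c) + roi_width)
        rois.append(roi)
        baseline[roi[0] : roi[1], roi[2] : roi[3]] = gamma_px
        w = three_sigmoid(times, sigmoid.shifted(d))
        site_dff[i] = w
        dff[:, roi[0] : roi[1], roi[2] : roi[3]] = w[:, None, None]

    truth = {
        "kind": "dendrite",
        "site_distances_um": distances.tolist(),
        "velocity_m_per_s": float(velocity),
        "site_delays_s": delays.tolist(),
        "sigmoid": sigmoid,
        "site_rois": rois,
        "site_dff": site_dff,
        "photons_per_site": photons_per_site,
        "stim_onset_s": float(min(sigmoid.midpoints)),
    }
    return _assemble(dff, baseline, dt, truth, bleach_tau)


def make_ais_scene(
    site_distances: Sequence[float] = (10.0, 20.0, 35.0),
    rise_slopes: Sequence[float] = (4.0, 7.0, 8.0),
    peak_dff: float = 0.08,
    frame_rate: float = 40_000.0,
    duration: float = 0.005,
    peak_times: Sequence[float] | None = None,
    photons_per_site: float = 30_000.0,
    um_per_px: float = 0.433,
    height: int = 21,
    width: int = 180,
    roi_height: int = 10,
    roi_width: int = 30,
    background_gamma: float = 10.0,
    bleach_tau: float = math.inf,
) -> SceneSpec:
    """Action-potential voltage transients at proximal/medial/distal AIS sites.

    ``rise_slopes`` are the 20-80% slopes of the *normalised* rise at each
    site, in fraction-of-peak per ms; distal and medial sites are steeper than
    the proximal one and the distal site peaks first (default peak times
    mirror that ordering). The waveform is a logistic rise truncated at the
    peak followed by a biexponential repolarisation.
    """
    distances = np.asarray(site_distances, dtype=float)
    slopes = np.asarray(rise_slopes, dtype=float)
    if len(distances) != len(slopes):
        raise ValueError("one rise slope per site required")
    if (slopes <= 0).any():
        raise ValueError("rise slopes must be positive")
    if peak_dff < 0:
        raise ValueError("peak dF/F0 must be >= 0")

    n_frames = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    times = np.arange(n_frames) * dt
    if peak_times is None:
        # distal first: later peaks for more proximal sites
        base = duration / 2.0
        order = np.argsort(-distances)  # most distal -> earliest
        peak_times_arr = np.empty(len(distances))
        for rank, idx in enumerate(order):
            peak_times_arr[idx] = base + rank * 3.0 * dt
    else:
        peak_times_arr = np.asarray(peak_times, dtype=float)

    # logistic time constant giving a 20-80% slope r on the normalised rise:
    # the rise from 0.2 to 0.8 spans 2*ln(4)*s seconds, so r = 0.6/(2 ln4 s).
    ln4 = math.log(4.0)
    s_site = 0.6 / (2.0 * ln4 * slopes * 1e3)  # slopes in /ms -> /s

    cols = np.clip(np.round(distances / um_per_px).astype(int), 0, width - roi_width)
    gamma_px = photons_per_site / (roi_height * roi_width)
    baseline = np.full((height, width), float(background_gamma))
    dff = np.zeros((n_frames, height, width))
    rois = []
    site_dff = np.zeros((len(distances), n_frames))
    r0 = (height - roi_height) // 2
    tau_fast, tau_slow = 0.25e-3, 1.2e-3
    for i, (c, tp, s) in enumerate(zip(cols, peak_times_arr, s_site)):
        m = tp - 3.5 * s  # rise ~97% complete at the peak
        w = _logistic((times - m) / s)
        top = _logistic((tp - m) / s)
        after = times > tp
        w[after] = top * (
            0.6 * np.exp(-(times[after] - tp) / tau_fast)
            + 0.4 * np.exp(-(times[after] - tp) / tau_slow)
        )
        w *= peak_dff / top  # exact peak at tp with value peak_dff
        roi = (r0, r0 + roi_height, int(c), int(c) + roi_width)
        rois.append(roi)
        baseline[roi[0] : roi[1], roi[2] : roi[3]] = gamma_px
        site_dff[i] = w
        dff[:, roi[0] : roi[1], roi[2] : roi[3]] = w[:, None, None]

    truth = {
        "kind": "ais",
        "site_distances_um": distances.tolist(),
        "rise_slopes_per_ms": slopes.tolist(),
        "peak_times_s": peak_times_arr.tolist(),
        "peak_dff": peak_dff,
        "site_rois": rois,
        "site_dff": site_dff,
        "photons_per_site": photons_per_site,
        "stim_onset_s": float(peak_times_arr.min() - 10 * dt),
    }
    return _assemble(dff, baseline, dt, truth, bleach_tau)


def make_blank_trial(scene: SceneSpec, bleach_tau: float = math.inf) -> SceneSpec:
    """No-stimulus companion trial: evoked dF/F0 zeroed, bleaching applied.

    Shares the parent's baseline map and frame timing; idempotent (the blank
    of a blank is itself, with the same bleach constant).
    """
    if bleach_tau <= 0:
        raise ValueError("bleach_tau must be positive (inf = no bleaching)")
    dff = np.zeros_like(scene.truth.get("dff_movie", np.zeros(scene.rate_movie.shape)))
    truth = {
        k: v
        for k, v in scene.truth.items()
        if k not in ("dff_movie", "site_dff")
    }
    truth["blank"] = True
    return _assemble(dff, scene.baseline_map, scene.frame_interval, truth, bleach_tau)
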