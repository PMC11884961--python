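"""Quantized photon-counting camera model and photon-transfer gain estimation.

An analog-to-digital converter with bit depth ``beta`` maps photoelectron
counts onto ``2**beta`` digital levels spanning the effective well capacity
(EWC) of the detector. The quantization step EWC / 2**beta sets the smallest
photoelectron difference the converter can discriminate; whether that matters
in practice depends on how it compares with the photon (shot) noise
sqrt(gamma) at mean signal gamma. At 8-bit depth with EWC ~ 200 the step is
below one photoelectron, so the camera behaves as a photon counter: one
digital number per photoelectron.

Detector gain (photoelectrons per digital unit) is estimated from data by
photon-transfer analysis: for shot-noise-limited light, the temporal variance
of the digital signal is proportional to its mean with slope 1/gain, and
offline binning provides the range of mean levels needed for the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binning import FrameStack, offline_bin

__all__ = [
    "CameraConfig",
    "PhotonTransferResult",
    "quantization_step",
    "quantize",
    "acquire",
    "gaussian_step_series",
    "estimate_gain",
]


@dataclass(frozen=True)
class CameraConfig:
    """Detector model: bit depth, well capacity, read noise, offset.

    Parameters
    ----------
    beta : int
        Bit depth of the A/D converter; digital values span 0 .. 2**beta - 1.
    ewc : float
        Effective well capacity in photoelectrons: the count mapped to the
        maximal digital value.
    read_noise_sd : float
        Gaussian read noise, photoelectrons RMS (0 = ideal photon counter).
    dark_offset_dn : int
        Constant digital offset added after conversion.
    gain_e_per_dn : float or None
        Optional override of the conversion gain in photoelectrons per
        digital unit. Some photon-counting devices advertise EWC slightly
        below 2**beta yet convert at exactly one electron per digital number;
        set this to 1.0 to reproduce that mode while keeping ``ewc`` as
        metadata. ``None`` uses ewc / 2**beta.
    """

    beta: int
    ewc: float
    read_noise_sd: float = 0.0
    dark_offset_dn: int = 0
    gain_e_per_dn: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("bit depth must be >= 1")
        if self.ewc <= 0:
            raise ValueError("effective well capacity must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read noise must be >= 0")
        if self.dark_offset_dn < 0:
            raise ValueError("dark offset must be >= 0")
        if self.gain_e_per_dn is not None and self.gain_e_per_dn <= 0:
            raise ValueError("gain override must be positive")

    @property
    def max_dn(self) -> int:
        return 2**self.beta - 1

    @property
    def step_e(self) -> float:
        """Photoelectrons per digital unit actually used by :func:`quantize`."""
        return self.gain_e_per_dn if self.gain_e_per_dn is not None else self.ewc / 2**self.beta

    @classmethod
    def photon_counting_8bit(cls) -> "CameraConfig":
        """8-bit photon-counting mode: EWC = 200, 1 digital unit = 1 e-."""
        return cls(beta=8, ewc=200.0, gain_e_per_dn=1.0)


@dataclass
class PhotonTransferResult:
    """Mean/variance pairs across binning levels and the fitted gain.

    ``slope`` is the OLS coefficient of temporal variance (SD^2) regressed on
    temporal mean; its reciprocal is the conversion gain in photoelectrons per
    digital unit (slope ~ 1 means one electron per digital number).
    """

    levels: list[int]
    means_dn: list[float]
    variances_dn: list[float]
    slope: float
    intercept: float
    r_squared: float = field(default=float("nan"))

    @property
    def gain_e_per_dn(self) -> float:
        return 1.0 / self.slope


def quantization_step(config: CameraConfig) -> float:
    """Theoretical discrimination limit EWC / 2**beta, in photoelectrons/DN."""
    return config.ewc / 2**config.beta


def quantize(photoelectrons: np.ndarray, config: CameraConfig) -> np.ndarray:
    """Convert photoelectron counts to digital numbers.

    The converter truncates: ``DN = clip(floor(e / step) + dark_offset, 0, 2**beta - 1)``.
    """
    pe = np.asarray(photoelectrons, dtype=np.float64)
    bad = ~np.isfinite(pe)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite photoelectron value at index {idx}")
    dn = np.floor(pe / config.step_e) + config.dark_offset_dn
    return np.clip(dn, 0, config.max_dn).astype(np.uint32 if config.beta > 16 else np.uint16 if config.beta > 8 else np.uint8)


def acquire(scene, config: CameraConfig, n_frames: int | None = None, seed: int | None = None) -> FrameStack:
    """Simulate an acquisition: Poisson shot noise + read noise + quantization.

    Per pixel and frame the detected count is
    ``Poisson(rate) + Normal(0, read_noise_sd)`` (rate in expected
    photoelectrons per frame, from ``scene.rate_movie``), then quantized.
    Reproducible for a fixed seed.
    """
    rates = np.asarray(scene.rate_movie, dtype=np.float64)
    if rates.min() < 0:
        raise ValueError("scene emission rates must be non-negative")
    if n_frames is not None:
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        reps = -(-n_frames // rates.shape[0])
        rates = np.tile(rates, (reps, 1, 1))[:n_frames]
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates).astype(np.float64)
    if config.read_noise_sd > 0:
        counts += rng.normal(0.0, config.read_noise_sd, size=counts.shape)
        counts = np.maximum(counts, 0.0)
    dn = quantize(counts, config)
    return FrameStack(
        data=dn,
        frame_interval=scene.frame_interval,
        bit_depth=config.beta,
        provenance="raw",
        extra={"camera": config},
    )


def gaussian_step_series(
    gamma: float,
    frac: float,
    n: int = 400,
    sd: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Analog photoelectron series with a mid-series fractional step.

    The first half is drawn from N(gamma, sd^2) and the second half from
    N(gamma * (1 + frac), sd^2); ``sd`` defaults to sqrt(gamma), the shot-noise
    SD at the baseline level. This is the idealised single-pixel signal used
    to examine what survives quantization at a given bit depth.
    """
    if gamma <= 0:
        raise ValueError("mean photoelectron level must be positive")
    if n % 2:
        raise ValueError("n must be even (equal halves before/after the step)")
    if gamma * (1.0 + frac) < 0:
        raise ValueError("fractional step would make the mean negative")
    if sd is None:
        sd = float(np.sqrt(gamma))
    rng = np.random.default_rng(seed)
    half = n // 2
    out = np.empty(n)
    out[:half] = rng.normal(gamma, sd, half)
    out[half:] = rng.normal(gamma * (1.0 + frac), sd, half)
    return out


def estimate_gain(stack: FrameStack, binning_levels: list[int]) -> PhotonTransferResult:
    """Photon-transfer analysis across offline-binning levels.

    For each level N the stack is sliding-binned and the temporal mean and
    variance of the *central* binned pixel are taken (a single pixel per
    level avoids the spatial correlation between overlapping windows).
    Variance is regressed on mean by OLS with a free intercept; the slope is
    1/gain.
    """
    if len(binning_levels) < 2:
        raise ValueError("need at least two binning levels for a regression")
    t, h, w = stack.data.shape
    means, variances = [], []
    for n in binning_levels:
        binned = stack if n == 1 else offline_bin(stack, n, mode="sliding")
        trace = binned.data[:, h // 2, w // 2].astype(np.float64)
        means.append(float(trace.mean()))
        variances.append(float(trace.var(ddof=1)))
    if np.allclose(variances, 0.0):
        raise ValueError("zero-variance data: photon-transfer analysis undefined")
    fit = stats.linregress(means, variances)
    return PhotonTransferResult(
        levels=list(binning_levels),
        means_dn=means,
        variances_dn=variances,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
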