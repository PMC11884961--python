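"""Multi-sigmoid waveforms shared by the scene generator and the kinetics fits.

A Ca2+ transient that rises to a plateau in discrete steps is described well
by a sum of three logistic terms,

    f(t) = sum_i a_i / (1 + exp(-(t - m_i) / s_i)) + c,

with amplitudes a_i >= 0, midpoints m_1 <= m_2 <= m_3 and time constants
s_i > 0. The form is monotone non-decreasing, its analytic time derivative

    f'(t) = sum_i a_i / (4 s_i) * sech^2((t - m_i) / (2 s_i))

is non-negative, and for a plateauing indicator signal that derivative tracks
the kinetics of the underlying Ca2+ current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SigmoidParams", "three_sigmoid", "three_sigmoid_deriv"]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of a 3-sigmoid rise: amplitudes, midpoints, slopes.

    Amplitudes are in dF/F0 units (>= 0), midpoints in seconds (sorted
    ascending), slopes are the logistic time constants in seconds (> 0).
    """

    amplitudes: tuple[float, float, float]
    midpoints: tuple[float, float, float]
    slopes: tuple[float, float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        m = np.asarray(self.midpoints, dtype=float)
        s = np.asarray(self.slopes, dtype=float)
        if a.shape != (3,) or m.shape != (3,) or s.shape != (3,):
            raise ValueError("SigmoidParams needs exactly three components")
        if (a < 0).any():
            raise ValueError("amplitudes must be >= 0")
        if (s <= 0).any():
            raise ValueError("slopes must be > 0")
        if not (m[0] <= m[1] <= m[2]):
            raise ValueError("midpoints must be sorted ascending")
        object.__setattr__(self, "amplitudes", tuple(float(x) for x in a))
        object.__setattr__(self, "midpoints", tuple(float(x) for x in m))
        object.__setattr__(self, "slopes", tuple(float(x) for x in s))

    @property
    def total_amplitude(self) -> float:
        return float(sum(self.amplitudes))

    def shifted(self, dt: float) -> "SigmoidParams":
        """Same waveform delayed by ``dt`` seconds."""
        return SigmoidParams(
            self.amplitudes,
            tuple(m + dt for m in self.midpoints),
            self.slopes,
        )


def three_sigmoid(t: np.ndarray, params: SigmoidParams, offset: float = 0.0) -> np.ndarray:
    """Evaluate the 3-sigmoid waveform at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, float(offset))
    for a, m, s in zip(params.amplitudes, params.midpoints, params.slopes):
        out += a / (1.0 + np.exp(np.clip(-(t - m) / s, -500.0, 500.0)))
    return out


def three_sigmoid_deriv(t: np.ndarray, params: SigmoidParams) -> np.ndarray:
    """Analytic time derivative of :func:`three_sigmoid` (offset drops out)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, m, s in zip(params.amplitudes, params.midpoints, params.slopes):
        # a/(4s) * sech^2((t-m)/(2s)), written via the logistic to avoid overflow
        z = 1.0 / (1.0 + np.exp(np.clip(-(t - m) / s, -500.0, 500.0)))
        out += a / s * z * (1.0 - z)
    return out
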