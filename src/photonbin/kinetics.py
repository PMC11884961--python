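"""Transient kinetics: 3-sigmoid fits, derivative Ca2+ currents, propagation
velocity and rise-slope analysis.

When a Ca2+ indicator signal reaches a steady-state plateau, the time
derivative of dF/F0 tracks the time course of the underlying Ca2+ current.
The workflow here is therefore: fit each site's dF/F0 transient with a
monotone 3-sigmoid function, differentiate the *fitted* curve analytically,
locate the current peak, and regress site distance against peak time (with
t = 0 at the most proximal peak) to obtain the mean propagation velocity
V_Ca in m/s. Voltage transients at the axon initial segment are compared
instead through the slope of their normalised rising phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .waveforms import SigmoidParams, three_sigmoid, three_sigmoid_deriv

__all__ = [
    "TransientFit",
    "CurrentKinetics",
    "VelocityEstimate",
    "fit_three_sigmoid",
    "current_kinetics",
    "fit_velocity",
    "rise_slope",
    "trace_noise",
]


@dataclass
class TransientFit:
    """Result of a 3-sigmoid least-squares fit to a dF/F0 transient."""

    params: SigmoidParams
    offset: float
    residual_rms: float
    fit_window: tuple[float, float]
    times: np.ndarray = field(repr=False)
    trace: np.ndarray = field(repr=False)

    def curve(self, t: np.ndarray) -> np.ndarray:
        return three_sigmoid(t, self.params, self.offset)

    def derivative(self, t: np.ndarray) -> np.ndarray:
        return three_sigmoid_deriv(t, self.params)

    def fine_grid(self, upsample: int = 10) -> np.ndarray:
        t0, t1 = self.fit_window
        n = len(self.times)
        return np.linspace(t0, t1, (n - 1) * upsample + 1)

    @property
    def fitted_curve(self) -> np.ndarray:
        return self.curve(self.fine_grid())

    @property
    def derivative_curve(self) -> np.ndarray:
        return self.derivative(self.fine_grid())


@dataclass
class CurrentKinetics:
    """Derivative (current) trace of a fitted transient and its peak time."""

    times: np.ndarray
    current: np.ndarray
    peak_time: float | None
    degenerate: bool = False


@dataclass
class VelocityEstimate:
    """Distance-vs-peak-time regression: the slope is V_Ca in m/s."""

    distances_um: np.ndarray
    peak_times_s: np.ndarray
    slope_m_per_s: float
    intercept_s: float
    r_squared: float
    excluded_sites: tuple[int, ...] = ()


def _initial_guesses(
    times: np.ndarray, trace: np.ndarray, n_restarts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Quantile-based multi-start initialisation for the 3-sigmoid fit."""
    c0 = float(np.median(trace[: max(3, len(trace) // 10)]))
    plateau = float(np.median(trace[-max(3, len(trace) // 10):]))
    amp = max(plateau - c0, 1e-12)
    rise = trace - c0
    span = times[-1] - times[0]

    def crossing(frac: float) -> float:
        idx = np.argmax(rise >= frac * amp)
        return float(times[idx]) if rise[idx] >= frac * amp else float(times[0] + frac * span)

    # jitter on the scale of the rising phase, not the whole trace (the trace
    # typically holds a long baseline and plateau around a brief rise)
    rise_dur = max(crossing(0.95) - crossing(0.05), span / 100.0)
    base_s = max(rise_dur / 12.0, span / 2000.0)
    quantile_sets = ((0.2, 0.5, 0.8), (0.1, 0.35, 0.7), (0.3, 0.6, 0.9), (0.15, 0.5, 0.9))
    guesses = []
    for k in range(n_restarts):
        fracs = quantile_sets[k % len(quantile_sets)]
        base_m = np.array([crossing(f) for f in fracs])
        if k < len(quantile_sets):
            m = base_m
            s = np.full(3, base_s)
            a = np.full(3, amp / 3.0)
        else:
            m = np.sort(base_m + rng.normal(0.0, 0.25 * rise_dur, 3))
            s = base_s * np.exp(rng.normal(0.0, 0.7, 3))
            a = np.full(3, amp / 3.0) * np.exp(rng.normal(0.0, 0.3, 3))
        guesses.append(np.concatenate([a, m, s, [c0]]))
    return guesses


def _sigmoid_residuals(x: np.ndarray, times: np.ndarray, trace: np.ndarray) -> np.ndarray:
    a, m, s, c = x[0:3], x[3:6], x[6:9], x[9]
    model = np.full_like(times, c)
    for i in range(3):
        z = np.clip(-(times - m[i]) / s[i], -500.0, 500.0)
        model = model + a[i] / (1.0 + np.exp(z))
    return model - trace


def _sigmoid_jacobian(x: np.ndarray, times: np.ndarray, trace: np.ndarray) -> np.ndarray:
    a, m, s = x[0:3], x[3:6], x[6:9]
    jac = np.empty((len(times), 10))
    for i in range(3):
        z = 1.0 / (1.0 + np.exp(np.clip(-(times - m[i]) / s[i], -500.0, 500.0)))
        zz = z * (1.0 - z)
        jac[:, i] = z
        jac[:, 3 + i] = -a[i] * zz / s[i]
        jac[:, 6 + i] = -a[i] * zz * (times - m[i]) / s[i] ** 2
    jac[:, 9] = 1.0
    return jac


def fit_three_sigmoid(
    trace: np.ndarray,
    times: np.ndarray,
    n_restarts: int = 16,
    seed: int | None = 0,
    max_nfev: int = 5000,
) -> TransientFit:
    """Least-squares fit of a 3-sigmoid function to a dF/F0 transient.

    Fits ``f(t) = sum_i a_i / (1 + exp(-(t - m_i)/s_i)) + c`` with a_i >= 0
    and s_i > 0 using bounded trust-region least squares, taking the best of
    ``n_restarts`` quantile-seeded multi-start initialisations (deterministic
    for a fixed seed). Midpoints are sorted ascending in the returned
    parameters; the fitted curve is monotone non-decreasing by construction.
    """
    trace = np.asarray(trace, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if trace.shape != times.shape or trace.ndim != 1:
        raise ValueError("trace and times must be matching 1-D arrays")
    if len(trace) < 30:
        raise ValueError("need at least 30 samples spanning baseline to plateau")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")

    rng = np.random.default_rng(seed)
    span = times[-1] - times[0]
    dt = span / (len(times) - 1)
    # bounds keep the fit physical: slopes no steeper than one sample interval
    # (a noise spike fitted by a quasi-step would dominate the analytic
    # derivative), midpoints inside the fit window (the trace is required to
    # cover baseline through plateau, and an out-of-window sigmoid toe merely
    # mimics baseline drift with unbounded amplitude), amplitudes bounded by
    # a generous multiple of the observed excursion
    a_max = 3.0 * max(np.ptp(trace), 1e-9)
    lower = np.concatenate([np.zeros(3), np.full(3, times[0]), np.full(3, dt), [-np.inf]])
    upper = np.concatenate(
        [np.full(3, a_max), np.full(3, times[-1]), np.full(3, 2.0 * span), [np.inf]]
    )

    best = None
    best_cost = np.inf
    any_success = False
    n_at_best = 0
    for x0 in _initial_guesses(times, trace, n_restarts, rng):
        x0 = np.clip(x0, lower + 1e-15, upper - 1e-15)
        res = optimize.least_squares(
            _sigmoid_residuals,
            x0,
            jac=_sigmoid_jacobian,
            bounds=(lower, upper),
            args=(times, trace),
            method="trf",
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev,
        )
        any_success = any_success or res.success
        if res.cost < best_cost * (1.0 - 1e-8):
            best_cost = res.cost
            best = res
            n_at_best = 1
        elif res.cost <= best_cost * (1.0 + 1e-8):
            if best is None:
                best = res
            n_at_best += 1
            if n_at_best >= 3:  # same optimum found repeatedly: stop early
                break
    if best is None or not any_success:
        rms = np.sqrt(2.0 * best_cost / len(trace)) if best is not None else np.nan
        raise RuntimeError(f"3-sigmoid fit failed to converge (best residual RMS {rms:.3g})")

    a, m, s, c = best.x[0:3], best.x[3:6], best.x[6:9], best.x[9]
    order = np.argsort(m)
    params = SigmoidParams(tuple(a[order]), tuple(m[order]), tuple(s[order]))
    rms = float(np.sqrt(np.mean(_sigmoid_residuals(best.x, times, trace) ** 2)))
    return TransientFit(
        params=params,
        offset=float(c),
        residual_rms=rms,
        fit_window=(float(times[0]), float(times[-1])),
        times=times,
        trace=trace,
    )


def current_kinetics(fit: TransientFit, upsample: int = 10) -> CurrentKinetics:
    """Analytic derivative of the fitted transient and its peak time.

    The derivative is evaluated on a grid upsampled ``upsample``-fold relative
    to the data, the discrete argmax (earliest on ties) is refined by bounded
    scalar maximisation of the analytic derivative, so a single-logistic fit
    peaks exactly at its midpoint. An all-zero fit has no defined peak and is
    flagged degenerate.
    """
    grid = fit.fine_grid(upsample)
    deriv = fit.derivative(grid)
    scale = fit.params.total_amplitude
    if scale <= 1e-9 or deriv.max() <= 0:  # null fit: no resolvable transient
        return CurrentKinetics(times=grid, current=deriv, peak_time=None, degenerate=True)
    k = int(np.argmax(deriv))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: -fit.derivative(np.asarray([t]))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        peak = float(res.x)
    else:
        peak = float(grid[k])
    return CurrentKinetics(times=grid, current=deriv, peak_time=peak)


def fit_velocity(
    sites: Sequence[tuple[float, float]],
    exclude: Sequence[int] = (),
) -> VelocityEstimate:
    """Propagation velocity from per-site current-peak times.

    ``sites`` are (distance um, peak time s) pairs. Peak times are re-zeroed
    at the most proximal *included* site, then distance (in metres) is
    regressed on time by OLS; the slope is V_Ca in m/s (um/ms and m/s are the
    same unit). Sites listed in ``exclude`` (e.g. the dendritic tuft) are
    dropped before fitting.
    """
    exclude = tuple(sorted(set(int(i) for i in exclude)))
    included = [(d, t) for i, (d, t) in enumerate(sites) if i not in exclude]
    if len(included) < 3:
        raise ValueError("need at least three included sites")
    d = np.array([p[0] for p in included], dtype=float)
    t = np.array([p[1] for p in included], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("peak times are all identical; velocity undefined")
    t0 = t[np.argmin(d)]
    t = t - t0
    fit = stats.linregress(t, d * 1e-6)  # distance in metres vs time in s
    return VelocityEstimate(
        distances_um=d,
        peak_times_s=t,
        slope_m_per_s=float(fit.slope),
        intercept_s=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        excluded_sites=exclude,
    )


def rise_slope(
    trace: np.ndarray,
    times: np.ndarray,
    lo_frac: float = 0.2,
    hi_frac: float = 0.8,
) -> float:
    """Slope of the normalised rising phase, in fraction-of-peak per ms.

    The trace is normalised to [0, 1] (min to peak); an OLS line is fitted to
    the samples between the first crossings of ``lo_frac`` and ``hi_frac``.
    With fewer than two samples in that range the two-point secant through the
    interpolated crossing times is used instead. Amplitude scaling leaves the
    result unchanged.
    """
    trace = np.asarray(trace, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if not 0.0 <= lo_frac < hi_frac <= 1.0:
        raise ValueError("require 0 <= lo_frac < hi_frac <= 1")
    peak_idx = int(np.argmax(trace))
    lo_v, hi_v = trace.min(), trace[peak_idx]
    if hi_v <= lo_v:
        raise ValueError("trace has no rise (peak equals minimum)")
    norm = (trace - lo_v) / (hi_v - lo_v)

    rising = norm[: peak_idx + 1]
    above_lo = np.nonzero(rising >= lo_frac)[0]
    above_hi = np.nonzero(rising >= hi_frac)[0]
    if len(above_lo) == 0 or len(above_hi) == 0:
        raise ValueError("lo/hi fraction crossings not found on the rising phase")
    i_lo, i_hi = int(above_lo[0]), int(above_hi[0])

    def interp_crossing(i: int, frac: float) -> float:
        if i == 0 or rising[i] == rising[i - 1]:
            return float(times[i])
        w = (frac - rising[i - 1]) / (rising[i] - rising[i - 1])
        return float(times[i - 1] + w * (times[i] - times[i - 1]))

    if i_hi - i_lo >= 2:
        seg_t, seg_y = times[i_lo : i_hi + 1], norm[i_lo : i_hi + 1]
        slope_per_s = float(stats.linregress(seg_t, seg_y).slope)
    else:
        t_lo = interp_crossing(i_lo, lo_frac)
        t_hi = interp_crossing(i_hi, hi_frac)
        if t_hi <= t_lo:
            raise ValueError("degenerate rise: crossings coincide")
        slope_per_s = (hi_frac - lo_frac) / (t_hi - t_lo)
    return slope_per_s / 1e3  # per second -> per ms


def trace_noise(trace: np.ndarray, baseline_window: tuple[int, int]) -> float:
    """Relative photon-noise level: SD / mean of the trace over a
    stimulus-free baseline window (half-open frame-index range).

    For a Poisson photon budget of gamma photoelectrons per frame this is
    1/sqrt(gamma); averaging k trials divides it by sqrt(k).
    """
    lo, hi = baseline_window
    seg = np.asarray(trace, dtype=np.float64)[lo:hi]
    if len(seg) < 2:
        raise ValueError("baseline window must contain at least two samples")
    mean = seg.mean()
    if mean == 0:
        raise ValueError("zero baseline mean; relative noise undefined")
    return float(seg.std(ddof=1) / mean)
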