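# Methods

## Detector model

A camera pixel detects a Poisson-distributed number of photoelectrons per
frame; the analog-to-digital converter maps them onto `2^beta` digital levels
spanning the effective well capacity (EWC), so the quantization step is
`EWC / 2^beta` photoelectrons per digital number (DN). `quantize` truncates
(`floor`) and clips to `[0, 2^beta - 1]`; truncation matches typical ADC
behaviour, and none of the arithmetic the toolkit reproduces depends on the
rounding convention. Read noise (Gaussian, in e⁻ RMS) and a dark DN offset
are available but default to 0: the 8-bit mode of interest behaves as a pure
photon counter.

`CameraConfig.photon_counting_8bit()` encodes that mode: beta = 8, EWC = 200.
Taken literally those numbers give a step of 200/256 < 1 e⁻, yet
photon-transfer measurements of such devices show one digital unit per
photoelectron. The config therefore accepts a `gain_e_per_dn` override
(set to 1.0 in the preset, clip still at 255) and keeps EWC as metadata;
`quantization_step` always reports the theoretical EWC/2^β limit.

Photon-transfer gain estimation (`estimate_gain`) bins a stationary uniform
stack at a series of window sizes, takes the temporal mean and variance of
the **central binned pixel only** (overlapping sliding windows are spatially
correlated; one pixel per level keeps the regression points independent), and
fits variance against mean by ordinary least squares with a free intercept.
The slope estimates 1/gain; the intercept (expected ≈ 0, or the read-noise
variance) is reported, not forced.

## Offline binning

Sliding binning assigns to pixel (i, j) the sum over the window rows
`[i - floor(N/2), i + ceil(N/2) - 1]` (top-left-biased for even N, a
convention shared with the median filter). At the borders the window is
intersected with the frame and the per-pixel contributing count is returned
alongside — no data are fabricated outside the frame, and all statistical
assertions in the tests use interior (full-window) pixels. Block binning sums
non-overlapping tiles. Accumulation is int64 via an exact integral image, so
binned integer stacks are bit-exact regardless of the nominal output depth
`beta + 2*ceil(log2 N)`. Both modes are provided because display-scale
binning can reasonably be either.

## Synthetic scenes

The generators produce expected-photoelectron-rate movies satisfying
`rate = baseline * (1 + dFF_true) * exp(-t / bleach_tau)` together with the
exact per-site ΔF/F₀ waveforms ("truth"). All randomness lives in `acquire`;
scenes are deterministic. Defaults encode the conditions of the three
emulated experiments:

- **Wave scene** (2 kHz, 150 ms, 64 × 96 px at 4 µm/px): six pulses at
  100 Hz from t = 20 ms; each pulse adds a logistic ΔF/F₀ increment
  (2 ms rise) decaying with τ = 80 ms; a pixel at distance d µm sees the
  train delayed by d/speed (default 0.02 m/s, crossing ~250 µm during the
  train) and attenuated by `2^(-d/extent)` so the response at
  `spatial_extent` (250 µm) is exactly half the origin peak (default 2.8%).
  Baseline 150 e⁻/pixel/frame, in the 100–200 range such staining yields.
  The per-pulse kinetics are a modelling choice, not a measured waveform.
- **Dendrite scene** (10 kHz, 60 ms, 56 × ~230 px at 3 µm/px): seven sites
  at 0–600 µm, each a 40 × 24 px ROI whose baseline sums to 120,000
  e⁻/frame (> 10⁵, the regime where nine-trial averaging reaches < 0.4%
  noise). Site i carries the 3-sigmoid waveform delayed by d_i/velocity
  (default 0.141 m/s), so true derivative-peak times lie exactly on the
  line t = d/v. The default waveform is a ~3% plateau whose dominant first
  component is sub-millisecond — the Ca²⁺ current driven by the brief AP
  depolarisation — followed by two smaller, slower components; a sharp
  dominant component is what makes the derivative peak well defined, as in
  AP-evoked recordings.
- **AIS scene** (40 kHz, 5 ms, 21 × 180 px at 0.433 µm/px): three sites at
  10/20/35 µm with 30 × 10 px ROIs collecting 30,000 e⁻/frame (> 2.5×10⁴,
  the < 1% noise regime). Waveforms are a logistic rise truncated at the
  peak (8% ΔF/F₀) followed by a biexponential repolarisation
  (τ = 0.25/1.2 ms). `rise_slopes` are the 20–80% slopes of the normalised
  rise in fraction-of-peak per ms (defaults 4/7/8: distal and medial
  steeper than proximal); peaks stagger by 3 frames (75 µs), distal first,
  matching the observed frame ordering. Only the slope ordering and peak
  ordering are asserted as contracts; the waveform shape itself is
  invented plumbing.

Blank trials share the parent's baseline map and timing, zero the evoked
component, and apply a single-exponential spatially uniform bleach — the
simplest model consistent with blank-trial subtraction being exact.

What the generators do **not** emulate: spatial structure of real tissue
(anatomy, non-uniform staining beyond the site/background split), dye
buffering and indicator nonlinearity, channel biophysics, motion, and
fixed-pattern detector noise. Passing tests therefore demonstrate that the
*pipeline arithmetic and estimators* behave as claimed under Poisson photon
statistics and quantization — not that any particular biological waveform is
correct.

## ΔF/F₀ pipeline

Order of operations: (optional binning) → bleach correction → F₀ → ΔF/F₀ →
trial averaging → spatial filtering → masking → rendering.

- **F₀** is the per-pixel temporal mean over an explicit pre-stimulus frame
  window; a warning is raised if the window is known (from scene truth) to
  reach past the stimulus.
- **Bleach correction**: with `b(t)` the Savitzky–Golay-smoothed blank
  (default window 21 samples, order 3 — smoothing the blank avoids adding a
  second dose of photon noise) and `<b>` its baseline mean,
  `corrected = (stack - b) / g + <b>`, where `g(t)` is the spatially pooled
  relative bleach course `mean_pixels(b(t)) / mean_pixels(<b>)`. Plain
  subtraction removes the baseline trend but leaves the evoked component
  attenuated by the bleach factor (bleached dye no longer reports the
  stimulus); the rescaling makes the correction exact in expectation for
  any bleach strength, and reduces to pure subtraction for a flat blank.
  `g` is pooled spatially because the bleach model is spatially uniform and
  a per-pixel ratio would bias late frames upward through its noisy
  denominator (E[1/x] > 1/E[x]). Adding `<b>` back preserves the F₀ scale.
- **Adaptive Wiener** (`wiener2`-style): per pixel,
  `out = mu + max(var - nu, 0)/max(var, nu) * (in - mu)` with local moments
  over a window (default 9 × 9 ≈ 80 pixels of neighbourhood area — the
  published description of the filter size is ambiguous between side, area
  and radius, so the window is configurable and no exact equivalence is
  claimed) and noise power `nu` the frame-mean local variance; applied
  `passes` times (3 in the emulated workflow). Local moments use the same
  exact window sums as binning, so the implementation agrees with a direct
  per-pixel evaluation to < 1e-12.
- **Masking**: pixels with F₀ below a configurable fraction (default 10%)
  of the robust (99th-percentile) maximum are dark and excluded (NaN).
- **Rendering**: each frame is median-filtered (default 8 × 8, same even
  anchor as binning) and mapped linearly onto a colour scale over
  [lo, hi]; below lo the background shows through, above hi saturates at
  the top colour. Presets: (0.7%, 2.8%) wave, (1%, 4%) dendrite,
  (2%, 8%) AIS.

## Transient kinetics

`fit_three_sigmoid` minimises least squares for
`f(t) = sum_i a_i / (1 + exp(-(t - m_i)/s_i)) + c` with bounds `a_i >= 0`
(monotone rise, non-negative derivative), `s_i >=` one sample interval (a
sigmoid steeper than the sampling is unresolvable, and without the bound a
single noise sample can be fitted by a quasi-step whose analytic derivative
dwarfs the real peak), `m_i` inside the fit window (the trace must cover
baseline through plateau; an out-of-window sigmoid toe merely mimics
baseline drift with unbounded amplitude), and `a_i <= 3 * ptp(trace)`. The
sum-of-logistics form is one of several "3-sigmoid" conventions; a sum was
chosen because it is monotone for multi-step rises and has a closed-form
derivative. Optimisation is bounded trust-region least squares with an
analytic Jacobian, tolerances 1e-10, at most 5000 function evaluations per
start, and a 16-start multi-start (quantile-seeded midpoints, jittered on
the scale of the rising phase; deterministic per seed; stops early once
three starts agree on the optimum). Midpoints are sorted ascending in the
result.

`current_kinetics` evaluates the analytic derivative on a 10×-upsampled
grid and refines the discrete argmax (earliest sample on ties) by bounded
scalar maximisation, so a single-logistic fit peaks exactly at its
midpoint. Fits with total amplitude below 1e-9 are flagged degenerate (no
peak). `fit_velocity` re-zeroes peak times at the most proximal included
site, then regresses distance (m) on time (s) — distance on time, so the
slope is directly m/s — optionally excluding sites (e.g. the dendritic
tuft, where propagation departs from the linear trend). `rise_slope`
normalises a trace to [0, 1] and fits a line between the first 20% and 80%
crossings of the rising phase (two-point interpolated secant when fewer
than three samples lie between).

`trace_noise` is SD/mean over a stimulus-free window: `1/sqrt(gamma)` for a
Poisson budget of gamma e⁻/frame, divided by `sqrt(k)` after averaging k
trials.

## Numerical and design choices

- Quantization: floor + clip; step-grid identity `quantize(k*step) = k`
  holds exactly for integer k below saturation.
- Window sums (binning, Wiener moments) use exact cumulative-sum integral
  images: integer results are bit-exact, float results agree with direct
  summation to machine precision.
- Degenerate inputs raise: zero-variance photon-transfer stacks, empty or
  out-of-bounds ROIs, non-finite traces, all-identical peak times,
  windows larger than frames.
- Problem sizes: simulations run at reduced frame sizes (e.g. the dendrite
  scene is 56 × ~230 px rather than 800 × 140) chosen so every statistical
  contract is still comfortably resolved; photon budgets per ROI match the
  emulated experiments, which is what fixes the noise levels.
- Monte-Carlo test sizes (e.g. 20 seeds for derivative-peak recovery, 6
  datasets for velocity recovery) are fixed-seed and sized to keep the
  suite fast while leaving the asserted medians well inside their bounds.

## Known limitations

- The bleach-factor rescaling assumes spatially uniform bleaching; strongly
  non-uniform bleaching would need a per-region pooled course.
- The 3-sigmoid fit is a local optimiser with multi-start; pathological
  traces (non-monotone, multiple plateaus) can converge to poor fits — the
  residual RMS is reported for screening.
- Saturation (clipping at `2^beta - 1`) is modelled but not corrected for;
  scenes whose bright pixels approach the clip will bias photon-transfer
  and ΔF/F₀ estimates.
- GIF/TIFF rendering only; no video-codec output.
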