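# photonbin

Functional neuroimaging — Ca²⁺ and membrane-potential fluorescence — normally
demands 12-bit or deeper cameras, because the signals are fractional changes
ΔF/F₀ of 0.1–10%. That bit depth caps how many pixels can be read out per
frame at kHz rates. An alternative is to acquire at **8-bit depth**, where a
photon-counting camera mode makes one digital unit correspond to roughly one
photoelectron, and to recover small signals afterwards by **N × N offline
binning**: assigning to each pixel the sum of the digital values in the N × N
window around it. Summing 2 × 2 8-bit values yields a 10-bit value, 4 × 4
yields 12-bit — binning grows both the photon count and the effective digital
depth, at the cost of spatial resolution.

`photonbin` is a simulator + analysis toolkit for this imaging mode:

- **camera** — quantized detector model (bit depth β, effective well capacity
  EWC, step EWC/2^β), Poisson photon statistics, and photon-transfer gain
  estimation: temporal variance regressed on temporal mean across binning
  levels has slope 1/gain (slope ≈ 1 ⇒ 1 digital unit ≈ 1 e⁻).
- **binning** — exact integer N × N sliding/block window sums with correct
  bit-depth growth, and the equivalent rectangular ROI traces.
- **scenes** — synthetic ground-truth photoelectron-rate movies emulating
  three experiments: a stimulus-locked Ca²⁺ wave in a hippocampal slice
  (2 kHz), back-propagating-AP Ca²⁺ transients along an apical dendrite
  (10 kHz), and AP voltage transients in the axon initial segment (40 kHz),
  plus blank (no-stimulus) trials with exponential photobleaching.
- **dff** — ΔF/F₀ pipeline: blank-trial bleach correction (Savitzky–Golay
  smoothed), F₀ estimation, trial averaging, adaptive Wiener filtering,
  median filtering + dark-pixel masking, colour-scale rendering.
- **kinetics** — fits each transient with a 3-sigmoid
  f(t) = Σᵢ aᵢ / (1 + exp(−(t − mᵢ)/sᵢ)) + c, takes the *analytic* time
  derivative (which tracks the Ca²⁺ current when the transient plateaus),
  locates current peaks, and regresses distance on peak time to estimate the
  propagation velocity V_Ca in m/s; also rise-slope comparison for voltage
  transients and ROI photon-noise measurement.

## Worked example: velocity of Ca²⁺-current propagation

Simulate the 7-site dendritic scene at a ground-truth velocity of 0.141 m/s,
acquire nine 8-bit trials, average, fit, differentiate, and regress:

```python
import numpy as np
from photonbin import (
    CameraConfig, acquire, trial_average, roi_trace, trace_noise,
    fit_three_sigmoid, current_kinetics, fit_velocity, make_dendrite_scene,
)

scene = make_dendrite_scene(velocity=0.141)          # 7 sites, 0-600 um, 10 kHz
camera = CameraConfig.photon_counting_8bit()         # beta=8, EWC=200, 1 e-/DN
trials = [acquire(scene, camera, seed=k) for k in range(9)]
movie = trial_average(trials)

peaks = []
for i, roi in enumerate(scene.truth["site_rois"]):
    f = roi_trace(movie, roi, "sum")                 # >100,000 photons/frame
    dff = f / f[:90].mean() - 1.0
    print(f"site {i}: noise {100 * trace_noise(f, (0, 90)):.3f}%")
    fit = fit_three_sigmoid(dff, scene.times, seed=i)
    peaks.append(current_kinetics(fit).peak_time)

est = fit_velocity(list(zip(scene.truth["site_distances_um"], peaks)), exclude=(6,))
print(f"V_Ca = {est.slope_m_per_s:.3f} m/s  (r^2 = {est.r_squared:.4f})")
```

Output:

```
site 0: noise 0.094%
site 1: noise 0.094%
site 2: noise 0.095%
site 3: noise 0.101%
site 4: noise 0.091%
site 5: noise 0.092%
site 6: noise 0.102%
V_Ca = 0.134 m/s  (r^2 = 0.9951)
```

Each ROI collects > 100,000 photoelectrons per frame, so averaging nine
trials brings the photon noise below 0.1% of baseline fluorescence — small
enough that the per-site ΔF/F₀ transients (a ~3% rise) can be fitted and the
velocity recovered within a few percent of the ground truth. On the noiseless
truth waveforms the same pipeline returns 0.141 m/s with r² = 1.

A command-line surface wraps the same functionality:

```sh
photonbin simulate --scene dendrite --velocity 0.141 --seed 7 --out run/
photonbin bin --n 5 --mode sliding run/dendrite.tif run/binned.tif
photonbin photon-transfer --levels 1,3,5,7,9,11,13,15 --out run/
photonbin dff --blank blank.tif --baseline 0:90 run/dendrite.tif run/dff.tif
photonbin render --lo 0.01 --hi 0.04 run/dff.tif run/movie.gif
```

## Conventions

Frames are indexed `(t, row, col)`, 0-based; ROIs are half-open
`(row_start, row_stop, col_start, col_stop)` rectangles. Stacks travel as
multi-page grayscale TIFF with a JSON sidecar carrying the frame interval,
bit depth and processing provenance. Distances are in µm, times in seconds,
velocities in m/s (≡ µm/ms). See `docs/methods.md` for the model details and
design choices.
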