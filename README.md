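# okrsphere

Analysis tools for the optokinetic response (OKR) of larval zebrafish
measured in a spherical LED stimulus arena. The package is aimed at
behavioural and systems neuroscientists who present moving gratings across
the whole visual field — not just on a flat screen — and want to turn raw
eye-position traces into spatial, frequency, and size tuning maps with
honest uncertainty and inference.

It covers the full chain:

- **Arena and stimulus geometry on the sphere** — fish-centred geographic
  coordinates (azimuth α positive to the right, elevation β positive above,
  (0, 0) rostral), spherical-cap and latitude-band coverage formulas, the
  solid angle of flat square LED tiles, and a procedural model of the
  232-tile / 14,848-LED arena.
- **Stimulus design** — 38 near-equidistant disk-stimulus centres generated
  by constrained repulsion of 7 seed points expanded under the three mirror
  planes of the protocol, plus drifting square-wave gratings with a
  sinusoidal velocity envelope, crop masks, and LED rasterisation.
- **Slow-phase trace analysis** — saccade detection and removal, and a
  joint piecewise-sinusoid fit over all inter-saccade intervals (ISIs):

      f(t ∈ ISI_k) = −c1·cos(c2·t + c3) + c_{k+3}

  with shared amplitude c1, angular frequency c2 and phase c3, and one free
  offset per ISI. The OKR gain is g = a_E / a_S = c1 / a_S, where
  a_S = A_v / (2πf) is the position amplitude of the stimulus (A_v velocity
  amplitude, f envelope frequency).
- **Spatial tuning** — the gain surface over stimulus position is modelled
  as a sum of two von Mises–Fisher components plus an offset,

      F(ξ) = Σ_j C_j κ_j exp(κ_j μ_jᵀξ) / (2π(e^{κ_j} − e^{−κ_j})) + C3,

  fitted by bounded multi-start least squares; plus vMF-kernel
  (Nadaraya–Watson) smoothing of the discrete samples, the rotated-arena
  bias correction, and sigmoid-in-log-size / log-Gaussian frequency tuning
  curves.
- **Asymmetry statistics** — yoking index Y = (g_L − g_R)/(g_L + g_R), the
  hemispheric bias index B = (m_L − m_R)/(m_L + m_R), the linear asymmetry
  decomposition B_k = φ·b1 + b2 + b3,k + η fitted by two-stage regression,
  and an exact permutation test of fish-level group labels.
- **Synthetic data** — a seeded generator producing cohorts of gain tables
  and raw 60 Hz eye traces with the exact statistical structure the
  analysis assumes, so every stage is testable without an animal.

## Worked example

Simulate a 7-fish position-tuning cohort (38 disk stimuli of 40°
diameter, two repetitions), re-estimate gains from the raw traces of one
trial, and fit the spatial tuning surface:

```python
import numpy as np
from okrsphere import (
    BimodalVmfModel, StimulusSpec, default_cohort, default_truth,
    generate_dataset, okr_gain, place_stimulus_centres,
)
from okrsphere.traces import detect_saccades, fit_piecewise_sinusoid

truth = default_truth(gain_noise_sd=0.06, sigma_e=0.1, saccade_rate=0.3)
centres = place_stimulus_centres()
cohort = default_cohort(n_fish=7, truth=truth, centres=centres,
                        n_repetitions=2, rng_seed=0)
table, traces = generate_dataset(cohort, truth)

tr = traces[14]
fit = fit_piecewise_sinusoid(tr, detect_saccades(tr), f_init=0.1)
print(fit.summary())
print("gain:", round(okr_gain(fit, StimulusSpec()).gain, 4))

res = BimodalVmfModel(table[table.stimulated == "direct"]).fit()
print(res.summary())
```

```
Piecewise sinusoid fit
======================
amplitude c1         1.8054 deg
ang. freq c2         0.6283 rad/s  (0.1000 Hz)
phase c3             0.0004 rad
ISIs                 25
observations       5414
residual RMS         0.1008 deg
R^2                  0.9999

gain: 0.0907

Bimodal von Mises-Fisher fit
============================
centre 1 (az, el)   (  -81.36,    7.03) deg   kappa   10.254  mass   0.1841
centre 2 (az, el)   (   80.81,    3.91) deg   kappa    8.479  mass   0.1872
offset C3               0.0472
positions               38
R^2                     0.9093
multi-starts             5
surface maxima      (  -81.36,    7.03) / (   80.81,    3.91) deg
```

The sinusoid fit recovers the 0.1 Hz envelope exactly and an eye
amplitude of 1.81°; against the 19.89° stimulus position amplitude that
is a gain of 0.09 for this off-peak stimulus location. The surface fit
places the two preferred locations laterally and slightly above the
equator, within a few degrees of the generator's ground-truth component
centres at (−82.5°, 5.1°) and (81.7°, 1.6°).

A command-line interface wraps the same stages:

```bash
okrsphere design-centres --seed 0 --out centres.json
okrsphere coverage-report
okrsphere simulate --seed 0 --out data/
okrsphere analyze-traces --traces data/traces --out gains.csv
okrsphere run --seed 0 --out results/
```

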