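# Methods

This note documents the models implemented in `okrsphere`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open.

## Coordinates and arena geometry

All directions are fish-centred geographic coordinates: azimuth
α ∈ [−180°, 180°], positive to the animal's right; elevation
β ∈ [−90°, 90°], positive above; (0, 0) directly rostral. The Cartesian
frame is x = East (right), y = North (rostral), z = Up, so
u = (cos β sin α, cos β cos α, sin β). Any right-handed frame used
consistently would do; this one makes equatorial azimuth a plain rotation
about z. Azimuth ±180° is normalised to +180° and the azimuth at the
poles is fixed to 0 so coordinate round-trips are deterministic. Public
interfaces use degrees throughout; radians appear only inside functions.

Coverage formulas are exact closed forms: a spherical cap of half-angle θ
occupies (1 − cos θ)/2 of the sphere; the band between latitudes ±L
occupies 1 − 2·cap(90° − L); an LED-free keel strip spanning w degrees of
azimuth scales the band fraction by (360 − w)/360. With the arena's
L = 69° and w = 30° these give 93.36% and 85.58%. Note that stimulus
sizes quoted as a "solid angle" or "stimulus diameter" in planar degrees
are full angles — a 180° stimulus is a 90° half-angle cap covering 50% of
the sphere; the smallest stimulus (10.4° half-angle) covers 0.8%.

The solid angle of one flat square tile of edge D tangent to a sphere of
radius R is computed by numerical quadrature of the central projection,
Ω = ∫∫ (1 + x² + y²)^{−3/2} dx dy over |x|, |y| ≤ D/2R, and checked
against the rectangular-pyramid closed form
4·arctan(D² / (2R·√(4R² + 2D²))); the two agree to better than 1e−9 sr
across D/R from 0.01 to 1. With D = 21 mm, R = 106.5 mm and 232 tiles the
tile-projection coverage evaluates to ≈ 71.1% of the sphere. The arena
build documentation quotes "around 66.5%"; that figure is not reproducible
from this projection (it likely reflects a different mounting distance or
counts the inter-tile gaps differently), so `arena_coverage` reports the
computed value and never asserts the quoted one. The procedural tile
layout (`build_arena`) packs rings of latitude to reproduce the tile and
LED counts and approximate distribution; it is not the physical CAD.

## Stimulus centre placement

The position-tuning protocol uses 38 disk-stimulus centres spread nearly
equidistantly and symmetrically over the sphere. Seven seed points live
in the closed positive octant: one fixed at the lateral equator (90, 0),
two constrained to the lateral meridian (azimuth 90, elevation free), one
constrained to the equator (elevation 0), three free. The full set is the
union of their orbits under the three mirror planes (left/right, up/down,
front/rear), with orbit sizes 2, 4, 4 and 8: 2 + 4 + 4 + 3×8 = 38.

Placement relaxes the seeds under mutual repulsion: pairwise forces
∝ 1/chordᵖ are projected onto each seed's tangent plane and then onto its
constraint set; the images are regenerated by reflection each step, so
the configuration stays exactly symmetric rather than approximately so.
Step size adapts to keep the matching Riesz energy strictly decreasing
(halved on an uphill trial step, re-expanded after accepted ones);
convergence is declared when the largest seed displacement falls below
1e−6 rad, and coordinates are rounded to 0.1°. The default exponent is
p = 6. A plain Coulomb force (p = 2) converges to a configuration whose
closest pair sits at 29.6° separation; steeper repulsion approaches the
max-min packing and keeps every pair at least 30° apart (30.1° at p = 6),
which is what "near-equidistant" is taken to mean here. The exponent is a
parameter for anyone who prefers the physical analogy over the packing.

Gratings are 50%-duty square waves in azimuth (meridian-bounded bars —
the display is binary LEDs, so a square profile is the natural choice),
displaced by the integral of the sinusoidal velocity envelope:
s(t) = a_S(1 − cos 2πft) with a_S = A_v/(2πf). Defaults follow the
position-tuning protocol: 0.06 cycles/°, A_v = 12.5 °/s, f = 0.1 Hz,
100 s per phase, 40° stimulus diameter (20° crop half-angle).
Rasterisation samples each LED at 60 Hz by default.

## Slow-phase analysis

Saccades are detected by thresholding a Savitzky–Golay smoothed
derivative of the eye-position trace (window ≈ 50 ms, default threshold
40 °/s), merging events closer than 0.5 s and padding each by 0.1 s.
These defaults are deliberately conservative for 60 Hz traces whose quick
phases move several degrees in one or two samples; all are configurable.

The remaining inter-saccade intervals are fitted jointly with
f(t ∈ ISI_k) = −c1·cos(c2 t + c3) + c_{k+3}. Because c1 and the offsets
enter linearly given (c2, c3), the fit uses variable projection: per-ISI
intercepts are profiled out exactly by within-ISI demeaning, leaving a
two-parameter nonlinear search solved by bounded least squares from two
phase starts (the profiled amplitude makes the landscape π-periodic in
c3). c2 is fitted rather than fixed, initialised at the known envelope
frequency and softly bounded within ±20% of it — the stimulus frequency
is known, but letting the data refine it guards against clock drift. A
negative fitted amplitude is normalised by flipping its sign into the
phase. On noiseless traces from the model class the fit is exact to
machine precision; the test suite asserts 1e−6.

Gain is g = c1/a_S. The Bode phase is c3 in degrees wrapped to
(−180°, 180°], with the stimulus position reference −a_S·cos(2πft) and
time zero at phase onset, so an eye lagging by a quarter period reads
−90°. Trial quality control rejects traces whose within-ISI residual
drift exceeds 0.2 °/s (checked before r², since a drifting trace also
depresses r² and the specific reason is the useful one) or whose fit
explains less than r² = 0.3 of the variance. Both thresholds are
unashamedly operational defaults, exposed in the pipeline config.

## Spatial tuning surface

OKR gain over stimulus position is modelled as the sum of two von
Mises–Fisher components and an offset. Each component is written with
the normalisation κ exp(κ μᵀξ) / (2π(e^κ − e^{−κ})), which integrates to
1 over the sphere, so C_j is the mass a component contributes above the
offset; this is verified by quadrature over a Fibonacci point set to
1e−4. Evaluation rewrites the exponent as κ(μᵀξ − 1) so it never
overflows; the surface stays finite for κ up to 700 and beyond.

Fitting aggregates records to a per-position median across fish and
repetitions first (matching the correction pipeline; per-record fitting
is available), then runs multi-start bounded least squares (default 5
starts) from mirror-symmetric lateral initialisation (±90, 0) with κ = 5.
Bounds keep κ ∈ [0.1, 700] and component masses positive via log
parameterisation. The merged map uses only records from directly
stimulated eyes; per-eye maps use all records of that eye. Results report
both the component centres μ_j and the numerically located maxima of F
(dense grid split at the sagittal plane, refined by Nelder–Mead) — for
overlapping components the surface maxima sit further apart than the
centres, and the two should not be conflated. A fit on gains with no
spatial variation is flagged degenerate (κ unidentifiable).

Discrete gain maps are smoothed with a vMF kernel by Nadaraya–Watson
weighting, w_i = exp(κ_smooth ξᵀξ_i), computed with a log-sum-exp shift.

The rotated-arena correction matches each stimulus position to its image
under the fish-centred remap (α, β) → (−α, −β) — the rotation swaps
left/right and upper/lower LEDs as seen by the fish — takes per-position
medians within each dataset, and averages the two medians. Any additive
bias that flips sign with arena orientation cancels exactly in
expectation. Positions present in only one dataset are flagged and
excluded. The remap is a config-visible choice because the physical
rotation admits more than one description.

Frequency tuning fits a log-Gaussian bump per location and reports both
the fitted peak and the raw argmax, flagging flat or boundary-peaked
profiles rather than extrapolating. Size tuning fits
g(s) = g_max / (1 + exp(−(ln s − ln s50)/w)) in the fractional-area size
s, requiring at least four sizes spanning a decade; s50 is the
half-maximum size.

Direct versus indirect (yoked) stimulation is decided per eye by whether
the stimulus centre lies within fov/2 + crop half-angle of the eye's
optical axis. Defaults: axes (−84.8°, 3.5°) and (80.1°, 4.9°) for the
left and right eye — measured resting directions for embedded larvae —
and a 163° field of view per eye, taken from the literature for slightly
younger animals and exposed as a parameter since the true value for
5–7 dpf fish is uncertain.

## Asymmetry model and inference

The yoking index Y = (g_L − g_R)/(g_L + g_R) and bias index
B = (m_L − m_R)/(m_L + m_R) are antisymmetric under left/right exchange
and bounded in [−1, 1]; both are flagged undefined when the denominator
vanishes. Hemisphere pools assign stimuli by azimuth sign; centres lying
exactly on the sagittal plane (azimuth 0 or ±180) join neither pool.

The decomposition B_k = φ·b1 + b2 + b3,k + η is fitted in two stages:
(b1, b2) by least squares of B on [φ, 1] — valid when the individual
biases b3,k average out across the population — then b3,k as each fish's
mean residual. Standard errors for (b1, b2) come from the usual OLS
covariance. With a single arena orientation b1 is unidentifiable and the
result is flagged rather than silently zero. On data generated from the
model the recovery is exact to machine precision at zero noise.

The embedding-direction comparison is an exact permutation test: all
C(n, n_A) size-preserving reassignments of fish to groups are enumerated
(up to 20 fish; Monte-Carlo with a fixed seed above that), the statistic
recomputed for each, and p reported as the fraction of assignments with a
statistic at least as large as the observed one — the identity assignment
is included, so p ≥ 1/P. The statistic follows the original design:
pool each group's records, fit the bimodal vMF surface, average the two
hemisphere elevations, and difference the groups. Assignments whose fit
degenerates are excluded and counted. Group sizes are caller inputs; a
3-vs-7 split enumerates the canonical 120 assignments.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
and only that. A trial's base gain is the vMF surface evaluated at the
stimulus centre, with default component centres (−82.5°, 5.1°) and
(81.7°, 1.6°), κ = 8, peak gain 0.3 over a 0.05 baseline. The peak
magnitude is an arbitrary but realistic scale for fast stimuli (gains
well below 1); it is configurable and never asserted against anything.
Hemispheric asymmetry enters multiplicatively, gain × (1 ± δ) with
δ = φ·b1 + b2 + b3,k by stimulus hemisphere, which reproduces the ratio
statistic B = δ exactly for a symmetric surface and to first order
otherwise (an additive option exists). The unstimulated eye's gain is the
stimulated eye's times (1 − Y0)/(1 + Y0), giving yoking index Y0 exactly.
Gains are truncated at zero.

Traces superimpose, on the sinusoidal slow phase −g·a_S·cos(2πft):
quick-phase resets arriving as a Poisson process (default 0.3 Hz),
directed against the current stimulus velocity with amplitudes
|N(8°, 2°)|; Gaussian measurement noise (default σ 0.1–0.2°); and an
optional linear drift (0.5 °/s) injected with a per-trial probability to
exercise the QC path. Everything is driven by one seeded generator:
identical seeds give byte-identical CSV output.

What the generator does **not** emulate: eye-plant dynamics and gain
dependence on retinal slip within a trial, saccade kinematics (resets are
instantaneous steps), habituation or slow gain drift across trials,
pigment/tracking artefacts, and any dependence of noise on eye position.
Passing recovery tests therefore shows that the analysis chain is
correct and well-calibrated for data satisfying its own assumptions — it
does not validate those assumptions against real fish.

## Problem sizes and calibration checks

The recovery checks run at the study's cohort scale: 38 positions ×
7 fish × 2 repetitions (1064 trials of 100 s at 60 Hz), with gain noise
at 20% of peak. Under those conditions the median great-circle error of
the fitted vMF centres, over seeded cohorts with full trace re-analysis,
is below 5°; the trace stage itself contributes negligibly (re-analysed
gains reproduce the fit obtained from the generated gains to two decimal
places). The asymmetry regression check uses 15 fish split across both
arena orientations with per-fish bias sd 0.1 and recovers (b1, b2) within
two standard errors. Permutation-null calibration uses 200 seeded
6-fish cohorts split 3-vs-3 (20 exact assignments each) and checks that
p ≤ 0.05 occurs in at most 7.5% of them. These sizes were chosen as the
smallest that exercise each property at the study's own scale.

## Known limitations

- The procedural arena layout reproduces counts and coverage, not the
  exact physical tile positions; LED-level comparisons with the real
  hardware are out of scope.
- The vMF surface model assumes exactly two modes; animals with more
  structured gain maps would need a larger mixture.
- The permutation statistic refits the surface per assignment with a
  single optimisation start for tractability; a pathological fit in one
  assignment is excluded and reported, not repaired.
- QC thresholds (r² ≥ 0.3, drift ≤ 0.2 °/s, saccade velocity 40 °/s) are
  operational defaults, not estimates of anything.
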