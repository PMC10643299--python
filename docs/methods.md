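# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic generators do and do not emulate.

## Polarimetry

Demosaicking treats superpixels as non-overlapping 2×2 blocks: each output
pixel of the four polarizer channels comes from exactly one subpixel, with
no sliding-window interpolation. This halves resolution but keeps every
superpixel's Stokes estimate independent, which is what the round-trip
guarantees below rely on. The default layout `[[90, 45], [135, 0]]` is the
arrangement of the Sony IMX250MZR sensor family used in common DoFP cameras
(Lucid Triton among them); it is a parameter everywhere.

Stokes convention: `S0 = (I0+I45+I90+I135)/2`, `S1 = I0−I90`,
`S2 = I45−I135`. The half-sum makes S0 equal the scene radiance under ideal
polarizers (which transmit half of unpolarized light), consistent with the
forward model `I_phi = 0.5(S0 + S1 cos 2phi + S2 sin 2phi)` used by the
renderer. Polarizer non-ideality (diattenuation, crosstalk) is not
modelled; there is no calibration matrix in the pipeline.

Degenerate pixels: DoP > 1 (possible under noise) is clipped to 1 and
counted; AoP at DoP < 0.01 is reported as 0° by convention and should be
excluded from angle statistics — `atan2(0,0)` has no meaning. Exposure
masking is per superpixel: any subpixel at `full_scale − saturation_margin`
(default margin 0) marks the superpixel overexposed; `S0 ≤ floor_threshold`
(default 1 count) marks it underexposed. Masked pixels render white/black
in false colour; DoP uses viridis, AoP uses the cyclic twilight map so
−90° and +90° meet.

## Stimulus construction

"Geometric expansion" of a looming disc is implemented two ways, selectable
per `LoomSpec`:

* `constant_approach` (default): θ(t) = 2·arctan(R/(v(t_c − t))), the
  kinematics of a disc of radius R closing at constant speed; v and the
  virtual collision time t_c are solved in closed form from θ(0) = θ_start
  and θ(T) = θ_max. This form cannot start at exactly 0°, so θ_start
  defaults to 0.5°.
* `exponential`: θ grows geometrically from θ_start to θ_max.

Presets: expansion 3 s (terrestrial) or 10 s (marine), hold 2 s, 60 Hz
frame rate (frame rate is a free parameter; the assay's displays are not
modelled). The full-size angle defaults to a 12 cm disc at 35 cm ≈ 19°.

Screen calibration is a grey→radiance and grey→DoP table interpolated
piecewise linearly; the radiance curve is regularised with a cumulative
maximum before inversion so `grey_for_target` (the inverse map) is well
defined. An identity calibration ships for synthetic work; measured tables
load from CSV (`grey,radiance,dop`). Requests outside the gamut raise an
error naming the achievable range. Inter-trial intervals are uniform on
[60, 180] s (the "1–3 min" pacing), and each series is a seeded uniform
shuffle of the contrast set, one modality per series.

## Behavioural statistics

**Scoring.** Response = any of stop/retreat/walk with onset inside the
window. The window is a parameter, defaulting to loom onset through end of
hold: 5 s (terrestrial), 12 s (marine). Trials flagged as pre-stimulus full
retreats are excluded before any fit.

**Psychometric curve.** 4-parameter logistic with base-10 slope fitted by
bounded trust-region least squares to per-contrast response proportions,
weighted by trial counts (weights optional). Bounds: bottom, top in [0,1];
x50 allowed 50% of the contrast span outside the data during optimization.
The parameterisation is sign-degenerate ((b,t,s) ↔ (t,b,−s)); fits are
canonicalised to bottom ≤ top. A fit is flagged non-converged when the
optimizer fails, |slope| < 1e-3, the amplitude top−bottom < 1e-3 (flat
curve: x50 meaningless), or x50 leaves the data range. Initial values come
from the data (tail means, midpoint crossing); tolerances 1e-12 so exact
model-class data is recovered to optimizer precision.

**Habituation.** OLS line through mean response probability at each
presentation order, pooled over contrasts; h = slope, in probability per
trial. Pooling across contrasts is the modelling choice here — the
per-order mean is then a constant mixture of contrast levels (each order is
a uniform shuffle), so an additive per-trial decrement passes through to
the slope unbiased as long as probabilities stay off the [0,1] boundary.

**GLMM.** Binary logistic regression with a Gaussian random intercept per
crab, fitted by maximising the exact marginal likelihood under adaptive
Gauss–Hermite quadrature: per group, a Newton solve locates the posterior
mode of the random intercept, the 20-node Hermite rule is recentred and
rescaled there, and the log-integral is accumulated with logsumexp. The
outer optimisation is L-BFGS-B over (β, log σ), σ bounded in [1e-6, 50],
started from a plain logistic fit and σ = 0.5. With one group the model
degenerates to plain logistic regression (warning; σ set to 0). The
implementation reproduces R lme4's `glmer(..., nAGQ=20)` to ~1e-3 on a
fixed test dataset, and its marginal log-likelihood matches brute-force
`scipy.integrate.quad` to 1e-4 on a 2-group toy problem.

Fixed effects are contrast and presentation order; an optional quadratic
term (squared *centred* contrast) is available for groups whose residuals
warrant it. Effects are tested by LRT (χ² = 2Δll, df = parameter
difference); negative χ² beyond 1e-4 raises a convergence error rather
than being silently truncated (differences inside that tolerance are
optimizer slack — measured at ~3e-6 worst case over a thousand paired
fits — and are clamped to zero). Polarity-split models refit contrast+order
on the positive-and-control and negative-and-control subsets — zero-contrast
controls anchor both — and splits with constant response are flagged
non-identifiable instead of fitted. No multiplicity correction is applied.

## Synthetic generators

**Scenes/mosaics.** `make_disc_scene` builds a uniform-intensity field with
a centred disc differing in DoP, horizontally polarized by default (the
assay's background is 50% polarized in the horizontal plane). The renderer
applies the Malus-law forward model per subpixel, optional Gaussian read
noise, then rounds and clips to the ADC range. It does not model photon
shot noise (optional future flag), polarizer crosstalk, optics, or the
spatial structure of natural scenes — passing round-trip tests shows the
estimator inverts the ideal camera model through quantization, not that
field imagery is calibrated.

**Observer.** Response probability is an asymmetric 4PL: bottom 0.05, top
0.95, slope 10, thresholds x50 = +0.2 (positive contrasts) and −0.2
(negative), chosen inside the 0.17–0.22 DoP threshold band typical of
these assays. Per-crab intercepts shift the probability on the logit scale
(SD 0.5); habituation subtracts 0.02 per trial on the probability scale —
additive on probability because that is the scale on which h is defined
and fitted. Defaults: 9 contrasts spanning ±0.5 against a 0.5-polarized
background, one series per crab. The generator produces binary responses
with a single nominal retreat onset at 1 s; onset-time distributions of
the three behaviours are not simulated. Per-crab variance and habituation
magnitude are order-of-magnitude choices, not measured quantities.

A second generator (`simulate_glmm_trials`) draws directly from the
logistic-GLMM data model (logit-linear in contrast and order) for
calibration studies where the generating model must be the fitted one.
Contrasts are shuffled per crab; without that shuffle, contrast is exactly
collinear with presentation order and the contrast effect is
unidentifiable.

## Validation studies and problem sizes

`polcrab.validation` wires generators to analyses; `scripts/acceptance.py`
runs all of them and `tests/test_acceptance.py` asserts their outcomes.

* Polarimetry round trip: 100 random disc scenes, 16×16 superpixels,
  12-bit, noiseless, S0 = 4000 counts (near-full-scale exposure maximises
  the ratio of signal to quantization error), DoP drawn from [0.05, 1]
  (AoP is ill-conditioned as DoP → 0), random AoP. Max DoP error is
  required within 2 LSB (2/4096) and AoP within 0.5°.
* Psychometric recovery: 500 replicates of 20 crabs × 9 contrasts
  (one binary response each) from x50 = 0.2, slope 10; percentile bootstrap
  (199 resamples of crabs) for the 95% interval. Percentile was chosen
  over BCa after a pilot showed BCa covering worse on this estimator at
  n = 20.
* LRT calibration: 1000 null replicates (no contrast effect, order effect
  −0.05, crab SD 0.5, 20 crabs × 9 trials) for type-I error at α = 0.05;
  300 replicates at a logit-scale contrast slope of 4 for power.
* Habituation recovery: 500 replicates, decrement 0.05/trial, using a
  high-floor observer (bottom 0.55, 5 orders, crab SD 0.3) so the additive
  decrement never clamps at 0 — clamping would bias the slope toward zero
  and the study measures the estimator, not boundary effects.
* Quadrature oracle: a 2-group toy dataset evaluated at fixed off-optimum
  parameters, AGQ vs `scipy.integrate.quad`.

These sizes complete in a few minutes on one core while leaving Monte Carlo
error well inside each study's decision margin.

## Known limitations

* No radiometric camera calibration, circular polarization (S3), or video
  polarimetry.
* The psychometric fit assumes proportions per contrast, not raw binary
  trials; with one series per crab the two coincide up to weighting.
* The GLMM supports only a random intercept (the assay's repeated-measures
  structure); random slopes are out of scope.
* The habituation line is a description of pooled response decay, not a
  mechanistic model; it conditions on nothing.
* Bootstrap coverage is slightly below nominal (~0.93–0.95 at 20 crabs),
  as expected for resampling so few exchangeable units.
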