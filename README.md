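# polcrab

A tested pipeline for polarization-vision looming assays in crustaceans:
Stokes polarimetry for division-of-focal-plane (DoFP) polarization cameras,
expanding-disc stimulus construction in intensity or polarization contrast,
and the behavioural statistics used to quantify whether an animal detects a
looming cue — psychometric thresholds, habituation rates, and mixed-effects
logistic regression with likelihood-ratio tests. Synthetic ground-truth
generators close the loop at every stage, so each analysis is validated
against data whose answer is known.

It is written for visual-ecology labs running playback assays (tethered
animals watching looming discs on calibrated displays) and for anyone
processing DoFP camera imagery.

## The science in brief

**Polarimetry.** A DoFP camera's 2×2 superpixels carry micro-polarizers at
0°/45°/90°/135°. Per superpixel:

```
S0 = (I0 + I45 + I90 + I135)/2,   S1 = I0 − I90,   S2 = I45 − I135
DoP = √(S1² + S2²)/S0             AoP = ½·atan2(S2, S1)   (0° = horizontal)
```

with over-/under-exposed superpixels masked (rendered white/black in the
false-colour maps).

**Stimuli.** A disc of diameter D at distance d subtends 2·arctan(D/2d);
the loom expands that angle over 3 s (terrestrial preset) or 10 s (marine)
and holds 2 s. Discs differ from the background in Weber contrast
(I_obj − I_bg)/I_bg or in DoP contrast (DoP_stim − DoP_bg), with grey levels
resolved through a measured screen calibration.

**Behaviour.** A trial is a response if any of *stop*/*retreat*/*walk*
starts within the scoring window (trials with a pre-stimulus full retreat are
excluded). Contrast-response curves are 4-parameter logistics
`p(x) = bottom + (top−bottom)/(1 + 10^((x50−x)·slope))` whose x50 is the
detection threshold; habituation is the OLS slope of response probability
over presentation order; and the contrast/order effects are tested with a
random-intercept (per animal) binary logistic GLMM fitted by adaptive
Gauss–Hermite maximum likelihood, compared by LRT
(χ² = 2·Δlog-likelihood).

## Worked example

Simulate a behavioural experiment from the default observer (20 crabs, nine
DoP contrasts spanning ±0.5 against a 50%-polarized background, detection
threshold x50 = 0.2) and analyze it:

```bash
polcrab simulate trials --seed 7 --out trials.csv
polcrab analyze --trials trials.csv --out results.json
```

`results.json` from this exact run contains (abridged):

```json
"half_max_thresholds": {"positive": 0.2157, "negative": 0.1365},
"habituation": {"h": -0.0325, "intercept": 0.6903},
"lrt": {
  "contrast": {"chi2": 0.069, "df": 1, "p": 0.793, "coefficient": -0.124},
  "order":    {"chi2": 5.194, "df": 1, "p": 0.023, "coefficient": -0.134}
},
"polarity_splits": {
  "positive": {"chi2": 64.23, "df": 1, "p": 1.1e-15},
  "negative": {"chi2": 49.63, "df": 1, "p": 1.9e-12}
}
```

Reading this: the half-maximum thresholds bracket the generating threshold
of 0.2 (one binary response per crab per level makes single-dataset
thresholds noisy; the recovery study below quantifies the spread), and the
order LRT picks up the injected habituation (h ≈ −0.03/trial against a
−0.02 decrement). The pooled *linear* contrast term is null — the default
observer responds symmetrically to both contrast polarities, so positive
and negative effects cancel in a linear model — while the polarity-split
models, which fit each sign separately with the zero-contrast controls as
anchor, are each decisively significant. That is precisely the analysis
pattern this assay needs for a polarity-symmetric responder.

Polarimetry runs the same way from a rendered or recorded mosaic:

```bash
polcrab simulate mosaic --out mosaic.tiff          # DoP-1 disc on a 0.5 background
polcrab polarimetry --input mosaic.tiff --out-prefix scene
```

writing `scene_{s0,s1,s2,dop,aop}.tiff` plus false-colour PNGs.

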