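# Methods

## The problem

When two brief flashes are shown in sequence during a smooth pursuit eye
movement (SPEM), the eye moves between them — 2° for a 200-ms stimulus onset
asynchrony (SOA) at the 10°/s pursuit speed used here — so the two flashes
land at different retinal eccentricities even when they share a screen
position. Whether the visual system judges their *relative* position in an
eye-centered (retinocentric) or a head-/screen-centered frame therefore
predicts different biases. `pursuitflash` implements the full analysis that
separates these hypotheses: psychometric estimation of the point of
subjective equality (PSE) per condition, an absolute-localization regression
quantifying how mislocalization grows with retinal eccentricity, and a
four-model comparison.

All analyzed quantities are horizontal. Internally every position lives on
the *screen axis* (degrees, positive rightward); pooling across hemifields
happens on the *eccentricity axis* (positive = farther from screen center
within the stimulus hemifield), which is a sign flip for left-hemifield
stimuli. Degrees of visual angle are computed with per-point arctangent
geometry, consistent with a 120 × 90 cm flat screen spanning ≈ 81° × 65° at
70 cm.

## The four reference-frame models

Let `PSE_fix(SOA)` be a subject's fixation PSE and `a` the subject's
eccentricity-effect slope for a placement (ahead/behind the pursuit
target). With the sign factor `s = +1` for (positive SOA, ahead) and
(negative SOA, behind), `s = −1` for the mirror cells and `s = 0` at SOA 0:

* **Model A** (screen-centered): `PSE = PSE_fix`
* **Model B** (eye-centered): `PSE = PSE_fix + s · v·|SOA|` (= ±2° here)
* **Model C** (screen-centered + eccentricity effect):
  `PSE = PSE_fix + s · v·|SOA| · a` (= ±2a)
* **Model D** (eye-centered + eccentricity effect): both shifts.

The shift formulas are written in terms of pursuit speed `v` and SOA so they
reduce exactly to the 2° and 2a constants at 10°/s and 200 ms but remain
usable at other design points; a `fraction` parameter on the retinal shift
expresses intermediate frames (0.5 → a 1° shift). All models coincide at
SOA 0, so simultaneous cells are excluded from model evaluation.

Model agreement with the measured pursuit PSEs is summarized by the OLS
slope of predicted on measured, Pearson r, and the mean pointwise distance
`d` of the (measured, predicted) points to the identity line. `d` is the
perpendicular distance `|p − m|/√2` by default; the vertical reading
`|p − m|` is available via `distance_metric: vertical` since the geometric
definition is a design choice, not forced by the statistic. Ranking is by
ascending `d_mean` with `|slope − 1|` as tie-break, and the full ranking is
always reported. Fig-6-style regressions are unconstrained (not through the
origin).

## Synthetic observers and what they emulate

The generator reproduces the statistical structure the analysis assumes,
not the visual system:

* **Responses** come from the same lapse-augmented cumulative Gaussian the
  analysis fits, `ψ(x) = γ + (1−γ−λ)·Φ((x − PSE)/σ)`, with the generating
  PSE set by the observer's frame regime (A–D) via the model equations
  above. This makes parameter and model recovery well-posed: recovery
  failures indicate analysis defects, not model mismatch.
* **Defaults are the emulated study's group means**: fixation PSEs 0.00° /
  −0.02° / +0.75° at SOA −200/0/+200 ms; pursuit gain 1.02 ± 0.03; slopes
  a_ahead = 0.24, a_behind = 0.26 (the representative subject's values);
  σ = 0.8°, γ = λ = 0.02. Intercepts of the absolute-mislocalization line
  are chosen so a flash at 7.5° retinal eccentricity is mislocalized +2.75°
  (ahead) and −0.95° (behind, i.e. perceived at 6.55°).
* **Between-subject scatter** in `generate_dataset` uses the study's group
  SDs: fixation-PSE SDs 0.42/0.17/0.55°, slope SDs 0.335/0.19 (half the
  reported compensation-shift SDs 0.67/0.38). Slope jitter re-anchors the
  intercept so the mislocalization *at 7.5°* stays at the group level (±0.3°
  anchor jitter): subjects differ in eccentricity scaling, not in the
  direction of mislocalization at the reference eccentricity.
* **Gaze traces** are 500-Hz samples; pursuit runs at `10·gain` °/s through
  screen center at the 1250-ms reference flash, with white positional noise
  (0.05° SD, an EyeLink-like RMS), instantaneous catch-up-saccade steps of
  0.8–1.5° with a 300-ms refractory period (0.3 Hz default), and blinks as
  60–150-ms invalid runs (p = 0.03 per trial). Saccade shape (no main
  sequence, no intrasaccadic samples) is deliberately simplified: the
  analysis only needs events that the detector must find and the exclusion
  rules must act on. Fixation-trace saccades step out and back so fixation
  is held on average.
* **Schedules** follow the published grids — fixation ±0.3/±1.0/±1.7/±2.5°;
  pursuit coarse 0,±2..±8°, fine1 0,±1..±4°, fine2 0,±0.5..±2° — with the
  adaptive re-centering rule: fine1 centers on the coarse-phase interim PSE
  rounded to 1°, fine2 on the fine1 PSE rounded to 0.5° (the rounding keeps
  offsets on grid-valued positions; the original procedure's rounding is
  unspecified). The number of coarse repetitions is a parameter
  (`coarse_per_offset`) since the original count is not stated.
* **Ruler reports** quantize the perceived position to 51 lines 0.8° apart
  spanning ±20°, shifted by 0.4° on half the trials; each trial draws a
  fresh uniform injection of the 51 lines into 100 two-digit labels, stored
  for decoding. Perceived positions beyond the span clamp to the end line
  and are flagged.

What passing tests on this generator do *not* show: robustness to real
oculomotor dynamics (saccade kinematics, pursuit onset/offset, drift),
2-D gaze errors, non-Gaussian psychometric shapes, serial dependencies, or
reaction-time effects. They do show that the estimators are consistent and
unbiased under the assumed model at realistic noise levels and trial counts.

## Quality control

Rules mirror the emulated protocol: frame-drop flag (boolean input column);
exclusion if gaze deviates > 2° from the *nominal* fixation/pursuit-target
trajectory within ±50 ms of the reference flash; exclusion if a saccade or
blink falls within ±100 ms of either flash (a 400-ms union window at
|SOA| = 200 ms, 200 ms at SOA 0). Saccade detection applies a 30°/s
threshold to Savitzky-Golay-differentiated velocity (9-sample window,
order 2, FIR form) *relative to the expected pursuit velocity*, minimum
duration 8 ms, sub-threshold gaps < 20 ms merged — the original tracker's
parser settings are unknown, so these conventional values are exposed in
config. Blinks are invalid runs ≥ 20 ms padded by 20 ms per side. Pursuit
gain is a 20%-trimmed mean of per-sample velocity in the ±100-ms flash
window divided by target speed; > 50% masked samples make the gain
undefined rather than silently biased. Trials are flagged, never dropped.

## Psychometric estimation

Maximum likelihood on per-level binomial counts, ψ as above, with bounds
PSE ∈ [min level − 5°, max level + 5°], σ ∈ [0.05, 20]°, γ, λ ∈ [0, 0.06].
The asymptote bound keeps the PSE identifiable with 8–17 levels while
allowing lapse slack; fits use 5 quantile-heuristic multistarts of L-BFGS-B
with the analytic gradient. Degenerate cells (all-0/all-1 responses) return
a non-converged fit with infinite CI. 95% CIs are percentile intervals from
a nonparametric bootstrap (999 resamples by default; 199 in the pipeline
default for speed) resampling per-level binomial counts, warm-started at
the point fit; > 20% refit failures widen the interval 1.5× with a warning.
This MLE+bootstrap combination replaces the original Bayesian toolbox; only
point PSEs and 95% CIs are consumed downstream, which it reproduces.

Pooling is task-specific by design: fixation trials are mirrored onto the
eccentricity axis and pooled across hemifields *before* fitting (one fit
per SOA); pursuit trials pool the two fine phases and are fitted per
direction, with parameters then averaged across leftward/rightward (CI
combined as the union hull). The eccentricity regression is ordinary least
squares on trial-level data (not per-position means) — equivalent for
balanced designs and lower-variance otherwise.

## Statistics

Paired t tests with Cohen's dz = |t|/√n (reported positive regardless of
the sign of t); one-tailed p values halve the two-sided p in the observed
direction. Multiple comparisons use the Holm step-down (sequential
Bonferroni): p values ascending, the i-th compared to α/(m−i+1), stopping
at the first failure. The specific battery of cell comparisons is a
declarative list in the config, not code.

## Problem sizes and numerical choices

Default generator counts follow the emulated protocol (≥ 150 valid trials
per pursuit-relative cell, ≥ 50 per absolute cell), topped up after
simulated exclusions. The test suite runs reduced designs chosen for
statistical adequacy: model-selection recovery uses 100 replicate
8-subject experiments per generating frame with ~18 valid trials per
pursuit cell — the B/C prediction gap (≈ 1.2–2° per cell) is several times
the resulting PSE noise (≈ 0.2°), so the ranking is decided by structure,
not trial count. PSE recovery uses 500 cells at the full 150-trial scale.
Master seeds derive per-trial streams as `(seed, subject, counter)`, making
datasets reproducible and order-independent; pipeline reruns with the same
config and seed are byte-identical.

## Known limitations

* 1-D gaze and stimulus geometry; vertical offsets are metadata only.
* The generator's saccades/blinks are schematic (see above).
* Whether the original deviation rule used the nominal trajectory or a
  sample-matched target position is unknown; the nominal trajectory is used.
* The exact asymptote priors of the original fitting toolbox are unknown;
  the [0, 0.06] bounds are a declared substitute.
* Configured stimulus eccentricities (e.g. 7.5°) are treated as exact
  degree values; whether the original display mapping was linear or
  arctangent in screen millimeters is not modeled.
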