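# pursuitflash

Analysis pipeline for **relative flash localization during smooth pursuit
eye movements** — for visual psychophysicists studying the reference frame
in which briefly flashed stimuli are localized.

When two flashes are presented in sequence (stimulus onset asynchrony,
SOA, of ±200 ms) during 10°/s smooth pursuit, the eye moves ~2° between
them. A judgment of which flash was *more eccentric* therefore
discriminates between spatial encodings:

- in an **eye-centered** frame, the intra-SOA eye displacement shifts the
  point of subjective equality (PSE) by ±2° relative to fixation;
- in a **head-/screen-centered** frame it does not;
- independently, absolute mislocalization grows linearly with retinal
  eccentricity (slope *a*), and the 2° retinal displacement then
  contributes a ±2*a* PSE shift.

Crossing these two factors gives four models of the pursuit-condition PSE:

| model | frame | eccentricity effect | predicted PSE |
|---|---|---|---|
| A | screen | no  | PSE_fix |
| B | eye    | no  | PSE_fix ± 2° |
| C | screen | yes | PSE_fix ± 2a |
| D | eye    | yes | PSE_fix ± 2° ± 2a |

(sign: + for *positive SOA, ahead* and *negative SOA, behind* cells, − for
the mirror cells, 0 at SOA 0). Models are scored against measured pursuit
PSEs by regression slope, Pearson r, and the mean pointwise distance *d*
to the identity line.

The package contains everything needed to run and validate this analysis
without recorded data: a synthetic-experiment generator (observers,
adaptive stimulus schedules, 500-Hz gaze traces, 2AFC and ruler
responses), trial quality control (saccade/blink detection, pursuit gain,
exclusion rules), cumulative-Gaussian PSE fitting with bootstrap CIs, the
eccentricity-effect regression, model comparison, and the paired-t /
Cohen's dz / Holm statistics layer. See `docs/methods.md` for the model
and all numerical choices.

## Worked example

Run the whole pipeline on a small synthetic experiment (4 observers
generated under the screen-centered-with-eccentricity-effect regime, the
generator default):

```bash
pursuitflash all --config demo.yaml --seed 7 --outdir demo_out
```

with `demo.yaml`:

```yaml
n_subjects: 4
counts: {pursuit_relative: 36, fixation_relative: 48, pursuit_absolute: 16, coarse_per_offset: 2}
n_boot: 0
```

prints

```
model    slope  pearson_r   d_mean     d_sd  n_points  rank
    A 0.487298   0.602032 0.366733 0.273306        16     2
    B 1.933573   0.712397 1.109466 0.345098        16     3
    C 1.079310   0.968276 0.142882 0.081943        16     1
    D 2.525584   0.764691 1.420697 0.168660        16     4
best model: C (d_mean = 0.143)
report bundle in demo_out
```

Reading this: each of the 16 points is one subject × (SOA ±200 ms) ×
(ahead/behind) cell, predicted PSE vs measured PSE. Model C — fixation
PSEs plus the per-subject eccentricity compensation ±2a, no eye-centered
shift — tracks the measured pursuit PSEs (slope ≈ 1, r ≈ 0.97, mean
distance to identity 0.14°), while the eye-centered models B and D
overshoot (slopes ≈ 1.9 and 2.5) and model A, which predicts no pursuit
effect at all, undershoots. The recovered best model matches the regime
the observers were generated under.

The `demo_out/` bundle holds the per-subject PSE table, the QC report, the
eccentricity/compensation-shift table (with mean ± SD summary row), the
per-cell model predictions, the model-comparison report, and the test
table with Holm-corrected significance flags — all as TSV plus a JSON run
manifest. The same run is available as a library call:

```python
from pursuitflash import run_pipeline
bundle = run_pipeline({"n_subjects": 4, "seed": 7, "n_boot": 0})
bundle["ranking"][0].model   # <FrameModel.C: 'C'>
```

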