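# gonogo

Error-monitoring EEG analysis for developmental go/no-go experiments:
behavioral post-error adjustments, the error-related negativity (ERN),
frontal midline theta power, and the within-subject statistics that link
neural error signals to subsequent behavior — with a built-in synthetic
cohort generator so the whole chain can be validated by parameter
recovery.

## The problem

When a child presses the button to a no-go stimulus (a **false alarm**),
three things tend to happen: the next response is slower (**post-error
slowing**, PES), the next response is more often correct when the
slowing is large (**post-error accuracy**, PEA), and the EEG shows a
fronto-central negativity within ~100 ms of the erroneous press (the
**ERN**) together with an increase in induced 4–7 Hz (**theta**) power
over frontal sites. This package implements the full analysis of that
phenomenology for 14-channel, 128 Hz recordings of a 90-trial-block
go/no-go task (P(go) = 0.7, 1200 ms onset-to-onset: 400 ms stimulus +
800 ms cross):

- **behavior** — outcome classification; RT summaries; single-trial
  PES/PCS (next-trial RT minus current-trial RT) with the RT-matched,
  20-repeat post-correct control; PEA/PCA; per-subject PES tertile
  splits; the response–stimulus interval RSI = SOA − RT; the
  ≥ 7-qualifying-trials inclusion rule.
- **preprocess** — 0.5–30 Hz zero-phase FIR; ICA blink/artifact
  component removal; response-locked epochs over [−450, 550] ms with a
  [−450, −50] ms baseline; pseudo-average reference over
  O1/O2/T7/T8/AF3/AF4; ±110 µV epoch rejection; F3/F4 ROI averaging.
- **spectral** — a 1-Hz Hilbert filter bank over the theta band:
  narrowband filter → analytic-signal envelope → squared magnitude,
  averaged across bins, computed on the continuous signal; power is
  trial-averaged **first** and then decibel-normalized against the
  [−450, −350] ms baseline.
- **stats** — sample-wise paired permutation *t*-tests with whole-series
  sign flips (exact enumeration for small cohorts), a ≥ 5-consecutive-
  sample (~40 ms) significance criterion at p < 0.01; Wilcoxon
  signed-rank and Friedman tests with exact small-sample options; one-way
  ANOVA on waveform areas; effect sizes r = |statistic|/√n; Bonferroni
  control (0.05/3 = 0.0167).
- **simulate** — the synthetic cohort generator (see
  `docs/methods.md` for the generative model).
- **pipeline** — the five cohort analyses (error vs correct contrasts,
  error-recovery contrasts, PES-tertile neural analysis, behavioral
  contrasts, RSI analysis) with per-analysis inclusion accounting and
  CSV/JSON report output.

## A worked example

```
python examples/02_post_error_behavior.py
```

prints, for one simulated 8-block subject:

```
hit rate            71.8 %
false-alarm rate    31.3 %
correct-trial RT    621 ms
error-trial RT      537 ms
PES                 190.5 ms
matched PCS         28.0 ms
PES - matched PCS   162.4 ms (the generator injected 150 ms)
PEA                 84.6 %
matched PCA         82.1 %
```

Errors are ~84 ms faster than corrects (commission happens in fast,
impulsive moments); the raw post-error slowing (190.5 ms) overstates the
strategic adjustment because fast trials regress toward the mean, and
subtracting the RT-matched post-correct control (28.0 ms) recovers
162 ms ≈ the 150 ms this subject's generator actually injected. `examples/03`–`05` do
the same for the ERN waveform, the theta ERSP, and the permutation
contrast; `examples/06` runs the whole cohort pipeline. A thin CLI
mirrors the two end-to-end entry points: `gonogo simulate` and
`gonogo analyze`.

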