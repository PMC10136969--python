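# Methods

This note documents the generative model behind the synthetic cohorts,
the analysis conventions the package fixes where the method leaves
latitude, the numerical choices, and what validation on synthetic data
does and does not establish about real recordings.

## Task and cohort layout

A session is a sequence of 90-trial blocks. Trial classes are drawn
independently with P(go) = 0.70; stimuli are 1200 ms apart (400 ms
stimulus + 800 ms fixation cross), so a response at latency RT leaves a
response–stimulus interval RSI = 1200 − RT before the next stimulus —
an exact identity in the simulation, and the definition the RSI
analysis uses. Blocks are separated by 2 s of signal-only padding.

## Behavioral generative model

Log reaction time on trial *t* is

    log RT_t = log m + x_t + u_t + w_t           (responded trials)

with *m* the subject's correct-trial median (default 587 ms), `x_t` a
slowly drifting AR(1) "tempo" state (autocorrelation 0.96 per trial),
`u_t` a single-trial transient impulsivity component, and `w_t` white
noise (log-sd 0.05). The total tempo sd is
`sqrt(rt_correct_spread² − rt_resid_sd²)` (spread default 0.29) and the
transient share of its variance is 0.30. The two tempo components play
different roles: the persistent drift makes a fast error predict a fast
next trial (so raw single-trial post-error slowing is close to the
injected strategic shift rather than shift + regression), while the
transient component makes the current trial's speed partly its own,
which is what produces the strong mechanical association between
slowing tertiles and the RSI observed in real data.

**Commission errors.** A no-go trial is responded with probability
`expit(L − g·(x_t + u_t))`: errors are selected in fast tempo states.
The intercept and slope are calibrated numerically (fixed-point on a
4001-node Gaussian quadrature) so that the marginal commission rate
equals `p_commission` (default 0.36) and the *median* error-trial RT
equals `rt_error_median_ms` (default 481 ms). Selection skews the
conditional tempo distribution, which is why the calibration targets
the median rather than the mean. Go trials are unresponded (omissions)
with probability 0.26, independent of tempo. Responses that would land
after the next stimulus onset (≥ 1200 ms) are censored to non-responses
and produce no event marker.

**Post-error dynamics.** The trial after a responded false alarm
receives an additive strategic slowing `pes_shift_ms` (default 150 ms)
plus Gaussian noise (sd 50 ms); over runs of consecutive errors the
adjustment compounds (the successor of a double error carries the
previous shift plus a new one). The same trial's response probability is
modulated on the logit scale by `pea_coupling` (default 0.30 per 100 ms)
times the realized slowing centered on the nominal shift — more slowing
means a higher hit probability on go and a lower commission probability
on no-go, producing the positive PES–PEA association and its tertile
pattern.

Realized defaults land the cohort medians near the study population:
hit rate ~74 %, false alarms ~36 %, correct RT ~590–610 ms, error RT
~490–510 ms (slightly above the 481 ms target because double errors
carry the shift and surviving errors cluster in fast states), raw PES
~180 ms, matched PCS ~30 ms.

## EEG generative model

Fourteen channels (the 10–20 subset AF3…AF4) at 128 Hz. Background
noise is Gaussian with a 1/f power spectrum (exponent 1.0), RMS 10 µV
per channel, independent across channels. Sources are mixed by a fixed
frontal-dominant channel-weight template (F3/F4 = 1.0 down to occipital
0.05); no head model — sufficient for ROI-level analyses, not for
topography.

- **Error negativity (phase-locked).** Every responded trial adds a
  biphasic kernel: a negative Gaussian peaking 70 ms after the press
  (sd 30 ms) and a smaller positive rebound at 250 ms. Amplitude is
  `ern_amp_uv` (default 6 µV) on errors and 20 % of it on hits (a CRN).
- **Theta bursts (induced).** Errors additionally receive a
  Hann-windowed 4.5–6.5 Hz burst over [−100, 650] ms around the press
  with uniformly random per-trial phase, so the bursts appear in
  trial-averaged *power* but cancel in the trial-averaged waveform.
  The late center (~275 ms) keeps the filter-smeared burst tail out of
  the [−450, −350] ms power baseline. A 1-Hz filter bank has ~1 s
  temporal resolution and recovers only ~18 % of a sub-second burst's
  peak power; `theta_gain_db` (default 3 dB) is therefore defined as
  the gain *measured* by the reference bank at the burst peak, and the
  injected amplitude is scaled accordingly (against the analytic 4–7 Hz
  share of the synthesized background). On error trials the gain gains
  `theta_pes_coupling` (default 0.005 dB/ms) times the realized
  next-trial slowing, which is what the tertile analysis recovers.
- **Blinks.** 300 ms raised-cosine transients at `blink_rate_hz`
  (default 0.2 Hz), 120 µV on AF3/AF4 with smaller weights on F7/F8 and
  F3/F4. The ground-truth blink time course is stored on the recording
  so artifact removal can be validated against it.

Everything is a pure function of (parameters, seed); cohorts spawn
per-subject seeds from one `SeedSequence`.

## Analysis conventions

- **Pair definitions.** "Next trial" is the immediate successor within
  the same block; successors of any stimulus class are eligible, and
  accuracy denominators count only responded successors. Both slowing
  pools exclude current trials that themselves immediately follow a
  responded error (switch `exclude_post_error`, default on in the
  subject summary): a post-error trial already carries the strategic
  adjustment, which contaminates it both as an error baseline (double
  errors) and as a correct control (its successor speeds back up), and
  RT matching would preferentially select exactly those trials.
- **RT matching.** Per repeat, each error pair is matched without
  replacement to the correct pair with the nearest current-trial RT
  (ties uniform at random); 20 repeats are averaged. With fewer correct
  than error pairs, matching samples with replacement and flags it.
- **Tertiles.** Rank cuts at ⌈n/3⌉ and ⌈2n/3⌉, stable under ties; the
  per-tertile inclusion rule (≥ 7 trials each) implies ≥ 21 qualifying
  trials.
- **Pipeline order.** Amplitude path: FIR band-pass → ICA component
  removal → segmentation + baseline → pseudo-average reference →
  ±110 µV rejection → ROI. Power path: band-pass → ICA → reference →
  filter bank + envelope on the continuous signal → segmentation →
  trial-average → dB baseline → (amplitude-derived) rejection mask →
  ROI. Rejection is applied after referencing on both paths, and the
  power path reuses the amplitude epochs' rejection mask because the
  ±110 µV criterion is defined on voltages.
- **Theta bins.** "1-Hz filters over 4–7 Hz" is implemented as four
  bins centered on 4, 5, 6 and 7 Hz ([f − 0.5, f + 0.5]); a contiguous
  edge variant ([4,5), [5,6), [6,7)) is available via `bin_mode`.
  Normalization is applied to the trial-average power, never averaged
  per-trial dB, which would bias heterogeneous trials.
- **Permutation test.** Whole-series sign flips of each subject's
  difference waveform preserve temporal autocorrelation under the null.
  Two-sided p per sample is (#{|t*| ≥ |t|} + 1)/(n_perm + 1), or the
  exact proportion over all 2^n flips when enumeration is requested;
  the feasibility floor 2/2^n means cohorts of n ≤ 9 cannot reach
  p < 0.01 reliably — cohort analyses at that scale should use the
  exact mode and n ≥ 10.
- **ANOVA on areas.** The tertile analysis integrates each subject's
  per-tertile average waveform (trapezoid, [−50, 150] ms for amplitude,
  [−350, 450] ms for power) and treats the 3 × n subject-tertile areas
  as independent groups in a classical one-way ANOVA — matching the
  degrees of freedom convention of the field's reports — with paired-t
  post hocs at the Bonferroni-adjusted alpha and r = |t|/√n effect
  sizes. The within-subject structure is knowingly ignored at the
  omnibus stage.
- **Small-sample exactness.** Wilcoxon p values are exact for small
  tie-free samples (scipy's policy); Friedman p values are computed by
  exhaustive within-row rank permutation when (k!)^n is small.

## Numerical choices

FIR filters are Hamming-windowed sinc designs, order ≈ 3.3/(normalized
transition width) with 0.5 Hz transitions, applied forward–backward
(zero-phase; stopband attenuation doubles). Time-to-sample conversion
is nearest-sample rounding with inclusive endpoints: [−450, 550] ms at
128 Hz is 129 samples. ICA is FastICA with full rank (14 components),
unit-variance whitening, seeded; components are removed when their time
course correlates with the blink reference at |r| ≥ 0.7, or — without a
reference — when kurtosis exceeds 8 and the AF3/AF4 mixing share
exceeds 0.5. Degenerate statistics are guarded: zero-variance paired
differences raise (nonzero mean) or return t = 0 (zero mean); a zero
dB baseline raises; display rounding is r to 2 decimals and alpha to 4.

## Problem sizes used in validation

The test suite validates at reduced scale chosen for precision per unit
compute: behavioral recovery on 50-subject, 8-block cohorts; neural
dissociation on 20 replicates of 10-subject, 2-block cohorts with
exhaustive sign flips; tertile-coupling direction on 10 replicates of
6-subject, 5-block cohorts; null calibration on 200 replicates of
12-subject noise cohorts; the tertile dissociation pattern on one
18-subject, 5-block cohort. ICA is exercised in its own tests and the
full-pipeline smoke test, and disabled in replicate batteries that
inject no blinks.

## What the synthetic validation does and does not show

Passing tests establish that the implementation computes the intended
quantities: injected effects are recovered at the right magnitude, the
permutation machinery is calibrated under the null, and the analysis
reproduces the qualitative result pattern (fast errors, PES beyond the
matched control, PEA and RSI rising across PES tertiles, an ERP run and
an ERSP run for the error contrast, theta—but not ERN—tracking PES).
The generator is a stylized emulator: real EEG has correlated channel
noise, non-blink artifacts, age- and subject-specific spectra, and RT
dynamics richer than a two-component tempo state; real error RT
distributions are not exactly lognormal, and real strategic slowing
need not be additive or compounding. Conclusions about real recordings
require the real data; the deposited study dataset can be analyzed by
reading its trial tables and continuous recordings into the events/CSV
dialect consumed by the pipeline.

## Known limitations

No head model or channel interpolation; blinks are the only artifact
class; EDF I/O is not provided (plain CSV/TSV interchange only); the
filter bank's ~1 s temporal resolution smears sub-second power changes,
so ERSP onsets/offsets are systematically earlier/later than the
underlying source dynamics; the burst-recovery constant (0.18) is
specific to the reference bank settings (1-Hz bins, 0.5 Hz transitions,
128 Hz) and sub-second bursts.
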