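# Methods

`epespike` implements a spike-count model for extracellular plant
electrophysiology (EPE): slow voltage transients recorded by tissue-inserted
electrodes are band-limited, thresholded into discrete spike events, counted
in windows aligned to the infestation timeline, and compared across
treatments.  A first-class synthetic-recording generator emulates greenhouse
stink-bug infestation experiments on soybean so that every stage can be
validated against known ground truth.  This note records the model, its
assumptions, the defaults and why, and what the tests do and do not show.

## Signal model

A recorded channel is modelled as

```
v(t) = sum_i a_i * s(t - t_i) + d(t) + e(t)
```

where `s` is a stereotyped spike waveform, `{t_i}` an inhomogeneous Poisson
point process, `d` slow baseline drift and `e` broadband sensor noise.

**Spike waveform.** A biphasic transient `exp(-t/tau_d) - exp(-t/tau_r)`
(rise `tau_r` = 15 s, decay `tau_d` = 60 s, unit peak).  Real spike shape is
not published beyond an averaged close-up; these constants give a transient
of roughly one analysis-band period.  Because the analysis bandpass
(0.0025–0.010 Hz) strongly reshapes any transient of this duration, amplitudes
are defined *post-filter*: the template gain is calibrated once against the
analysis filter so that a drawn amplitude `a_i` equals the peak of the
filtered waveform.  This matches how the published amplitude statistics
(mean 1.9 mV, SD 0.8 mV) were measured — on the preprocessed signal.  The
filtered waveform is a band-limited wavelet with a negative side lobe of
about 0.6× the peak; this is intrinsic to a two-octave passband, not a
tunable artifact.

**Amplitudes.** Normal(1.9, 0.8) mV, non-positive draws resampled.  The
resampling truncation affects <1% of draws and biases the mean by <0.02 mV.
The 99th percentile of draws sits near 3.8 mV, consistent with insect-related
potential changes staying below 5 mV.

**Drift and noise.** Drift is a Gaussian random walk (step scale
1.0 mV/√hour) low-passed below 0.001 Hz, i.e. entirely below the analysis
low cut, so preprocessing removes it; its only role is to make raw traces
realistically non-stationary.  Broadband noise is white with SD 0.2 mV per
sample; the narrow analysis band attenuates it to ≈0.03 mV RMS, small against
the 1 mV threshold, so false detections are rare but amplitude readings
carry realistic jitter.

**Electrode sensitivity ("walling off").**  Tissue encapsulation of inserted
electrodes is modelled as an exponential amplitude attenuation with
half-life 60 days from insertion.  The published experiments attribute most
of the late-experiment count decline to the event rate itself, so the
sensitivity half-life is deliberately mild; it is exposed as a parameter.

## Event-rate model

The rate of an actively infested plant (events/day, DAI = days after
infestation; DAI 0 coincides with lights-on of the infestation day):

```
lambda(t) = R1 * diurnal(t) * decay(t) * survival(t) * knockdown(t)
```

* `R1` (injected day-1 rate) defaults to 57.5 events/day.  About 87% of a
  Normal(1.9, 0.8) population clears the 1 mV threshold, so the expected
  *detected* day-one count is ≈50 — the centre of the published 20–80 range.
* `diurnal(t)` is a two-level step: day level = 3.7 × night level under the
  14 h/10 h photoperiod, renormalized so the daily mean is 1
  (day factor 1.437, night factor 0.388).  Only a day:night contrast is
  reported for the real data, so no smoother shape is assumed.
* `decay(t)` is 1 during the first day and halves every 3 days afterwards.
  The onset after 24 h reflects the observation that spiking shows no
  apparent decline during the first day of infestation; the half-life is a
  free parameter (the real decline is reported qualitatively only).
* `survival(t)` (insecticide-treated pots) is 1 − the dead-or-affected
  fraction, a piecewise-linear curve through the daily assessment
  checkpoints: VC stage (0, 0) → (1, 0.83) → (2, 1.0); R5 stage
  (0, 0) → (1, 0.62) → (7, 0.98), constant after the last checkpoint.
  Checkpoints are reproduced exactly.
* `knockdown(t)` (treated pots) is an additional fast feeding-suppression
  factor `2^(-t / 3 h)`.  Contact knockdown and feeding deterrence act
  within hours, well before impairment is visible at daily assessments;
  without this factor a treated pot would spike ~3× the control level on
  day one, contradicting the observed pattern in which treated plants are
  indistinguishable from controls from the onset and fall *below* controls
  by day three.  The assessed-mortality curve still governs the insect
  status ground truth exactly.

Non-infested plants, all plants before DAI 0, and plants after manual
insect removal run at the control rate (10 events/day, times the diurnal
factor).  The control level is not published; 10/day keeps control bars
visibly non-zero, as in the real figures.  Removal drops the rate to the
control level immediately at the removal instant (the real data show
reversion within a day; sub-day dynamics are not resolvable from the text).

Irrigation events multiply the rate by a random Gamma factor with mean 1
and variance 1.0 for 2 h (a doubly stochastic burst): irrigation is reported
to increase the *fluctuation* of spike detection, not obviously its mean.

Realization is by thinning against a grid-estimated supremum (padded 10%
because step discontinuities can fall between grid points; candidates are
re-checked against the bound, so the realization stays exact).  All
randomness descends from one `SeedSequence` with one spawned child per
channel; identical inputs reproduce recordings bit-for-bit.  Channels of the
same plant (stem and pod) are independent realizations of the same rate —
the real data motivate this simplification by showing statistically
indistinguishable counts and amplitudes at the two insertion sites.

## Preprocessing

Per-channel median subtraction (robust to sparse spikes; idempotent)
establishes the common baseline, followed by a zero-phase Butterworth
bandpass 0.0025–0.010 Hz: order 2 per pass, applied forward–backward as
second-order sections (effective order 4, no phase distortion, so event
times are preserved), with reflective padding of one low-cut period (400 s)
per end.  Traces shorter than three low-cut periods are rejected rather
than filtered badly.  The filter family, order and edge handling are not
published; these are this package's choices, standard for slow biopotentials.

## Detection

A sample is an event iff its score (|v|; configurable to one polarity)
reaches the threshold (1 mV, inclusive) and is the maximum score within
±100 s, ties resolved toward the earlier sample.  The 100 s window — the
period of the upper passband edge — prevents one slow transient from being
counted twice; its direct consequence is a detector dead time: of two
events closer than 100 s the smaller is suppressed.  A deliberately naive
O(n·w) transcription of the same rule is kept as a test oracle, and the
vectorized implementation must agree with it exactly.

Two quantified consequences of the dead time (measured on simulated
cohorts, and the reason two distribution laws are tested on restricted
event sets):

* at day-phase rates (~3.4 events/h) roughly 7–10% of day events are
  suppressed versus ~3% at night, so a day:night rate ratio measured on
  first-day data alone underestimates the injected 3.7 by ≈0.3;
* the detected-amplitude distribution equals the injected normal truncated
  at the threshold only for events without a close, larger neighbour; the
  truncation test therefore uses isolated events (neighbour gap >300 s),
  a restriction independent of amplitude.

## Quantification

Windows are half-open, aligned to DAI 0 (matching the DBI/DAI axes of the
published figures, not calendar midnight), with lengths dividing 24 h.
Counts are reported raw and as `log10(x + 1)`, the transform used for all
count statistics.  Hourly windows are labelled day/night via the
photoperiod (day = first 14 h of each cycle, half-open); with integer
lights-on every clock hour is single-phase.  The day:night contrast is
reported two ways: the published median-based ratio (medians of raw hourly
counts) and a mean-hourly-rate companion.  Medians of low-count Poisson
hours are coarse — a median ratio of 3/1 is the closest attainable value
near 3.7 — so parameter-recovery checks use the mean-rate ratio and report
the median descriptively.  The calibration estimator pools all infested
days of a 20-plant × 5-day cohort (100 plant-days): pooling across the
decaying multi-day rate range both matches the "plant-days" framing and
averages the dead-time bias of single-day estimates.

The average spike waveform is the peak-aligned mean of per-event segments
(negative events sign-flipped), skipping and counting events too close to
the trace edge.  The parameter sweep runs the full pipeline over a
(threshold, low-cut, high-cut) grid and reports the infested-minus-control
mean log-count separation and the total count, flagging the Pareto set —
the trade-off that motivates the 1 mV / 0.0025–0.010 Hz operating point.

## Statistics

Per-window one-way fixed-effects ANOVA on per-channel `log10(x + 1)` counts
with Tukey HSD pairwise comparisons; paired two-sided t-tests for
within-plant contrasts (stem vs pod, day vs night); t-based 95% confidence
intervals for insect-survival counts; significance stars at 0.05/0.01/0.001.
The experimental unit is the pot/channel, windows are tested marginally
without cross-window multiplicity correction (matching per-window stars in
the published figures), and no mixed-effects structure is attempted.
Degenerate inputs (zero within-group variance everywhere, zero-variance
paired differences) are flagged rather than reported as arbitrary numbers.
Pod damage is classified from the percentage of damaged seeds:
<1% none, 1–30% moderate, 31–50% critical, 51–70% severe, 71–100% complete
("none" is implied, not named, by the published scale); fractions round to
the nearest integer percent.

## Defaults at a glance

| parameter | default | unit | origin |
|---|---|---|---|
| bandpass | 0.0025–0.010 | Hz | published |
| detection threshold | 1.0 (inclusive) | mV | published |
| min separation | 100 | s | upper passband period (package choice) |
| amplitude mean / SD | 1.9 / 0.8 | mV | published |
| day:night rate ratio | 3.7 | — | published |
| injected day-1 rate | 57.5 | events/day | derived (≈50 detected) |
| control rate | 10 | events/day | package choice |
| decay half-life (after day 1) | 3 | days | package choice |
| treated knockdown half-life | 3 | h | package choice |
| mortality checkpoints | VC 0.83@1, 1.0@2; R5 0.62@1, 0.98@7 | fraction | published |
| photoperiod | 14 / 10 | h | published |
| template rise / decay | 15 / 60 | s | package choice |
| sample interval | 1 | s | package choice (≥50× oversampling) |
| white noise / drift step | 0.2 / 1.0 | mV | package choice |
| sensitivity half-life | 60 | days | package choice |

## What the generator does and does not emulate

It emulates: the three experiment designs (pots, insects, electrode
placements, insertion days), diurnally modulated infestation spiking with
decline, insecticide and removal dynamics, assessed insect mortality,
amplitude statistics, drift, broadband noise, irrigation burstiness and
electrode ageing.  It does not emulate: insect movement and spatially
heterogeneous feeding, within-plant signal propagation (stem and pod
channels are independent), non-stationary circadian shape (step, not
sinusoid), weather or greenhouse-climate coupling, electrode contact
artifacts, or any biophysical membrane mechanism — events are
phenomenological.  Passing tests therefore demonstrate that the pipeline
recovers known structure of this class of signals at realistic rates and
signal-to-noise; they cannot certify performance on real recordings, whose
artifact structure is unmodelled.

## Numerical choices and problem sizes

Half-open conventions everywhere (windows, photoperiod phases, spans);
boundary events belong to the later window.  Exact detection ties go to the
earlier sample.  CSVs are written with 17 significant digits and parsed
with round-trip float precision, so write→read is lossless and reruns are
byte-identical.  Night medians of zero make the median ratio undefined and
flagged, never infinite.  Test and calibration cohorts are sized to give
stable statistics in seconds on one CPU: 10,000 amplitude draws, 20 plants
for first-day counts, 100 plant-days for the day:night contrast, 160
flat-profile plants (2 s sampling) for the n≥5000 truncation law, 1000–2000
replicates for Monte-Carlo rate and type-I-error checks.

## Known limitations

* Detector dead time biases rate estimates at high rates (quantified
  above); no dead-time correction is applied because the published
  quantities are plain windowed counts.
* The treated-pot knockdown half-life and the control rate are
  unpublished free parameters; absolute treated/control levels should be
  read qualitatively.
* The piecewise-linear mortality curve is exact only at assessment
  checkpoints; between-day dynamics are an interpolation.
* Real F/t/p values from the original recordings cannot be reproduced —
  the recordings are unreleased; the statistical layer is validated by
  construction (type-I error, F = t², coverage) and by qualitative
  scenario patterns instead.
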