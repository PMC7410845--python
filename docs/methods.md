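# Methods

This package reimplements, as tested and reusable code, the complete
analysis battery of a tVNS-paired speech-category-learning experiment:
behavioral learning statistics, the frequency-following-response (FFR)
pitch-encoding pipeline, the sub-threshold vagal-evoked-potential (VEP)
pipeline, and the stimulation protocol.  The original human data are not
publicly deposited, so every analysis runs on synthetic data whose
generating processes mirror the study's statistical structure.  This note
records the models, the defaults and why they were chosen, and what the
synthetic conditions do and do not establish about real data.

## The experimental design being emulated

Thirty-six native English speakers (12 per group: tVNS-easy, tVNS-hard,
Control) learn to categorize Mandarin syllables into four lexical tones
(T1 high-level, T2 low-rising, T3 low-dipping, T4 high-falling) over six
40-trial training blocks with corrective feedback, followed by a 40-trial
generalization block with novel talkers and no feedback or stimulation.
The stimulus catalog is 5 syllables x 4 talkers x 4 tones = 80 items,
split into training and generalization talker halves.  The tVNS-easy
group receives sub-perceptual-threshold stimulation paired with the
perceptually salient tones (T1/T3), tVNS-hard with T2/T4; a supplementary
tVNS-feedback condition pairs stimulation with positive feedback.  A
separate aggregate cohort of 678 unstimulated learners provides a
resampling null for group-level learning gains.

## Synthetic generators (`synthgen`)

**Tone templates.** Only the ordinal contour relations (level vs. rising
vs. dipping vs. falling, high vs. low register) matter to the pipeline,
so tone F0 templates are simple piecewise polynomials inside a
configurable speech band, default 100-300 Hz (female register): T1 flat
at 0.85 of the band with a 1% ripple, T2 an accelerating rise from the
low register, T3 a parabola dipping to the band floor at 60% of the
syllable, T4 a linear fall across most of the band.  Talkers differ by a
fixed +/-6% F0 scaling.  Stimulus duration defaults to 0.40 s, the
duration-normalized length of the natural Mandarin monosyllables used in
this training paradigm.

**Learner cohorts.** Trial outcomes are Bernoulli draws from
`logit p = baseline + slope_g * trial + tone_offset + b_subject`, with
`b_subject ~ N(0, 0.5^2)` and the trial index running 1..240 through the
training phase.  This is exactly the model family the analysis fits
(logistic GLMM with random subject intercepts), so parameter-recovery and
calibration studies are well-posed.  Defaults: baseline logit -1.1 (~25%
chance at trial 0), Control slope 0.006 logit/trial (matching the scale
of learning the unstimulated analysis reports), tVNS-easy 0.008,
tVNS-hard 0.005, tone offsets +/-0.3 (easy tones above hard tones, which
reproduces an easy-vs-hard accuracy gap of roughly ten percentage
points).  Incorrect responses are uniform over the other three tones.
The tVNS-feedback condition runs a shorter training (default 4 blocks;
the source describes only "a shorter version", so the count is config).

**Aggregate cohort.** Each of 678 learners gets an independent baseline
(`N(-0.85, 0.45^2)` logits, ~30% Block-1 accuracy) and learning slope
(`N(0.004, 0.003^2)` logit/trial); block accuracies are binomial draws.
Learners above 85% correct in Block 1 are excluded before any analysis,
and the excluded count is recorded on the returned table.

**FFR acquisition.** Each single-trial FFR is a unit sinusoid whose
instantaneous frequency follows the stimulus F0 contour delayed by a 7 ms
neural latency, plus Gaussian noise band-limited to the 80-1000 Hz
analysis band; SNR is the RMS ratio in dB and `signal_scale = 0` yields
pure noise.  Trials repeat with inter-stimulus intervals jittered
uniformly on 122-148 ms; 1100 repetitions per exemplar reproduce the
study's acquisition count.  The simulation sampling rate defaults to
8 kHz (the hardware ran at 25 kHz; all analysis parameters are expressed
in seconds/Hz, so the rate only affects cost).  In end-to-end cohort
runs the single-trial SNR defaults to -15 dB with a 4 dB between-subject
spread: single-trial FFRs sit below the noise floor and only averaging
(~100 trials at desk scale, ~1000 in the study) reveals the contour,
which yields the realistic spread of stimulus-response correlations
needed for the encoding mixed models.

**tVNS artifacts.** Pulse artifacts are the rendered biphasic square
pulse (150 us per phase) scaled by 100 uV/mA; the optional evoked
component is a triphasic sum of Gaussians with peaks -1.07 uV at 2 ms,
+0.27 uV at 6 ms and -0.15 uV at 11 ms after pulse offset (the reported
N1/P1/N2 morphology).  Injection returns ground-truth markers for
round-trip tests.

## Behavioral statistics (`behavior_stats`)

**Binomial GLMM.** `outcome ~ group*trial + (1|subject) + (1|tone)` with
a logit link, Control and Block 1 as reference levels.  No installed
Python package fits frequentist binomial mixed models, so the package
implements the Laplace approximation directly: for candidate variance
components the joint penalized log-likelihood is maximized over fixed and
random effects by damped Newton steps (tolerance 1e-6), the marginal
likelihood is approximated at the joint mode, and the variance components
are profiled by Nelder-Mead.  This is the same strategy as lme4::glmer
(nAGQ = 1), and the test-suite verifies agreement with lme4 on shared
data to ~0.01 on coefficients.  Wald z and two-sided normal p-values are
reported; separation and non-convergence are flagged on the returned fit
rather than raised.  Under null simulations at the study's scale the
interaction test rejects at 4-5% for alpha = 0.05.

**Retention.** For each participant and block n >= 2, the percentage of
the 40 training stimuli answered correctly in both block n and block
n-1; modeled as `retention ~ group*block + (1|subject)` via REML
(statsmodels MixedLM), block 2 reference.  The linear model's Wald
statistics are reported as z (whether the original report's z for this
model is Wald z or t-as-z is ambiguous; on 60+ observations the two are
indistinguishable).

**Improvement and the Monte-Carlo null.** Per-participant improvement is
the mean over blocks b >= 2 of (accuracy_b - accuracy_1) in percentage
points (a last-minus-first variant is available by flag).  The
Monte-Carlo p for a group is the proportion of 1000 sub-populations of
12 learners, resampled without replacement from the aggregate cohort,
whose mean improvement is at or above the group mean (one-sided upper
tail, ties counted as exceeding).  Calibration: groups drawn from the
aggregate's own generating distribution produce uniform p-values (KS
test at alpha = 0.01).  Each calibration replicate regenerates the
aggregate: p-values computed against a single fixed finite aggregate are
correlated across replicates and systematically non-uniform, so only the
fresh-aggregate design is a valid uniformity check.

**False positives.** Percent of non-target-tone trials answered with a
target tone; the denominator is the non-target trials (the source does
not state one; an all-trials denominator is available by flag).

**Psychometric slope.** Logistic regression of "rising" responses on the
continuum step index; acuity is |beta|.  Perfect separation leaves the
slope at the optimizer bound and flags the fit.

## FFR analysis (`ffr_analysis`)

**Filtering.** "Zero-phase second-order Butterworth, 80 Hz-1 kHz" is
implemented as a second-order design applied forward and backward
(filtfilt), i.e. fourth-order magnitude; the wording does not
disambiguate, and this is the conventional reading.

**Epoching.** Epochs span [onset + 7 ms, onset + 7 ms + duration), are
baseline-corrected to the mean of the pre-onset noise floor (-40-0 ms)
and rejected beyond +/-50 uV.  Because segmentation removes the latency,
response and stimulus contours share the stimulus clock and correlate
without further alignment.

**Pitch tracking.** 40 ms frames sliding in 10 ms steps ("30 ms
overlap"; the alternative hop = 30 ms reading would leave a 0.4 s
stimulus with 13 frames and is rejected).  Per frame the unbiased
autocorrelation is searched over lags for 60-400 Hz; among local maxima
the smallest lag within 10% of the best is taken (guarding against
octave-down errors, since lag 2T scores as well as lag T for a periodic
frame), refined by parabolic interpolation.  Voicing is decided on the
Pearson correlation between the frame and its lag-shifted copy
(threshold 0.3): unlike the raw unbiased ACF value, this statistic is
bounded by 1 and does not over-voice noise at long lags.  All parameters
are configurable.

**Scoring.** Stimulus and response contours are interpolated onto a
common frame grid over their shared support; Pearson r runs over frames
voiced in both (>= 3 required, else missing).  Averaged responses whose
trial count falls more than 5 SD below the leave-one-out cohort mean are
flagged for the caller (mirroring the study's exclusion of one average
built from 686 instead of ~995 trials).  Encoding quality is modeled per
tone as `r ~ group*session + (1|subject)` via REML.

**HMM decoding.** "Training size 500 / testing size 500 / averaging size
200" is read as a disjoint split of the ~1100 single trials into training
and testing sets, with sub-averages of 200 trials resampled with
replacement within each set.  The disjoint split matters: resampling
train and test sub-averages from one shared pool leaks pool-specific
noise means and decodes even identically distributed tone sets well above
chance, while the split restores chance behavior.  Features are
frame-wise [F0, log energy], standardized on the training set; one
4-state left-to-right Gaussian-emission HMM per tone (hmmlearn, zeros in
the transition matrix preserved by EM) is trained per participant, and
test sub-averages go to the higher-likelihood model.  Confusion is the
percent misclassified; pre/post change is post minus pre.  Chance-level
checks use replicate means with a +/-15-point band: sub-averages within
a replicate share trials and are correlated, so replicate-level spread
(SD ~ 12 points), not the nominal binomial CI, sets the scale, and the
band is three standard errors of a 6-replicate mean.

## VEP analysis (`vep_analysis`)

**Detection.** The pulse template, padded with 0.5 ms of zeros per side
(a match requires locally flat surroundings), is cross-correlated with
the EEG under window normalization, so scores are bounded by 1 and
amplitude-invariant.  Local maxima at or above `threshold_frac`
(default 0.6) of the perfect-match score, separated by a refractory
spacing of 80% of the nominal 40 ms inter-pulse interval, become onsets;
offsets add the template length.

**Excision.** Only the samples inside each [onset, offset) gap are
replaced; the 2 ms pads are conditioning context, not removed (one
plausible reading of "2 ms both sides the gap"; the alternative of also
removing the pads widens every gap sevenfold at these pulse widths).
Reconstruction fits least-squares AR models — order = samples in 4 ms,
100 at 25 kHz — on the context adjacent to each side and crossfades the
forward and backward predictions linearly across the gap, the same
scheme as MATLAB's fillgaps.  Samples outside the gaps are bit-identical
on output; edge gaps fall back to one-sided extrapolation with a
warning.

**Epoching and peaks.** Response epochs (0-15 ms after pulse offset) are
corrected against their own pre-onset baseline (-15-0 ms) and rejected
beyond +/-35 uV.  N1/P1/N2 are windowed extrema of the average in
[0,4], [4,9] and [9,15] ms (configurable windows bracketing the nominal
2/6/11 ms); an extremum on a window edge or an all-zero average sets a
low-confidence flag.  Note the band-pass filter attenuates the injected
Gaussian components' magnitudes (N1 -1.07 uV injected recovers ~-0.8 uV)
without shifting latencies; magnitude comparisons are therefore always
within-pipeline, never against the injected template.

**Group statistics.** Peaks are tested against baseline magnitudes with
two-sample t-tests per component (the study's wording; a paired variant
is exposed).  Intensity analyses report per-component Pearson r against
stimulation amplitude plus mean magnitudes in the half-open bins
(0.2,1], (1,2] and (2,3] mA (so exactly 1.0 mA is "low"), the inverted-U
summary.  Peak-vs-learning correlations use the per-participant percent
improvement.

## Stimulation protocol (`stim_protocol`)

The staircase steps up 0.1 mA after a miss and down 0.3 mA after a
detection, terminating after 8 reversals; the threshold is the mean
amplitude at the reversal points ("average stimulation amplitude after
eight reversals" read as the standard reversal average; the mean of all
post-first-reversal amplitudes is available by flag).  The training
amplitude is the estimate minus 0.2 mA, floored at zero.  Starting
amplitude and the iteration cap are configuration (a degenerate observer
raises after the cap).  Pulse trains are 15 biphasic pulses, 150 us per
phase, at 25 Hz, first pulse 300 ms before stimulus onset; amplitudes
above 3 mA raise a safety error by construction.  The nominal train
(14/25 s = 560 ms) extends ~260 ms into the stimulus; the onset is
configurable, and within-trial jitter is not modeled by default.
Pairing flags are a pure function of (condition, tone, outcome) and are
never set in the generalization block.

## Orchestration, sizes and runtime

`run_full_pipeline` expands one global seed into per-stage seeds via
`numpy.random.SeedSequence`, so stages are independently reproducible
and a run is a pure function of its `RunConfig`.  Every exclusion step
logs (before, after, rule) to `log.jsonl`.  Desk-scale defaults: the
full 36-participant cohort with 240 trials each, 144 averaged FFR
records built from 100 (not 1100) repetitions per exemplar at 8 kHz,
10 pulse trains per stimulated participant at 25 kHz; a complete run
takes well under a minute.  Calibration studies in the acceptance
suite use 500 null replicates and 100 recovery replicates at the full
cohort scale, and HMM checks use pools of 120 trials with 60/60
train/test splits and sub-averages of 30 — scaled-down analogues of the
500/500/200 study parameters chosen so the whole battery runs in
minutes on one CPU.

## What passing does and does not show

The synthetic generators share the fitted models' functional form, so
recovery and calibration results validate the estimators and the
pipeline plumbing — not the models' adequacy for real EEG or behavior.
Real FFRs contain harmonics, non-stationary noise, and latency jitter
that the single-sinusoid model omits; real pulse artifacts vary in shape
across electrodes; real learners drift and lapse.  Conclusions supported
by the tests are therefore of the form "the implementation measures what
it claims with the stated accuracy under the stated model", which is the
precondition for — not a substitute for — validity on recorded data.

## Known limitations

- Recordings are exchanged as two-column delimited text; EDF I/O is not
  provided.
- The binomial GLMM supports random intercepts only (the study's models
  use only intercepts; random slopes were reported to not improve
  deviance).
- The HMM decoder's feature set and topology follow common FFR decoding
  practice (frame-wise F0 + energy, left-to-right states); the original
  classifier's exact internals are documented elsewhere and were not
  reproduced sample-for-sample.
- Degrees of freedom are always reported as (df_between, df_within);
  some published F subscripts appear order-swapped and are not imitated.
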