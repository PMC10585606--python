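# Methods

## Signal model

The pipeline assumes phasic pupil activity on each trial is a linear
superposition of two stereotyped components riding on noise:

* a **task-related response**: a slow dilation entrained to trial
  timing, present on every trial, whose amplitude indexes arousal and is
  the component a reward manipulation should drive;
* a **stimulus-evoked response**: a transient constriction following
  the onset of an equiluminant peripheral grating, confined to roughly
  the first 4 s of the trial, whose amplitude scales with stimulus
  contrast and spatial frequency.

Amplitudes, not waveforms, carry the scientific questions.  The
waveform ("response template") is treated as participant- and
condition-specific but constant across trials, so a two-parameter OLS
fit per trial — template coefficient plus intercept — converts each
7500-sample epoch into one amplitude.  Goodness of fit (R²), and the SD
of the epoch across time as a regression-free amplitude proxy, are kept
alongside.

## Preprocessing

Order of operations: blink detection → interpolation → z-scoring →
low-pass filtering.

* **Blinks.** A sample is blink-like if the tracker flagged it or its
  pupil value is non-finite or ≤ 0 (the dropout conventions of
  ASC-derived exports).  Maximal blink-like runs are padded by
  `blink_pad = 3` samples on both sides, merged, and replaced by the
  straight line joining the flanking samples; intervals touching a run
  edge hold the nearest finite value (with a logged warning).
* **Normalization.** The pupil series of all runs of a session are
  concatenated and z-scored with one global affine map (population SD).
  Interpolation happens first so blink zeros cannot contaminate the
  global mean and SD; the opposite ordering — z-scoring statistics from
  the raw concatenation — is available via
  `AnalysisConfig.zscore_before_interpolation` because the original
  description leaves the order open.  The effect is a scale factor
  only, common to all trials of a session, and cancels out of every
  within-participant comparison.
* **Filtering.** A digital (bilinear, pre-warped) 3rd-order Butterworth
  low-pass at 4 Hz is applied per run — runs are temporally
  discontinuous, so filtering the concatenation would smear run
  boundaries (`filter_scope` switches this).  To cancel the phase
  shift, the series is padded with 200 points per end lying on the
  least-squares line through the nearest 50 original samples, filtered,
  reversed, filtered again, re-reversed and trimmed.  "Linearly
  interpolated from the nearest 50 timepoints" is read as least-squares
  linear *extrapolation*: interpolation is undefined beyond the series
  boundary, and a fitted line damps edge transients.  Each pass starts
  from the filter's step steady state scaled to the first padded sample,
  so a constant series passes through exactly (DC gain 1); the two
  passes square the magnitude response, giving amplitude ratio 0.5 at
  the 4 Hz cutoff and zero net phase (input–output cross-correlation
  peaks at lag 0).

Epoching takes the first `trial_samples = 7500` samples from each trial
onset (0-based, half-open window) — the minimal trial length the design
guarantees — so all trials are directly comparable.

## Template regression

Per participant, four templates: the null template per reward level is
the mean of that level's null trials; the stim template per reward
level is the mean of that level's stim trials after subtracting the
*un-normalized* null template (subtraction must happen in signal
units).  Templates are z-scored (population SD) before entering the
design matrix so the amplitude scale is common across conditions;
degenerate (constant) templates raise instead of propagating NaN.
Templates include the trial being fit — no leave-one-out — matching the
original description; with ~25 null trials the self-inclusion bias on
the amplitude is O(1/n) and identical across the conditions being
compared.  Stim templates are kept constriction-shaped (not
sign-flipped), so a *positive* stim amplitude means a larger
constriction.

The per-trial fit is the closed form β = cov(Y, template)/var(template)
with intercept ȳ − β·mean(template); it is checked against a generic
least-squares solver in the tests.  R² is computed about the trial
mean, consistent with fitting an intercept.  `sd_measure` is the SD of
the *measured* epoch (before null subtraction), reading "SD of pupil
size across time on each individual trial" literally.

## Pseudo-trial split bootstrap

To show that the null-template subtraction cannot manufacture or hide a
reward effect on stimulus-evoked amplitudes, null trials (which contain
no stimulus response) are re-analyzed as if half of them were stimulus
trials: per iteration and participant they are split in half within
each reward level (the odd trial goes to the pseudo-null half),
the full template pipeline is re-run on the split, and the high-minus-
low mean amplitude difference is recorded per pseudo kind.  Per
iteration the per-participant differences are averaged into one
group-level value (a per-participant "pooled" aggregation is also
available; which the original used is not stated).  The one-sided p is
the fraction of the null distribution at or equal to the actual
difference; the literal fraction can be 0, so a smoothed
(k+1)/(n_iter+1) variant exists and is what calibration studies use.

Implementation note: all bootstrap amplitudes live in the span of the
participant's null-trial vectors, so iterations run on the trials' Gram
matrix — an exact algebraic reformulation of the per-trial regressions
(the test suite proves equality with the direct computation).  This
makes 10,000 iterations per participant effectively free.

Random-stream discipline: one master seed spawns independent
per-participant child streams (`numpy` `SeedSequence`), so results are
reproducible and participant order does not couple streams.

## Group inference

* **Paired comparisons** of per-participant condition means: Shapiro–
  Wilk on the differences (normality screen), paired t with its
  parametric CI, Wilcoxon signed-rank (normal-approximation Z, signed
  by the effect direction) with a BCa bootstrap CI of the mean
  difference.
* **BCa intervals**: bias constant z₀ from the fraction of bootstrap
  replicates below the point estimate, acceleration from jackknife
  skewness; with z₀ = a = 0 the interval reduces exactly to the
  percentile interval, and a degenerate bootstrap distribution
  collapses to the point value with a warning.
* **Scheirer–Ray–Hare**: all N values are mid-ranked jointly, factorial
  ANOVA sums of squares are computed on the ranks (Type II on
  unbalanced data), and H = SS_effect / MS_total with
  MS_total = SS_total/(N−1) is referred to χ² with the effect's df.
  Using the observed rank variance makes the tie correction implicit:
  with one factor this H is *exactly* tie-corrected Kruskal–Wallis
  (verified against an independent implementation).  SRH ignores the
  subject factor (a plain factorial rank test), a known limitation of
  the construction.
* **Mixed ANOVA**: trial-level amplitudes with subject as an additive
  random blocking factor, so the residual df reflects the trial count
  (denominators in the thousands).  Type-II sums of squares handle the
  unbalanced cells a 75%-stim design produces; on balanced complete
  designs the decomposition is exact (effect + subject + residual SS =
  total SS).  A factor constant within every subject is refused as
  confounded.
* **Behavioral accuracy**: percent correct excluding missed responses,
  per participant × reward × trial type; all-missed cells are absent
  rather than zero.
* No multiple-testing correction is applied; the report prints raw p
  values.

`dissociation_report` assembles the full table: reward effects on null-
and stim-trial amplitudes (and on the SD measure as a robustness
column), reward × contrast, reward × spatial-frequency and contrast ×
spatial-frequency factorials plus the three-way mixed ANOVA, accuracy
comparisons, and the bootstrap p values.

## Synthetic-data generator

The generator emulates the experiment the analysis was built for:
500 samples/s, 17 trials per run, 75% stimulus trials, run-level reward
alternating high/low, gratings at contrasts {0.2, 1.0} × spatial
frequencies {0.5, 0.8, 1.3, 2.0, 3.2} cpd, blinks, and AR(1) noise.
Choices the source design leaves open, fixed here once:

* **Kernels** are unit-peak beta-density bumps `(t/T)^3 (1−t/T)^b` with
  the exponent b set by the peak time: dilation peaking at 2.5 s with
  10-s support; constriction peaking at 1.2 s with 4-s support (the
  stimulus/response epoch).  Compact support with a smooth (C²) onset —
  rather than a gamma density, whose tail is still ~10⁻² of peak at the
  trial boundary — keeps each trial's filtered response inside its own
  epoch, which is what makes noise-free cohorts *exactly*
  reconstructible by the regression.  Only the sign, epoch and linear
  scaling structure of the kernels matter to the analysis; no attempt
  is made to match empirical time courses.
* **Trial spacing**: recorded trials last 16.0 s of which the first
  15 s (7500 samples) are analyzed, mirroring recordings in which the
  analysis window is the minimal trial length.  The 1-s overage also
  keeps the zero-phase filter's backward smear of the next trial's
  response (decay e^(−12.5 t) from the 4 Hz Butterworth poles) out of
  the preceding epoch.  Runs carry a 1-s baseline lead-in/lead-out.
* **Amplitude structure**: reward drives only the task-related
  amplitude by default (gain 1.5 high vs 1.0 low), so the double
  dissociation is the ground truth; `reward_target="stim"` routes the
  same ratio onto the stimulus gain instead, for counterfactual tests.
  The stimulus gain surface is multiplicative,
  g(c, s) = 0.8 · c^0.7 · (s/s_max)^0.4 — increasing in both factors
  and producing a factorial interaction on the amplitude scale — with
  an additive option (mean of the two factors' terms) for
  interaction-null calibration.
* **Noise**: per-trial amplitudes are mean-preserving lognormal around
  their condition means (σ_log = 0.2; amplitudes are positive gains);
  additive AR(1) noise with stationary SD 0.3 (in signal units, i.e.
  ~30% of the low-reward task amplitude) and lag-1 coefficient 0.99 at
  500 samples/s (~0.2-s correlation time); blinks are Poisson events
  (15/min, 100–400 ms) encoded as zeroed, flagged samples; gaze is
  white jitter (SD 0.15°) around fixation; per-subject kernel peak
  times get lognormal jitter (σ = 0.1).  Responses are drawn at 76%
  accuracy with a 4% miss rate, independent of condition.

What the generator does **not** emulate — and hence what passing tests
do not certify about real data: pupil foreshortening and gaze-dependent
artifacts, saccades and microsaccade-linked constrictions, slow
session-scale drifts and tonic baseline changes, luminance imbalance,
trial-to-trial waveform shape variability within a participant, and any
dependence of behavior on stimulus condition.  The generator's additive
kernel-plus-noise structure matches the analysis model by construction,
so recovery results certify the *implementation*, not the biological
adequacy of the linear-system assumption.

## Study sizes used by the packaged checks

Chosen so each check estimates what it needs at useful precision:

* exact recovery: 3 subjects × 2 runs, noise-free, native resolution;
* dissociation recovery: 30 subjects, 6 runs × 17 trials, 20 seeded
  replications per direction of the reward manipulation;
* bootstrap calibration: 300 reward-free cohorts (6 participants × 24
  null trials of 1500 samples at 100/s), 500 iterations each, smoothed
  p, with the "actual" value taken from one additional independently
  seeded split so that exchangeability — and hence uniformity of p —
  holds exactly (comparing the full-sample difference against
  half-sample splits is conservative by construction);
* factorial type-I error: 1000 value-level null simulations of a
  balanced 2 × 5 design (the machinery, not the generator, is what is
  being calibrated);
* interaction detection: 30 cohorts per gain mode at 10 subjects ×
  6 runs, 250 samples/s;
* BCa coverage: 500 simulations of n = 30 at 2000 replicates.

## Known limitations

* The mixed ANOVA realizes "subject as a random effect" as a fixed
  additive block on trial-level data — an intercept-only random effect
  with the residual as error term; random slopes would need a true
  mixed model, which is out of scope.
* SRH has no subject term and, like all rank-transform factorial tests,
  limited power and only approximate behavior for interactions under
  strong main effects.
* The literal bootstrap p can be exactly 0; report such values as
  < 1/n_iter or use the smoothed variant.
* Blink detection is a reproducible superset (flags ∪ non-positive ∪
  non-finite) of a tracker's proprietary online detector, not a
  reimplementation of it.
* EyeLink EDF/ASC files are not parsed natively; exports must be
  converted to the documented TSV layout first.
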