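# Methods

## Scope and model

`apneahrv` analyses whole-night beat-to-beat (RR) interval series. The
premise is physiological: obstructive and central apnea events provoke a
cyclic variation of heart rate — progressive bradycardia during the event
with an abrupt tachycardic recovery at its end — so a night with many
events concentrates tachogram power at very low frequencies and inflates
global variability measures. The package quantifies this with eleven
whole-night HRV features and relates them to clinical severity measures
(AHI, ODI, ESS) by ordination and supervised classification. The analysis
deliberately uses the *whole* recording, with no prior per-event scoring.

Input begins at annotated beats: R-peak detection from raw ECG waveforms is
out of scope (EDF annotation channels can be read through the optional
`mne` extra).

## RR pre-filter

Two rules, applied in order:

1. **Range rule** — intervals < 300 ms or > 1500 ms are implausible during
   sleep and are excluded. The wording is read strictly: exactly 300 ms and
   exactly 1500 ms survive.
2. **Running-median rule** — an interval deviating more than 20% from the
   median of its up-to-ten preceding and ten following neighbours (on the
   range-filtered series, centre excluded) is excluded.

Unspecified details are fixed as follows: the median rule runs once, in a
single pass whose decisions are all made against the input series
(removals do not cascade); edge beats use truncated neighbourhoods and are
kept when fewer than two neighbours exist; even-sized neighbourhoods use
the midpoint median. These choices make the filter deterministic and
testable against a brute-force oracle; idempotence is *not* claimed (a
second pass may remove more beats). Removed beats leave timing gaps;
durations are never modified or interpolated — the filter excludes, it
does not correct.

## HRV features

Time-domain features are computed once over the whole night: SDNN
(population SD of RR), pNN50 (% of successive differences > 50 ms), rMSSD,
IRRR (Q3 − Q1 with linear-interpolation quantiles), MADRR, and the
triangular index HRVi (beat count over the modal histogram count, bin width
1/128 s anchored at 0).

MADRR is implemented as the conventional median absolute successive
difference. The phrase "median of the absolute values of the RR time
series" that sometimes labels this feature would make MADRR a duplicate of
median RR; the literal reading remains available via
`time_domain_features(..., madrr_verbatim=True)`.

Frequency-domain features: the tachogram is linearly interpolated to a
4 Hz grid between the first and last beat (gaps left by filtering are
interpolated across), then short-time Fourier spectrograms are computed
over 300 s windows displaced by 10 s (a 100 s window is supported for
sensitivity analyses). Each window is mean-detrended and Hamming-tapered;
one-sided periodograms with density scaling are integrated over the bands
ULF [0, 0.03), VLF [0.03, 0.05), LF [0.05, 0.15), HF [0.15, 0.40) Hz.
Density integration makes the calibration taper-independent: a sinusoid of
amplitude A inside a band contributes A²/2 ms². Whole-night band powers
are arithmetic means of the per-window values; LF/HF is the ratio of the
aggregated means (not the mean of per-window ratios), which is stable when
individual windows have near-zero HF power. Band edges, taper, resampling
rate and the aggregation rule are configurable; the defaults follow common
HRV-toolbox conventions and are deliberately exposed rather than hidden.

## Ordination

PCA is computed on the correlation matrix — i.e. after standardizing each
feature to zero mean and unit sample SD — because the features carry
incommensurate units. All components are kept, so explained-variance
fractions sum to 1; signs are oriented so the largest-magnitude loading of
each component is positive, making biplots reproducible.

Vector fitting regresses an external variable on the first two component
scores; the normalized coefficient vector is the direction of maximal
correlation and the regression R² its strength. Significance comes from
randomly permuting the variable: `p = (1 + #{R²_perm ≥ R²_obs}) / (1 +
n_perm)` with 999 permutations by default — the add-one form cannot return
p = 0. Surface fitting is the same regression viewed as a linear trend
surface; isocline levels are equally spaced across the fitted range, so a
linear relationship yields parallel, equally spaced contours perpendicular
to the fitted vector — the visual diagnostic of linearity. Restricting
fits to the first two components matches what is plotted and interpreted;
more axes can be requested.

## Classification

Responses are dichotomized at swept percentile cut-offs (10th–90th, step
5), with `value ≥ cutoff` labelled high. No validation scheme is inherent
to the cut-off sweep idea, but resubstitution accuracy would be
misleading, so repeated stratified k-fold cross-validation (default 10
folds × 5 repeats) with out-of-fold scoring is used throughout; features
are standardized inside each training fold only. The operating point is
each classifier's native decision boundary (score 0) so that sensitivity,
specificity and accuracy describe one confusion matrix.

Classifiers: RBF-kernel SVM (C = 1, class-balanced weights), LDA, KNN
(k = 5), and OPLS-DA written in-house (NIPALS orthogonal signal correction
followed by a one-component PLS; the number of orthogonal components is a
fixed hyperparameter, default 1). AUC is the Mann–Whitney statistic with
ties counted 1/2; its 95% CI uses the DeLong placement-value variance. The
cut-off sweep reports every percentile and highlights the
accuracy-maximizing cut-off; no multiple-testing correction is applied
across the sweep, which is a documented caveat of reading the "optimal"
cut-off.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Per subject, an instantaneous RR trajectory on a 0.25 s grid
sums: a baseline drawn from N(1000, 80) ms; a 0.10 Hz oscillation (25 ms)
and a 0.25 Hz respiratory oscillation (20 ms), each with ±30% per-subject
amplitude scatter and random phase; and one bradycardia–tachycardia cycle
per apnea event — half-cosine lengthening over 85% of the cycle, a sharp
drop to a −0.4× undershoot, recovery by cycle end — with cycle lengths
uniform on 30–80 s and swing 120 ms scaled by (0.7 + 0.01·AHI). Events
arrive as a homogeneous Poisson process at the subject's AHI per hour.
Beats are produced by integrate-and-fire stepping through this trajectory
plus 8 ms white per-beat jitter, so event timing and tachogram spectra are
physically consistent and event power lands in the ULF/VLF bands in
proportion to severity.

Both sensors render the *same* beat process; they differ only in artifact
burden. Artifacts arrive as a Poisson process (belt 30/h ≈ 1% of beats,
patch 3/h — the literature gives no quantitative belt/patch rates, so
these are free parameters chosen to reflect textile- vs. gel-electrode
experience) and are, with equal probability, a missed beat (two intervals
merged) or a false beat (one interval split into unequal parts, fraction
uniform on 0.15–0.45). Total recording time is conserved to numerical
tolerance.

Clinical variables: AHI follows a two-component lognormal mixture — an
18% "no apnea detected" fraction with low AHI (log-mean 0.69, log-SD 0.6)
and apnea patients with log-mean 3.30, log-SD 0.98 — calibrated so the
population quartiles sit near 7 / 21 / 41 per hour, the profile of a sleep
laboratory referral cohort; a single lognormal cannot reproduce both that
median and that markedly asymmetric IQR. ODI = 0.8·AHI + N(0, 5) truncated
at zero; ESS is an integer score drawn independently of AHI (mean 9,
SD 4.4, clipped to 0–24), so daytime sleepiness carries no HRV signal by
construction and any apparent ESS classifiability would indicate leakage.
BMI, age and sex are nuisance descriptors.

All draws derive from named substreams of a single per-subject seed, so
cohorts are pure functions of (config, seed) and sensor pairs stay
comparable.

### What the generator does not emulate

Sleep-stage architecture and its HRV modulation, oxygen-saturation
dynamics, circadian baseline drift, ectopic-beat morphology, and
body-position-dependent artifact clustering. Synthetic nights are
consequently *cleaner* than clinical ones: cross-validated AUCs near 0.95
on the default cohort show the pipeline recovers the encoded severity
signal, not that clinical AUCs of that size are attainable (reported
clinical performance for comparable methods is nearer 0.8). Passing tests
demonstrate correctness of the machinery and the qualitative pattern —
AHI/ODI recoverable, ESS not, filtering helping the noisier sensor — not
clinical effect sizes.

## Numerical choices and degenerate inputs

* Onset/duration consistency is enforced to 1 µs on every unfiltered
  series; filtered series may carry gaps.
* An entirely filtered-out series is representable (empty); feature
  extraction requires ≥ 2 beats and a span of at least one spectral
  window.
* Quantiles use linear interpolation throughout (numpy default).
* Permutation p-values use the add-one convention; permutation count and
  seed are recorded in every result.
* Degenerate dichotomizations (single class, or a class smaller than the
  fold count) are skipped with a log entry rather than silently scored.
* Text outputs are written with fixed float formats; rerunning a pipeline
  with the same config and seed reproduces every CSV/JSON byte for byte.

## Problem sizes

The test suite and the reproduction script use the generator's default
conditions (200 subjects, 7 h nights) for the end-to-end pattern checks,
20 seed replicates for the filtering-benefit and vector-fit-pattern
frequencies, 2000 subjects for cohort calibration, 1000 random series for
the filter oracle, and 200 null replicates (999 permutations each) for
permutation-test calibration. Within the 20-seed replicate loop the
cross-validation uses 2 repeats instead of 5 — the quantity of interest
there is a paired within-seed AUC difference, for which extra repeats add
little — while headline AUCs use the full 10×5 scheme.

## Known limitations

* The median-rule pass/cascade semantics of historical analyses vary; ours
  is fixed and documented, and alternatives would remove slightly
  different beat sets.
* OPLS-DA uses a fixed number of orthogonal components rather than inner
  cross-validated selection.
* DeLong CIs are asymptotic and degenerate to a point at AUC = 1.
* The accuracy-optimal cut-off is reported without multiplicity
  correction, and raw accuracy is compared across cut-offs with different
  prevalences: when the classifier is strong, extreme percentiles win
  simply because their baseline (majority-class) accuracy is high. On the
  clean synthetic cohort this drives the "optimal" cut-off toward the edge
  of the swept range; balanced accuracy would behave differently.
* Tachogram resampling interpolates across filter gaps; long gaps
  attenuate genuine high-frequency power.
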