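# Methods

## The measurement model

The unit of analysis is the *participant-day instance*: one
participant's derived daily feature vector with an imputed PHQ-9
score.  Raw inputs are three streams:

* **sensor polls** every `poll_interval_min` minutes (default 2, so
  720/day): relative gravity (acceleration as a multiple of earth's
  gravity, ≈1 at rest), screen state, and optionally latitude and
  longitude;
* **call-log events**: direction (made / received / missed), duration
  in minutes (0 when missed), and a hashed contact identifier;
* **PHQ-9 surveys** every `survey_interval_days` days (default 14),
  total score 0–27.

### Derived variables

The default registry holds 53 variables over four channels.

*Activity.*  A poll is *active* when relative gravity leaves the
stationary band [0.8, 1.2] in either direction — deviation below 1 g
also indicates device motion, since the band is defined as the
stationary region.  Counts (and the per-window active fractions) are
reported for the full day and for the canonical half-open windows
night [00:00–06:00), am [06:00–12:00), day [12:00–16:00),
eve [16:00–24:00).  Eve is the complement that makes the four windows
partition 24 h, so window sub-counts sum exactly to the day total and
a boundary poll is never double-counted.

*Sleep.*  Estimated sleep = poll interval × length of the longest
contiguous run of night polls that are stationary *and* screen-off;
also night screen-on count, night stationary fraction, sleep
efficiency (sleep minutes / 360), and the number of wake episodes.
This is a proxy: it measures device rest inside the night window, not
polysomnographic sleep, and is capped at 6 h by construction.

*Mobility.*  Distinct locations = distinct cells after snapping
coordinates to a 3-decimal-degree grid (~110 m); distance = sum of
haversine hops (earth radius 6,371,000 m) between consecutive located
polls, with hops under 20 m treated as GPS jitter contributing zero.
Hops are assigned to the clock window of their departure poll, so
window distances also sum to the total.  The grid size and jitter
floor are conventional choices for consumer GPS noise and are
configurable.

*Communication.*  `calls_total` counts made+received calls; missed
calls are a separate feature.  `people_called` counts distinct
contacts over made+received.  Mean duration is total/count and is
missing when the count is zero (division guard).  Peak hours default
to [09:00, 18:00) — business hours, configurable — and peak/off-peak
sub-counts partition each base feature.

### Missing data

Missing never means zero.  A day absent from the poll stream yields
missing poll-derived features; a day absent from the call log yields
missing communication features *unless* the log is known to cover the
day with zero events (`covered_call_days`).  A zero-event day is
indistinguishable from an unlogged day in flat call logs, so the
conservative default is missingness; in practice (and in the
simulator) days with zero connected and zero missed calls are rare.
No imputation of sensing variables is performed anywhere: instances
drop out of exactly the comparisons they lack values for.

## Labeling

Daily scores: a day strictly between consecutive surveys receives the
arithmetic mean of the two totals; a survey-date day receives that
survey's total; days before the first or after the last survey stay
unlabeled and are excluded (a nearest-survey carry exists but is off
by default — extrapolating a biweekly screen outward has no support
in the averaging rationale).  Fractional scores are compared to the
cutoffs without rounding: univariate class D iff score > 9, modeling
class D-ML iff score ≥ 5.  Cutoff nesting (D ⊆ D-ML) is a structural
invariant.

## Univariate stage

Welch's unequal-variance t-test per variable, D vs ND, with
Welch–Satterthwaite degrees of freedom.  The summary-statistic route
(`welch_from_summary`) applies identical formulas to printed (mean,
SD, n) triples and reproduces the raw-sample route exactly; it exists
so published tables can be checked without raw data.  P-values are
two-sided by default; a one-sided option is provided because
published single-bound p-values of this design are sometimes
consistent only with a one-sided reading (e.g. a daytime-activity
contrast whose printed .005 matches the one-sided value while the
two-sided value is ≈ .011).  Outlier removal, when requested, applies
Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] per variable per class —
the removal rule is a package choice (standard, and it produces the
expected qualitative effect: shrunken SDs, slightly smaller n).
Samples smaller than 4 are passed through unchanged with a warning.
No multiplicity correction is applied by default; Bonferroni and
Benjamini–Hochberg are available via `adjust=`.

## Classification stage

Complete cases only: an instance missing any registered variable or
its label is dropped entirely.  The 90:10 split is stratified (an
unstratified 10% draw cannot guarantee both classes in a small test
set) with test size = round(N × 0.10); stratified 10-fold CV runs on
the training set; the final model refits on the full training set and
is evaluated once on the test set.  Five families with
library-default hyperparameters and a fixed seed: RBF-kernel SVM,
decision tree, random forest, AdaBoost, XGBoost; the voting ensemble
takes the 3-of-5 majority label.  No nested CV and no hyperparameter
search — method comparison, not tuning, is the purpose.  The CV
interval is mean ± 1.96 × SD of the fold accuracies (fold dispersion,
not a standard error; configurable via `z`), clipped to [0, 100].
Training confusion matrices are reported in both natural readings —
refit-on-train predictions and pooled out-of-fold CV predictions —
because either may be meant when a "training confusion" is published.
Metrics: accuracy, precision, recall, specificity in percent, with
zero-denominator ratios reported missing.

## The synthetic cohort

The simulator emulates the study conditions the pipeline targets: a
46-participant, ~8-week periurban cohort with whole-day stream
losses.  Each participant is none / mild / major with probabilities
(0.60, 0.28, 0.12 by default).  The prevalences are instance-level
realism choices: major-class days make up ~11–12% of labeled
instances and positive (D-ML) days ~40%, matching the accounting of
the cohort type this emulates.  Survey scores are drawn inside the
group's severity band (none 0–4, mild 5–9, major 10–27), so
between-survey averaging keeps every day in its participant's class
and the imputation rule is exercised without class flips.

**Channel targets.**  Each behavioral channel draws a daily aggregate
target from a gamma distribution moment-matched to the configured
class-conditional (mean, SD) — the natural family for non-negative,
right-skewed behavioral aggregates, and the only two-moment match
possible for overdispersed channels such as night screen-ons (CV > 1).
Counts are integerized by stochastic rounding (floor + Bernoulli on
the fractional part), which preserves expectations exactly at the
cost of a variance increase of at most 0.25.  Default contrast
channels: daytime/morning activity, night screen-ons, calls, people
called, call duration; screen use in other windows, missed calls,
excursions and mobility are class-neutral, since mobility contrasts
are not an established effect in this population.

**Mild days.**  Mild-group days sit `mild_severity_shift` (default
0.5) of the way from the ND to the D mean on contrast channels, and
the none-group moments are solved so the none+mild *mixture* — which
is what the ND univariate class is — reproduces the configured ND
mean and SD exactly.  This encodes a severity dose-response without
disturbing class-conditional fidelity; setting the shift to 0 makes
mild days identical to none days (and the positive ML class
correspondingly harder to learn).

**Realization.**  Targets become raw records: active and screen-on
poll slots are placed uniformly within their windows (active polls get
relative gravity strictly outside the band, stationary polls strictly
inside); calls are placed in 08:00–21:00 with exponential-weight
duration splits, the first *p* calls on distinct contacts; GPS is a
participant home point plus 300–3000 m daytime excursions with ~3 m
per-poll jitter (below the 20 m floor, so a home day measures 0 m).
The communication trio shares a Gaussian copula factor (ρ = 0.7);
residual people > calls violations raise the call count to the people
count, inflating the calls-total mean by roughly +0.3–0.6 — people
called stays unbiased, which is the quantity the calibration checks
target.  Missingness drops whole (participant, day, stream) units
independently (default 0.3 per stream; whole-day loss matches the
dominant real failure modes), applied to polls and calls; surveys are
complete, as survey compliance is actively managed in such studies.

**What passing tests show — and do not.**  The simulator makes the
pipeline's arithmetic and contracts testable and shows that the
configured effect sizes are recovered end to end (extract → label →
Welch), and that the classification protocol detects a learnable
signal.  It does not establish classifier performance on real
cohorts: real streams have within-day autocorrelation, participant-
level behavioral idiosyncrasies beyond a home location, partial-day
missingness, device heterogeneity, and label noise that the generator
does not model.  Classifier accuracies on synthetic cohorts are
therefore internal benchmarks, not estimates of field performance.

## Numerical and problem-size choices

Degrees of freedom use sample SDs with ddof = 1 throughout; a
zero-standard-error Welch comparison returns t = 0 (equal means) or
±∞.  Band membership is inclusive ([0.8, 1.2] is stationary);
windows are half-open.  Percentiles use linear interpolation (NumPy
default).  All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns, making every stream, split and
fit reproducible; identical (config, seed) pairs give byte-identical
outputs.  Test-suite and acceptance cohorts use 20–50 participants
over 4–8 weeks (≥ 2000 participant-days at study scale) — sizes at
which the headline contrasts carry |t| ≈ 9–17, so their significance
conclusions are stable across seeds.  File writes are atomic
(write-then-rename), and readers report malformed rows by line number
with skip/abort policies.

## Known limitations

* The 53-variable registry is a faithful reconstruction of the
  four-channel design (window splits, sleep proxies, peak/off-peak
  communication), not a copy of any particular deployment's internal
  list; it is fully overridable.
* Sleep is bounded by the night window; late-night sleepers are
  under-measured.
* The zero-call-day ambiguity (above) means a handful of genuinely
  call-free days are treated as unlogged.
* SVM uses library defaults on unscaled features; it is included for
  protocol completeness, and scaling-sensitive users should wrap it in
  a pipeline with standardization.
* Timestamps are taken as participant-local wall time; no time-zone
  arithmetic is attempted.
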