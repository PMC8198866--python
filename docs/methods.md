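# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical software appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Time and interval conventions

All core computations run in seconds since recording start with half-open
intervals `[start, end)`; absolute datetimes exist only at the I/O
boundary (`recording_epoch`). Posture events must abut exactly (tolerance
1 µs, matching the timestamp precision of the CSV dialect). Clock minutes
for counts-per-minute (cpm) decisions are anchored at the recording start;
the anchor is configurable because exports differ in whether their epoch
grid starts at device start or midnight, and the original convention is
not recoverable from an event file alone.

## The five measurement methods

**POPAI** (dual-sensor reference). Every sitting event from the thigh
sensor is partitioned: `floor(d/60)` start-aligned 60-s spans, plus —
when the duration is not a whole number of minutes — an end-aligned 60-s
window that classifies only the trailing fraction. Events under one
minute get a single window centred on the event midpoint. A span of
length `L` seconds is sedentary iff its synchronized vertical-axis counts
are below `75·L/60` — the fractional cut-point rule (25 counts for a
20-s event). Classification spans partition each event exactly, which
yields the package-wide conservation law *sedentary + active sitting =
sitting*, tested to 1 µs.

**activPAL / ActiGraph** reproduce standard field practice: all sitting
sedentary; minutes with < 100 counts on the vertical axis sedentary. Both
cut-points use a strict `<`, mirroring the stated "fewer than 100 counts"
convention; the 75-boundary operator is configurable since it is never
printed with an operator in the literature this follows.

**activPAL+** applies a trained inactive/active classifier to the thigh
raw signal using the identical partition scheme; sub-minute and remainder
spans take their covering window's prediction. Models carry the feature
registry version and refuse to run against a different one.

**ActiGraph+** applies a per-minute posture model (sit / stand / step) to
the waist signal, then splits sitting minutes at 75 cpm. The posture
model is pluggable: any object with `predict_minutes`. The bundled
default is a random forest over six per-minute waist features
(orientation means per axis, vector-magnitude variability and activity
fraction), trained with the thigh event timeline as its label source —
the same dual-sensor supervision used to build published waist posture
algorithms.

## Pre-processing

*Valid days*: ≥ 500 steps, ≥ 12 h waking wear, and no posture above 95%
of waking wear.

*Bedtime*: the cited bedtime algorithm is proprietary to its authors, so
a configurable heuristic stands in: per night, the longest block of
contiguous non-stepping events overlapping a 22:00–08:00 window, at
least 3 h, clipped to the window; a diary entry overrides it. Nights
whose detected start is after 01:00 or end before 04:30 are flagged for
manual review and never auto-resolved.

*Synchronization*: the waist sensor's delay is estimated by maximizing
the normalized cross-correlation of the two sensors' 1-s movement
envelopes (per-second SD of the vector magnitude — insensitive to
gravity orientation) over ±60 s, then removed as one global shift.
A single clock offset, not drift, is modelled. A peak correlation below
0.2 raises a low-confidence warning.

*Waist non-wear*: candidates are maximal constant-signal runs (per-axis
SD < 10⁻³ g over 1-s blocks in raw mode; all-axes-zero runs in counts
mode). A candidate is non-wear when it lasts ≥ 90 min **or** when the
thigh sensor recorded a posture change or stepping inside it — a
constant waist signal during thigh-detected movement can only mean the
sensor is off. The duration-only reading is selectable
(`movement_qualifies=False`) because the conjunction is genuinely
ambiguous in the field description this follows. Counts-mode boundaries
are only as sharp as the nearest nonzero count; the 1-epoch recovery
guarantee holds for the raw-signal mode.

## Feature catalogues

Set sizes are contractual — 563 (Set 1), 213 (Set 2), 52 (Set 3) — and
enforced at registry construction; the composition within those totals is
this package's design:

* Set 2 = 4 channels (x, y, z, vector magnitude) × 52 time-domain
  statistics (moments, percentiles, crossings, autocorrelations at lags
  1–50, jerk statistics, rolling 1-s-block variability) + 5 cross-axis
  features (3 correlations, signal-magnitude area, mean tilt).
* Set 1 = Set 2 + 4 × 86 frequency features (70 relative band powers up
  to Nyquist + 16 spectral summaries) + 6 cross-spectral features.
  Set 2 is exactly the time-domain subset of Set 1.
* Set 3 = 4 × 13 recurrence-quantification measures of the channel's
  time-delay embedding: recurrence rate, determinism, diagonal-line
  statistics and entropy, divergence, laminarity, trapping time,
  vertical-line statistics, and recurrence-time statistics.

RQA conventions: embedding dimension 4, delay 8 samples, radius = 10% of
the maximum pairwise embedded distance, minimum line length 2 — common
practice, all configurable. The main diagonal is excluded from the
recurrence rate and all line structures (a constant signal still has
recurrence rate 1 because every off-diagonal pair recurs); with no
off-diagonal recurrence, determinism, laminarity, line statistics and
entropies are all defined as 0. Windows are decimated to ≤ 120 embedded
points before the O(n²) matrix; measures are validated against an
exhaustive loop-based enumeration for n ≤ 50.

No additional filtering is applied before feature extraction beyond the
simulator's own bandwidth, since none is described for the instruments
emulated here.

## Training framework

Training minutes are the *middle* integer minutes of each sitting event
(offset `(d − 60k)/2`), labelled inactive iff the synchronized counts are
< 75 cpm. Cross-validity is the mean of sensitivity and specificity of
pooled leave-one-subject-out predictions; a held-out participant with a
single class still receives predictions and contributes to the pooled
score, but the score itself requires both classes overall.

Forward selection scores every remaining candidate per iteration. By
default candidates are scored with the incumbent hyperparameters and only
the winner is retrained with a fresh randomized search
(`candidate_mode="fixed_spec"`); full re-optimization per candidate is
available (`"reoptimize"`) because the original procedure is ambiguous on
this point. The search samples learning method (bagging / boosting),
split criterion, tree count (log-uniform 10–120), split cap (log-uniform
2–64), minimum leaf (1–20) and learning rate (0.05–1); ties break toward
fewer trees, then a smaller split cap, so results are a pure function of
the seed. "Twoing" has no scikit-learn counterpart and is approximated
by Gini impurity; bagging maps to bootstrap-aggregated trees and boosting
to AdaBoost (a boosting round that cannot beat chance falls back to a
majority-class predictor for that fold rather than aborting the search).
Selection stops when the running maximum has not increased for 10
consecutive feature additions, and the model at the maximum is returned.

Among trained candidates (one per feature set at full scale), the
algorithm with the lowest |Bland–Altman bias| against POPAI on the
development cohort wins; ties break by narrower limits of agreement,
then fewer features.

## Comparison statistics

For per-participant mean daily sedentary minutes, differences are
method − reference. Bias = mean(d), SE = SD/√n; LoA = bias ± 1.96·SD with
SE(LoA) = √(3·SD²/n); 95% CIs via t(n−1). The 1.96 multiplier follows
classic Bland–Altman practice; a t-multiplier is a one-line config
change. Relative bias = 100·bias / mean(reference). When the difference
regressed on the pairwise mean has a significant slope (two-sided,
α = 0.05), the bias becomes b₀ + b₁·m; when the absolute residuals do,
the LoA become bias(m) ± 2.46·(c₀ + c₁·m). With both slopes flat, the
object reduces exactly (10⁻¹⁰) to the constant analysis.

The daytime analysis averages, per participant and day type (weekday /
weekend by local calendar date), sedentary minutes in each 30-min clock
bin over days with full wear of that bin, runs Bland–Altman across
participants per bin in % of 30 min, and suppresses bins with fewer than
80% of the cohort (n ≥ 50 at a cohort of 62).

## The simulator: what it does and does not emulate

Behaviour is a semi-Markov chain over BED plus five waking states with
log-normal dwell times; one BED block per night (wake 06:45–22:45).
Default dwell means (20 / 13 / 6 / 17 / 5 min for inactive sitting,
active sitting, inactive standing, active standing, stepping) were set
once, from the stationary occupancy formula π·E[dwell], so a default day
contains roughly 43% inactive sitting, 2 h active sitting, 1.4 h quiet
standing and ~7000 steps — the descriptive profile of an office-worker
cohort. Counts are per-minute gamma draws per state (means 20 / 250 /
50 / 300 / 2500 cpm; occupancy-weighted across state boundaries) spread
over seconds; raw signals are posture-dependent gravity orientations
plus state-dependent movement noise, gait periodicity at 1.9 Hz while
stepping, and 3 mg sensor noise at 10 Hz sampling. A 3-s waist delay is
injected by default. Everything is a pure function of
(profile, days, seed).

Deliberately not emulated: biomechanical signal realism beyond what the
features consume, MET values (intensity exists only through the count
distributions), postural transitions inside events, clock drift,
device-specific count filters. Consequently, passing tests show that the
*measurement and evaluation machinery* is correct and that the training
framework recovers separable structure — they do not certify classifier
accuracy on real free-living signals.

## Problem sizes used in the checked runs

The study-scale acceptance run keeps the original cohort structure — 38
development and 62 comparison participants — with one recorded day per
participant, a 12-feature subset of catalogue Set 1, 4 screened
candidate features, a search budget of 2 and ≤ 25 training minutes per
participant. These sizes are the package's desk-scale defaults for its
own verification runs; study-scale analyses would use the full 563-
feature registry, 7-day recordings, a three-figure search budget and the
default 100-feature screen, which the same configuration object
expresses.

## Known limitations

* The bedtime heuristic is a stand-in, not a reimplementation of the
  published algorithm it replaces; on recordings whose evening sitting
  merges seamlessly into lying, it marks bedtime from the start of the
  night window and so clips some late-evening wear.
* The ensemble search approximates the original optimizer's space
  ("twoing", tree-size coupling) rather than replicating it.
* Counts-mode non-wear boundaries inherit count sparsity (see above).
* Simulated cohorts share one behaviour profile; between-participant
  variance is dwell/count sampling noise only, which narrows limits of
  agreement relative to a heterogeneous human cohort.
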