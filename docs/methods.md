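# Methods

This note documents the models, conventions, and design choices behind
`gazecourse`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where genuinely open
choices were settled.

## 1. Fixation detection (I-DT)

A fixation is a maximal window of consecutive valid samples whose dispersion
stays at or below `max_dispersion_px` (default 100 px) and that spans at
least `min_duration_ms` (default 80 ms). Conventions:

- **Dispersion metric**: `(max x − min x) + (max y − min y)`, the classic
  sum-of-ranges used by low-speed (< 200 Hz) dispersion filters. Vendor
  tools in this space do not publish their exact formula; the metric is a
  config choice, and the sum-of-ranges is the standard reading.
- **Window growth**: greedy left-to-right. From the current start the window
  expands rightward while dispersion stays within threshold (dispersion is
  monotone under expansion, so the maximal end is well defined); it is
  emitted if long enough, and scanning resumes after it. Output windows are
  therefore non-overlapping and ordered. On instances up to 300 samples the
  implementation is tested to be identical to an exhaustive brute-force
  enumeration.
- **Duration**: each sample covers one sample period Δ (median inter-sample
  interval, 8.33 ms at 120 Hz), so a window of n samples spans
  `t_last + Δ − t_first` — 60 stable samples at 120 Hz are a 500 ms
  fixation, and the 80 ms minimum requires 10 samples.
- **Track loss**: invalid samples break candidate windows (`max_gap_samples
  = 0` by default; a bridging tolerance exists but bridged samples never
  contribute to centroid or dispersion). No blink interpolation, no
  velocity-based (I-VT) detection, no smooth-pursuit handling.
- **Centroid**: mean of member samples; fixations are indexed 1-based within
  their trial.

## 2. Dynamic AOIs

Two equal rectangles (defaults 16 cm × 8.5 cm each at 35.5 px/cm → 568 ×
302 px) stacked without gap, translating with the face centre. The px-per-cm
constant is pinned from the presentation monitor's geometry (22-in 16:10
panel at 1680 × 1050 → visible width ≈ 47.4 cm); it is a documented
stand-in, exposed in `SimConfig`, because true viewing geometry varies
between labs.

Membership is half-open in x (`x_min ≤ x < x_max`). In y the shared edge
belongs to the **upper** rectangle (upper closed at its bottom edge, lower
open at its top), so the two halves partition the face region and every
sample gets exactly one of {upper, lower, none}. Coordinates are 0-based
with y increasing downward; AOI positions between trajectory timestamps are
a step function (last position at or before the sample time); a lookup
outside the trajectory's coverage is a data error.

A fixation's AOI is the majority label of its member samples; a plurality of
out-of-AOI samples gives `none`; an upper/lower tie falls to the temporally
first in-AOI member sample. The majority rule and tie-break are conventions
the upstream literature delegates to vendor software; they are pinned here
and tested.

## 3. Exclusion rules

A trial enters analysis iff its summed fixation duration reaches
`min_trial_looking_ms` (default 1000 ms, inclusive: exactly 1000 ms keeps).
"Recorded looking" is counted as fixation time rather than raw valid-sample
time — the fixation stream is the analysis's unit of looking — and the
choice is configurable. Exclusion is strictly per-trial: dropping one trial
cannot change any other trial's outputs. Subjects stay in the dataset with
however many trials survive; only condition-level (ANOVA-style) analyses
require all four stimulus conditions, and subjects lacking one are flagged
ineligible rather than dropped.

## 4. Dependent variables

- **Trial level**: per-AOI sums of fixation durations; `proportion_lower =
  lower / (lower + upper)`, undefined (NaN) when the denominator is 0.
  Fixations labelled `none` count toward neither AOI.
- **Condition level**: default pooling is by duration across the condition's
  trials (`Σ lower / Σ (lower + upper)`), which is robust to unequal trial
  looking; an unweighted mean of per-trial proportions is available
  (`method="mean"`). Which of the two the upstream literature used is
  typically unstated; both are implemented and the pooled form is default.
- **Fixation level**: the long table (one row per fixation with index,
  duration, AOI, condition, covariates) is exactly the input a linear or
  logistic mixed model consumes. Fitting those models is deliberately out of
  scope — they are off-the-shelf calls in any stats package; this library's
  job is producing auditable inputs.

### Experience classification

- *Mother's race*: White (Hispanic or not) → White; Asian American alone or
  with White → Asian American; any other race, or Hispanic with no reported
  race → Other. Race sets not covered by these rules (e.g. Black + White)
  collapse to Other.
- *Diversity of face experience*: count the distinct racial groups the
  infant regularly sees — the union of the mother's group, any regular
  female caregiver's group, and the face-experience questionnaire (exposure
  to White, Asian American, and Black women; the questionnaire considers
  women only, matching the stimulus faces). The mother always contributes,
  including when her group is Other. 3 groups → high, 2 → medium, 1 → low;
  undefined without the questionnaire.
- *Language*: English > 75% of exposure → monolingual English; another
  single language > 75% → other-monolingual; otherwise multilingual; empty
  report → unreported. A single reported language at ≤ 75% is treated as
  multilingual (the remaining exposure is unspecified other languages).

## 5. Binned time courses

Bins are half-open `[k·250, (k+1)·250)` ms over the first
`analysis_window_ms` (7500 ms → exactly 30 bins of 30 samples at 120 Hz).
Per bin: `n_lower / (n_lower + n_upper)` over **all** labelled samples
(fixation-filtered and not — binning operates on the sample stream), with
`n_lower + n_upper + n_none` equal to the bin's sample count; a bin with no
in-AOI samples is missing. Aggregation is strictly two-stage available-case
averaging: trials → subject (unweighted mean of non-missing trials per bin),
subjects → group (each subject weighs equally; per-bin n and a t-based 95%
CI are reported). No imputation, no smoothing. Scopes: all trials pooled,
plus each of the four stimulus conditions; experience-group time courses are
deliberately not computed (splitting the cohort leaves too few subjects per
bin for stable per-bin tests).

## 6. Cluster-mass permutation test

Per bin, a two-sided one-sample *t* test of subject values against chance
(0.50) at `alpha_bin = .05`, using only subjects with data in that bin
(df = n − 1). Bins with fewer than `min_subjects_per_bin = 2` subjects or
zero variance are *untestable*: they are excluded from clusters and break
runs (zero-variance bins would otherwise produce infinite t). Clusters are
maximal runs of consecutive significant bins whose t statistics share a
sign (the mass of a mixed-sign run is uninterpretable; below- and
above-chance episodes are distinct findings); single-bin clusters are
allowed, and a cluster's onset/offset are the bin-grid edges (a lone
significant first bin spans 0–250 ms).

The null: on each of `n_permutations = 1000` iterations every subject's
whole deviation-from-chance time course is independently sign-flipped —
`x_ib → 0.5 + s_i (x_ib − 0.5)` — preserving within-subject autocorrelation
and each subject's missingness pattern; this is the standard exchangeable
null for a one-sample-vs-chance cluster test. Bin tests and clusters are
recomputed and the largest |mass| stored (0 when no cluster forms, keeping
the null at full length). Internally the permutation reduces to a
sign-matrix product (sign flips leave per-bin sums of squared deviations
unchanged), which is tested against exhaustive enumeration of all 2^n sign
assignments at small n.

Decision rule: the threshold is the empirical 95th percentile (order
statistic) of the null; an observed cluster is significant iff |mass|
strictly exceeds it. The p-value is the plain proportion
`#{null ≥ |mass|} / n_permutations` — reported as 0.000 when no null mass
reaches the observed — with a (+1)-corrected variant behind a flag. Two-
sided bin tests are used throughout because both below- and above-chance
episodes are substantively meaningful.

Calibration and power are part of the test suite: on null cohorts the
family-wise rate of any significant cluster sits in the 99% binomial CI of
.05 (300 cohorts × 300 permutations, 12 infants × 4 trials × 2500 ms — the
test's exactness does not depend on cohort size, so calibration is checked
at reduced scale to keep the suite fast); a +0.20 bias planted in
2000–4000 ms at the full design (30 infants × 8 trials) is recovered as an
overlapping significant cluster in ≥ 80% of cohorts, with significant
clusters almost never wholly outside the window.

## 7. The synthetic generator

The generator emulates the acquisition: 120 Hz sampling (900 samples per
7500 ms trial), up to 8 trials per infant in blocks of four (one trial per
condition per block, order shuffled, the two blocks using the two models per
face race), a face translating with slow sinusoids (default amplitude 30 px)
with the AOI pair riding on it, and per-(subject, trial) random streams
derived from the master seed so adding or removing subjects never perturbs
anyone else's data.

Gaze is alternating fixations and saccades:

- Fixation durations ~ Normal(620, 300) ms clipped at 100 ms (population
  mean near the ~600–670 ms fixations typical of infants on dynamic faces);
  the final fixation may be truncated by the trial end and is flagged when
  it falls under the detector's 80 ms minimum.
- Each fixation targets the lower AOI with the bias profile's probability
  for that condition and onset time; the centroid is drawn uniformly inside
  the target rectangle (with margin), rejection-sampled to sit ≥ 200 px from
  the previous centroid — saccades are repositioning movements, and a
  "saccade" below the dispersion cap would not be separable by any
  dispersion filter.
- Within-fixation jitter is isotropic Normal(0, 10 px) truncated at ±2 SD,
  which bounds any fixation's dispersion at 8 SD = 80 px < 100 and so
  guarantees planted fixations are detectable.
- Saccades occupy a 40 ms gap as a ballistic arc: a brief hold at the old
  centroid (< 8 ms), one to three in-flight samples at a via-point offset
  150 px perpendicular to the path, then the new centroid. The offset
  guarantees in-flight samples are farther than the dispersion cap from both
  fixation clouds, so saccades can neither merge adjacent fixation windows
  nor split them — at 120 Hz a *linearly* interpolated saccade leaves
  approach samples 60–140 px from the next centroid, which the greedy I-DT
  window absorbs and then terminates mid-fixation. With the arc, the
  detector recovers ≥ 95% of planted fixations ≥ 120 ms with ≤ 2-sample
  boundary error on loss-free data (tested).
- Track loss is bursty: a two-state Markov chain with mean burst 200 ms and
  stationary invalid probability `trackloss_rate` (default 0.15), plus a 5%
  fraction of heavy-loss trials (rate 0.85) standing in for fussy infants.
  Independent per-sample loss at realistic rates would fragment every
  fixation below the 80 ms minimum; with bursts the synthetic cohort lands
  in the observed regime of this paradigm (mean trial looking ≈ 6100 ms,
  ~4–5% of trials excluded by the 1000 ms rule). `trackloss_rate = 0`
  yields all-valid samples regardless.
- Covariates: age uniform on 217–320 days; mother's race, diversity, and
  language groups drawn with the cohort frequencies typical of this
  population (≈ 49/22/29% White/Asian American/Other mothers; 32/40/19%
  low/medium/high diversity with 9% questionnaires missing; 67/23/6/3%
  monolingual-English/multilingual/other/unreported), together with raw
  parental reports generated to be consistent with each label so the
  classification rules can be validated against ground truth.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: calibration error and drift, head movement
beyond planar face translation, smooth pursuit of the moving face (synthetic
gaze is screen-fixed within a fixation), saccade main-sequence kinematics,
anticipatory or stimulus-driven gaze dynamics beyond the planted bias
profile, and any dependence of track loss on gaze position. Results about
detector/oracle agreement, calibration of the permutation test, and pipeline
plumbing transfer to real data; results about *recovery rates* (e.g. the
95% round-trip figure) are statements about this generator's gaze model.

## 8. Numerical and reproducibility notes

- Default analysis sizes: the acceptance script runs the full study design
  (98 infants × 8 trials, 1000 permutations, ≈ 10 s); the test suite uses
  smaller cohorts per test, chosen so each property is measured at adequate
  Monte-Carlo precision.
- All randomness flows from integer seeds through `numpy.random.Generator`
  (PCG64); per-subject/trial/stimulus streams are keyed as
  `(seed, stream_id)`. Identical config + seed ⇒ bit-identical tables.
- Proportions with empty denominators are NaN, never 0; available-case
  means propagate NaN only when all contributors are missing.
- The 95th-percentile threshold uses the inverted-CDF (order-statistic)
  quantile, so `significant` and `p ≤ .05` agree up to ties.
- Timestamps are `k · 1000 / rate` in float64; bin edges at multiples of
  250 ms are exact, so `floor(t / 250)` never misassigns grid samples.
- CSV schemas are validated on read and write with errors naming file,
  column, and row; every pipeline run writes a JSON manifest (seed, configs,
  input digests) sufficient to reproduce it byte-for-byte.
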