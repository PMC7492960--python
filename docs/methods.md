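# Methods

`neoseize` implements the evaluation computation of a two-arm, multicentre
trial of bedside decision support for neonatal seizure recognition: how well
the cot-side clinical team identifies neonates with electrographic seizures,
and individual seizure hours, when judged against a dual-expert EEG gold
standard. This note describes the models and procedures, the parameters that
matter, the numerical choices, and what the synthetic cohort generator does
and does not emulate.

## Gold standard: dual-expert consensus

Each neonate's continuous EEG is annotated independently by two expert
neurophysiologists as a list of `[start_s, end_s)` seizure intervals (an
electrographic seizure being at least 10 s of evolving, repetitive
stereotyped activity). Because inter-expert agreement on very short seizures
is poor, the gold standard keeps only periods where the two annotations
overlap by at least 30 s:

1. each annotation set is normalised (sorted, overlapping or touching
   events merged; total covered time preserved);
2. the set-intersection of the two coverages is computed as maximal
   disjoint segments;
3. segments of duration >= 30 s become *confirmed seizures*.

The confirmed-event extent is the intersection segment itself, not either
annotator's extent: the final annotation is defined as the periods during
which the two annotations overlapped, and all burden summaries are computed
from these extents. Sub-30 s overlap periods contribute nothing, even to
burden. One long event in one annotation overlapping two separate events in
the other yields two intersection segments, each tested against the 30 s
rule independently. The threshold comparison is inclusive (>= 30 s) and
exposed as `min_overlap_s`.

A *seizure neonate* has at least one confirmed seizure. A *seizure hour* is
a 60-minute bin containing positive overlap with a confirmed seizure. Bins
are anchored at recording start (bin k covers `[3600k, 3600(k+1))` seconds);
wall-clock anchoring is available through a configurable `bin_offset_s`. The
trailing partial hour is a valid bin and its burden is reported as raw
within-bin minutes without rescaling. Burden summaries per neonate: total
burden (sum of confirmed durations, minutes), maximum hourly burden
(worst-bin overlap, min/h), and median confirmed-event duration (seconds;
midpoint of the central pair for even counts; absent with no events).

Numerics: interval arithmetic is floating point with a 1 ms tolerance
(`TOL_S`): segments closer than 1 ms are touching, intersection slivers
shorter than 1 ms are discarded, and the >=30 s comparison allows 1 ms
slack. Events extending past the recording end are clipped with a warning.
Exactly two annotators are supported; a neonate with events from only one
annotator is treated as having an empty second annotation (warned), which
yields an empty consensus.

## Clinical scoring

The cot-side team completes an hourly seizure record form and may give
antiseizure medication (ASM). All rules operate at hour granularity
(sub-hour times floor to their bin):

* **Neonate-level identification** — positive iff any hour is form-marked
  or any therapeutic ASM dose is recorded. An optional per-row
  `asm_therapeutic` flag (default 1) lets users exclude maintenance doses.
* **Hour-level identification** — a gold hour H is identified iff the form
  is marked or ASM given in H, or in H+1 when H+1 exists (no padding past
  the record); the hour-after window absorbs charting delay.
* **False detection** — a form-marked hour with no confirmed seizure in
  that hour or the hour before (the hour-before clause is skipped at H=0).
  The false-detection denominator is form-marked hours only:
  medication-only events enter identification but not this denominator. A
  medication in H+1 does not rescue a form false detection at H.
* **Inappropriate ASM** — a dose at hour H with no confirmed seizure in H
  or H-1 (H-1 skipped at H=0); the hour-before window allows preparation
  time.

Missing hour rows are treated as blank with a logged warning; record forms
are known to be incomplete in practice, which the medication rule partly
compensates.

For the post-hoc breakdowns, each hour bin is classified by the wall clock
at its start: weekday (Mon-Fri) vs weekend, and day shift (08:00-20:00) vs
night shift (20:00-08:00). This requires a per-neonate recording-start
timestamp.

## Accuracy statistics

Neonate-level sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp),
false detection rate = 100·fp/(fp+tp); hour-level sensitivity and the form
false-detection rate are ratios of pooled counts. A zero denominator
returns an explicit `None` (undefined) rather than NaN. All percentages are
kept at full precision internally and rounded half-up to one decimal only
at the reporting layer.

**Cluster-stratified BC bootstrap.** Neonates are divided into clusters by
(randomisation group, hospital) — 16 clusters in the emulated design. Each
iteration resamples every cluster's neonates with replacement, preserving
cluster sizes, pools the resample and recomputes the statistic (or the
between-group difference, resampling both groups jointly). The interval is
bias-corrected (BC, not BCa: no acceleration constant, matching the stated
method): with point estimate t from the original data and B replicates,
z0 = Phi^-1(b/B) with b counting replicates strictly below t plus half of
ties (tie-splitting prevents z0 = ±inf on discrete statistics); b/B is
clamped to [1/(B+1), B/(B+1)] with a warning; endpoints are the
bootstrap-distribution quantiles (numpy linear interpolation) at
Phi(2·z0 + z_{alpha/2}) and Phi(2·z0 + z_{1-alpha/2}). Replicates on which
the statistic is undefined (e.g. a resample with no seizure neonates) are
dropped and counted. With z0 = 0 the interval reduces to the percentile
interval. The default is 100 000 iterations (`BootstrapConfig`); the
pipeline report and the test suite use 2 000-10 000, where BC endpoints
have long stabilised. An `exhaustive=True` mode enumerates every equally
likely resample for toy cohorts, used for validation.

**Interaction test.** The post-hoc weekday/weekend and shift contrasts fit
logit P(identified) = b0 + b1·group + b2·period + b3·group×period on one
row per gold seizure hour (statsmodels `Logit`, Newton/IRLS) and report the
Wald p-value for b3 — Wald rather than likelihood-ratio, the common default
of the era's software. Hours are treated as independent observations; the
result carries an explicit caveat that within-infant clustering of hours is
not adjusted for in this fit (the bootstrap, not the interaction model,
handles clustering in the primary analyses). Separation or non-convergence
is reported through `converged=False`, never raised.

**Sample size.** `required_seizure_neonates(delta, sd, power, alpha)` is
the standard two-sample normal approximation
n = 2(z_{1-a/2}+z_{1-b})²·sd²/delta² per group, rounded up. With delta = 25
percentage points, SD = 35, 80% power and two-sided 5% it gives 31 per
group; trial reports of this design have printed 33 for the same inputs,
so the exact routine used there evidently differed (perhaps a t-based or
software-specific correction) — the package reports the formula value and
documents the gap rather than asserting the printed figure.
`required_group_size(n_seizure, prevalence)` = ceil(n_seizure/prevalence)
converts the seizure-neonate requirement into monitored neonates per group:
83 at 40% expected prevalence, 132 at 25%.

## Synthetic cohort generator

Clinical EEG datasets of this kind cannot be shared, so the generator
produces complete synthetic cohorts with the same structure, and its
defaults are fixed study conditions chosen once to match the published
marginals of this design:

* **Design** — 130 neonates per arm, block-randomised (blocks of 2 or 4)
  within 8 hospitals; every group×hospital cluster populated. Seizure
  prevalence 25% (algorithm arm) / 29% (non-algorithm arm).
* **Recordings** — log-normal duration, median 50 h, sigma 0.6, clipped to
  [2, 100] h; random start timestamps over a two-year window (uniform over
  days and hours, so weekday/weekend and shift strata are all populated).
* **Seizures** — bout-structured trains: bout starts are a homogeneous
  Poisson process (0.09 bouts/h scaled by a per-neonate log-normal severity
  multiplier, sigma 0.8, so low-burden neonates exist and can plausibly be
  missed); each bout holds 1 + Geometric(mean 5) seizures separated by
  exponential 300 s gaps; event durations log-normal with median 105 s,
  sigma 0.7, floored at the 10 s seizure definition. Overlapping events are
  merged and everything is truncated at the recording end. Under defaults
  this yields a median total burden of roughly 35-45 min, median event
  duration ~110 s, and ~7-9 gold hours per seizure neonate.
* **Annotators** — each expert independently jitters boundaries (Gaussian,
  sd 5 s), misses events shorter than 60 s with probability 0.3, and adds
  spurious 10-25 s events at 0.1/h. Spurious events almost never survive
  consensus (independent short events rarely overlap 30 s); jitter
  occasionally pushes 30-60 s events below the window, exercising the
  confirmation rule.
* **Clinical detection** — in an hour with true burden b min the form is
  marked with probability expit(intercept + 0.9·log b), plus a weekend
  log-odds offset (0 algorithm, -0.4 non-algorithm: seizures are less
  likely to be recognised at weekends without decision support). Default
  intercepts -1.5 / -2.3 target overall hour sensitivities of roughly 66%
  and 45%. False marks cluster within neonates: 13% of neonates are prone
  to suspicious non-seizure movements and their seizure-free hours are
  marked at 0.08/h; others never false-mark. ASM follows a marked hour
  with probability 0.3; after the first recognised seizure hour further
  doses arrive at 0.01/h (maintenance dosing, the main source of
  inappropriate administrations in seizure neonates); a 0.001/h background
  rate produces sporadic doses in any neonate.

Ground truth (true events, per-hour burden, latent mark probabilities) is
emitted alongside the data and never consumed by the pipeline.

**Planting a group effect.** `plant_group_effect(config, sens_a, sens_b)`
returns a configuration in which each arm's *expected* hour-level
sensitivity equals a target. It first strips the nuisance channels — ideal
annotators, no false marks, no maintenance/background ASM, no weekend
offset — so the target refers to the burden-dependent detection channel
alone and is well defined; it then finds each arm's intercept by bisection
(scipy `brentq`, xtol 1e-4) against a Monte-Carlo evaluation of the
generator's own burden process: 3000 simulated seizure neonates' event
trains and per-hour uniforms are drawn once (fixed internal seed), making
the sensitivity-vs-intercept map deterministic and monotone, including the
hour-after rescue effect between consecutive gold hours. Unreachable
targets raise a calibration error.

**What the generator does not emulate.** Real EEG waveforms, detector
probability traces and alarms, artefact periods and paused recordings,
drug type or dose, diagnosis-specific seizure phenotypes, and any
correlation between hospital and case mix or annotator behaviour. The
published design reports only marginal burden summaries and a binned
detection-vs-burden curve, so the temporal law (Poisson bouts) and the
joint burden-detection distribution are modelling choices, exposed in
`CohortConfig`. Passing tests therefore demonstrate that the evaluation
machinery is correct and well calibrated under a realistic data-generating
process of this shape — not that any particular clinical dataset would
yield the same numbers.

## Pipeline and reporting

`run_pipeline` executes consensus → scoring → statistics and produces three
tidy tables (neonate-level accuracy with confusion counts; hour-level
sensitivity overall and per stratum, with difference CIs; burden medians
and inappropriate-ASM proportions) plus metadata (config hash, seed,
version). Percentages are rounded half-up to one decimal in the tables;
medians are reported unrounded. Stratified tables are produced only when
every neonate has a start timestamp. CSV I/O is comma-separated UTF-8 with
a header row, '.' decimal and ISO-8601 timestamps. Runs are deterministic:
the same inputs, seed and configuration produce byte-identical outputs.

## Test problem sizes

The suite verifies interval algebra and hour rules against brute-force
per-second and exhaustive enumeration oracles; bootstrap correctness
against an exact 27-resample enumeration and a percentile-bootstrap limit;
interval coverage on 100 planted trials at 2 000 iterations (the planted
21 pp difference should be covered by ~95 of 100 intervals); planted-effect
recovery over 50 seeds; and Wald p-value uniformity under the null over
1 000 replicates of 10 000 hours. These sizes were chosen so the full suite
completes in a few minutes while leaving each check statistically sharp.

## Known limitations

* Exactly two annotators; no kappa-style agreement statistics beyond the
  consensus rule.
* The interaction fit ignores within-infant clustering (flagged in its
  output); GEE/mixed-model alternatives are out of scope.
* No multiplicity adjustment (none is applied in the emulated design).
* Hour-level rules cannot represent sub-hour medication timing or paused
  EEG periods.
* The BC (not BCa) interval can undercover for strongly skewed statistics
  with few clusters; the coverage test quantifies this for the planted
  design.
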