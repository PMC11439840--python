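# Methods

This note documents the generative model behind the synthetic cohorts, the
event-detection algorithm, the definitions of the derived measures, the
statistical conventions, and the places where the design was genuinely
open and a choice had to be made.

## Task model and trial designs

Four identities (A–D) map one-to-one onto four distinctive facial features
(forehead, chin, ears, nose). A trial shows a name prior in one of the four
screen corners (750 ms) and then a face that matches the prior, mismatches
it, or is a 50/50 morph of the expected and one unexpected identity.

* Short-presentation design: 3 blocks x 144 trials, 48 per condition per
  block; prior -> face-outline interval (1000 ms) -> face (100 ms) ->
  response window (1500 ms).
* Free-viewing design: 4 blocks x 72 trials. The phrase "72 trials per
  block" is read as 72 *total* per block (24 per condition), by parallel
  with the short design's explicit "48 per condition"; the alternative
  reading (72 x 3 conditions) would triple the session length.

Design invariants enforced by construction and by test: exact condition
counts per block; each prior appears equally often in each corner per
participant; no prior name more than twice in a row (also across block
boundaries); every morph contains the prior identity; the 12 prior-by-morph
combinations are balanced. For a fixed ROI the expected:unexpected trial
ratio is therefore exactly 1:3.

One known timing ambiguity: the outline interval is specified as 1000 ms in
the procedure but the trial-exclusion rule mentions a 750-ms window. The
simulator uses 1000 ms; the data-loss rule defaults to the full simulated
interval, with `ExclusionRules.isi_loss_window_ms` available to restrict it
to the first 750 ms. At the default artifact rates the decision changes
almost nothing (loss is uniform over the interval).

## Behavioural generator

Choices are Bernoulli draws: `p_correct_match`, `p_correct_mismatch`
control accuracy (for the free-viewing design mismatch correctness is the
*joint* event "unexpected" + right name, matching the scoring rule, so a
pure guesser scores 0.5 x 0.25 = 12.5% there); `assimilation_q` is the
probability of an expectation-compliant identity report on morph trials and
maps to a perceived-face-identity index of exactly `100 q` in expectation.
Misses occur with `miss_rate` or when the drawn RT exceeds the response
window.

RTs are log-normal (positive support, right skew typical of RT data),
parameterised by the target mean and SD per condition. Defaults anchor to
the observed group means of each design (short: 670/720/751 ms for
match/mismatch/partial, SD 100; free-viewing: 1439/1761/2207 ms, SD 300);
accuracies default to 0.86/0.84 and 0.98/0.88, `assimilation_q` to 0.58 and
0.62. These are the package's standard operating points, not fitted values.

## Gaze generator

One sample per millisecond (1000 Hz). The eye rests at a screen-centre
point at trial start, saccades to the prior corner (~130–230 ms), and then:

* short design — two anticipatory saccades during the outline interval.
  The first launches 150–350 ms after outline onset (always satisfying the
  100-ms latency criterion) and targets the expected ROI with probability
  `p_sacc1_expected`, otherwise a uniformly random other ROI; the second
  follows after one fixation duration with probability `p_sacc2_expected`.
  Scanning then continues through the face and response periods.
* free-viewing design — the first face-directed movement goes to the face
  centre with probability `p_center_first` (the central-viewing tendency;
  the centre region lies outside all feature ROIs), after which the four
  ROIs are visited in an order whose first two feature targets carry the
  same expectation bias; remaining ROIs follow in random order, then
  scanning continues uniformly. Presentation ends at the response.

Saccades use a minimum-jerk position profile; nothing downstream depends on
the waveform beyond its velocity profile. Durations follow a main-sequence
law `D = 21 ms + 2.2 ms/deg x A`, so the implied peak velocity
`1.875 A / D` is strictly increasing and saturating in amplitude —
numerically close to textbook human values (e.g. ~470 deg/s at 15 deg).
Fixation durations are normal (mean 250 ms, SD 50, floor 80 ms). Gaze
targets get 15-px Gaussian scatter, clipped inside the target region; a
re-fixation of the currently fixated region keeps a >= 60 px separation so
that every ground-truth saccade is a detectable movement (a smaller jump
would be drift, which the generator does not model). Measurement noise is
0.5 px per sample (~0.013 deg, the precision class of a tower-mounted
research tracker).

Artifacts: blinks arrive as a Poisson process (default 0.1/s, ~150 ms
closures); tracking loss is injected as short (~20 ms) invalid spans up to
a target fraction (default 1%). Both only flag samples invalid — the
latent trajectory underneath is unchanged, which is what makes
blink-obscured saccades *honestly* undetectable in the validation below.

What the generator does not emulate: drift and microsaccades, saccadic
undershoot/overshoot with corrective saccades, pupil-size artifacts around
blinks, smooth pursuit, head motion, or any coupling between gaze path and
the eventual button response (choices and gaze are conditionally
independent given the trial). Passing recovery tests therefore shows the
*pipeline* is unbiased under clean assumptions, not that real data would
behave this way.

## Event detection

Angular position is obtained per axis as `atan((px - centre) * mm_per_px /
distance)`. Velocity uses the five-sample symmetric difference
`v[t] = (x[t+2] + x[t+1] - x[t-1] - x[t-2]) / (6 dt)` (strong noise
suppression at 1000 Hz); acceleration applies the same operator to the
speed trace. Any window touching an invalid sample is invalid.

Classification rules, in order:

1. blink = maximal invalid run >= 50 ms, padded by 10 ms each side;
2. saccade candidates = samples with `v > 30 deg/s` OR `|a| > 8000
   deg/s^2` (outside blinks); candidate runs are extended outward while
   `v >= 10 deg/s` — the hard velocity crossing happens a few ms after
   motion onset, and the extension brings detected onsets within ~2
   samples of the true movement start; runs separated by <= 30 ms (lost
   samples mid-flight) are bridged;
3. runs whose endpoint-to-endpoint displacement is below the 0.1-deg
   motion threshold, or shorter than 4 ms, are discarded as jitter;
4. fixations fill every remaining gap; the three kinds exactly tile the
   trial (partition invariant, asserted on every simulated trial).

All secondary constants (extension threshold, merge gap, blink run length
and padding, debounce) are `DetectionParams` fields. Validation against
generator ground truth: >= 95% of true saccades are detected with onset
error <= 2 samples at the default artifact rates; the residual misses are
saccades overlapped by blinks or loss, which no detector could recover.

## Derived measures

* ROI classes per trial: *expected* = the prior's feature; *unexpected* =
  the other morph member's feature (partial) or the shown identity's
  feature (mismatch); undefined for match trials; *others* = the rest.
* Predictive-saccade table: per ROI and saccade index (first/second
  qualifying saccade in the outline window, >= 100 ms latency), landing
  rates are computed separately over expected-trials and
  unexpected-trials and then averaged across the four ROIs. Denominators
  count trials contributing a qualifying saccade at that index (a trial
  with only one qualifying saccade contributes to "first" only).
* Fixation order: feature ROIs ranked by first-fixation onset during face
  presentation; unfixated ROIs get the remaining ordinals uniformly at
  random (single fill by default; the fill RNG is seedable and analyses
  can average replicate fills).
* Count/dwell proportions: fixations are assigned by centroid; dwell is
  event overlap with the presentation window (shortened by the response),
  divided by presentation duration. Multi-ROI classes report the per-ROI
  mean. 500-ms bins split dwell at bin boundaries; bins not fully covered
  by the presentation are missing.
* Perceived-face-identity index: per prior-by-morph combination,
  (compliant − noncompliant) / attributed trials, averaged over the 12
  combinations, then mapped by `(score + 1) / 2 x 100`. The source
  formulation ("divided by the number of possible combinations, N = 12")
  is ambiguous between pooled and per-combination normalisation; the
  per-combination form is used because it keeps the index invariant to
  unequal trial loss across combinations, and both agree under balance.
  Off-morph identity reports count as neither compliant nor noncompliant.
* Linkage: the fixation whose interval contains face onset defines the
  onset ROI (a saccade in flight counts as no ROI); the last-sampling
  measure takes the final feature-ROI fixation before the response.

## Statistics

* Repeated-measures ANOVA (one and two within-subject factors) from sums
  of squares on per-subject cell means; Greenhouse–Geisser epsilon from
  orthonormal within-factor contrasts, clamped to `[1/(k-1), 1]`;
  generalized eta^2 per the Olejnik–Algina convention (subject variance
  and all error strata in the denominator) and partial eta^2. The
  corrected p is the headline value; the uncorrected one is kept in
  `extra`. (The df correction is conservative in the rejection region;
  for F << 1 it can lower p, which is why the monotonicity property is
  only asserted where p < 0.05.)
* Wilcoxon signed-rank: exact null for n <= 25 without ties, otherwise
  normal approximation with continuity and tie correction; the effect
  size r = |z| / sqrt(n) always comes from the (always computed)
  approximation, matching common reporting practice.
* Clustered goodness-of-fit: per-cluster category proportions, equal
  cluster weights (robust to informative cluster size), Wald statistic
  with the empirical between-cluster covariance (reported as chi^2 with
  df = k−1). With a few dozen clusters a chi-square reference is
  anticonservative (measured type-I error ~8% at 34 clusters), so the
  p-value uses the Hotelling T-squared F reference, which restores the
  nominal 5% size. Cramér's V uses the total observation count, not the
  cluster count — the only convention consistent with reported values of
  V ~ 0.03 alongside chi^2 ~ 27 at 34 participants.
* Clustered proportion test: estimate = unweighted mean of cluster
  proportions, SE from the between-cluster variance, referred to
  t(m−1) — with size-one clusters this *is* the one-sample t-test on
  indicators. Effect size: per-cluster Cohen's h against the null
  proportion, averaged.
* Bonferroni corrections multiply p by the family size and cap at 1.

Calibration, verified by simulation in the test suite: both clustered
tests hold type-I error within [3.5%, 6.5%] at nominal 5% over 2000 null
cohorts (34 clusters x 200 observations; the proportion test also under a
beta-binomial cluster model with within-cluster correlation 0.1, where its
95% CI covers the truth 93–97% of the time).

## Exclusion rules

Trial level, in order: prior not fixated (no fixation centroid inside the
prior's corner region during the 750-ms prior); no response; short design —
more than 30% invalid samples during the outline interval; free-viewing
design — less than 50% of the face presentation covered by fixation
events. Participant level: more than 30% invalid trials, or match/mismatch
accuracy at or below the 50% chance level (used conservatively for the
free-viewing design, whose strict mismatch chance is 12.5%). The
prior-fixation region defaults to a corner rectangle of 30% of the screen
per side; its exact extent is a config choice, not a printed constant.

## Problem sizes used in the validation suite

Cohort-scale checks run at the full design (34 participants, 432 or 288
trials each): parameter recovery uses three short-design cohorts at
planted first-saccade biases {0.25, 0.5, 0.9} (recovered within +/- 3
percentage points) and three behavioural cohorts at assimilation
probabilities {0.25, 0.5, 0.75}; the detection oracle runs on a ~1000-trial
mixed set; statistical calibration uses 2000 simulated null cohorts per
test. These sizes make the whole suite run in minutes on a single core
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The gaze generator is a scripted scan-path model, not a fitted model of
  human exploration; it contains no bottom-up salience and no
  gaze–response coupling, so linkage metrics are validated only under the
  null.
* Non-1000-Hz sampling rates are not generated (the detector itself only
  assumes a uniform 1-ms grid).
* ROI placements are proportional defaults over the face box; analyses are
  placement-independent but absolute landing rates naturally depend on ROI
  geometry.
* The printed stimulus angle of 27.44 deg is not exactly reproduced by
  either the arctangent or the small-angle formula from the stated
  geometry; the arctangent form is used and agrees to within 0.1 deg.
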