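# gazexpect

Expectation-guided face-viewing analysis: a tested, reusable pipeline from
raw 1000-Hz gaze samples to saccade/fixation events, region-of-interest
(ROI) expectation metrics, behavioural scores and the accompanying
statistical battery — together with a synthetic-data generator that plants
known ground truth, so every stage can be validated end to end without any
recorded data.

## The scientific problem

When we anticipate *whose* face we are about to see, do our eyes move
ahead of time toward the facial feature that would identify that person?
The package models a cued face-recognition paradigm: a name prior announces
one of four learned identities, each distinguished by a single feature
(forehead, chin, ears, nose). The face that follows either matches the
prior, mismatches it, or is a 50/50 morph containing the expected and one
unexpected identity (*match* / *mismatch* / *partial*). Two designs are
supported:

* a **short-presentation** design (3 blocks x 144 trials, 48 per
  condition): the face appears for only 100 ms after a face-outline
  interval, so informative eye movements must be *predictive* — the first
  two saccades during the outline interval (latency >= 100 ms) are scored
  by whether they land in the expected feature ROI;
* a **free-viewing** design (4 blocks x 72 trials): the face stays up to
  4500 ms or until the response, and expectation effects appear in the
  *order* of first fixations on the four ROIs, the proportion of fixations
  and dwell time per ROI, and their 500-ms time course.

Core quantities:

* **predictive-saccade table** — for each ROI, the relative frequency of
  first (second) saccades landing in it, computed separately over trials
  where its feature was expected vs. not (the trial sets differ 1:3), then
  averaged over ROIs: a 2 x 2 saccade-by-expectation table per participant;
* **perceived-face-identity (assimilation) index** — per prior-by-morph
  combination (12 in total), (compliant − noncompliant) identity reports /
  trials, averaged and mapped linearly to 0–100% (50% = no prior effect);
* **event detection** — saccades are intervals where angular velocity
  exceeds 30°/s *or* acceleration exceeds 8000°/s², with a 0.1° motion
  threshold; blinks are long invalid runs; fixations fill the rest, and the
  three event kinds exactly tile each trial;
* **clustered statistics** — subject-level χ² goodness-of-fit and marginal
  proportion tests that treat the participant as the sampling unit
  (unweighted cluster means, between-cluster variance), with Cramér's V and
  mean Cohen's h effect sizes; repeated-measures ANOVA with
  Greenhouse–Geisser correction and generalized/partial η²; paired t and
  Wilcoxon signed-rank tests with Cohen's d and Wilcoxon's r.

## Worked example

```python
import gazexpect as gx
from gazexpect.pipeline import run_synthetic_experiment, participant_metrics

rois = gx.build_default_roiset()          # 1600x1200 screen, centred face
detection = gx.DetectionParams()          # 30 deg/s, 8000 deg/s^2, 0.1 deg

# simulate a 4-participant short-presentation cohort in which half of the
# first anticipatory saccades target the expected feature
gaze = gx.GazeSimParams(p_sacc1_expected=0.5, p_sacc2_expected=0.5)
bundle = run_synthetic_experiment("exp1", 4, seed=11, rois=rois,
                                  gaze=gaze, detection=detection)
m = participant_metrics(bundle, rois, detection)
cols = ["sacc_first_expected", "sacc_first_unexpected", "assimilation_index"]
print(m[cols].mean().round(2))
```

Output:

```
sacc_first_expected      49.62
sacc_first_unexpected    16.54
assimilation_index       57.11
dtype: float64
```

Reading: about 50% of first anticipatory saccades landed in an ROI when its
feature was expected (recovering the planted 50% bias), versus about 17%
when it was not (the bias spills over because second saccades were also
half-directed at the expected feature), and morphs were reported as the
expected identity at a rate mapping to an index of ~57% (the generator's
default assimilation probability is 0.58; 50% would mean no prior effect).

A command-line interface mirrors the stages:

```bash
gazexpect simulate --experiment exp1 --participants 4 --seed 11 --out sim/
gazexpect detect   --samples sim/samples.tsv --out sim/events.tsv
gazexpect analyze  --experiment exp2 --participants 4 --seed 11 --out results/
gazexpect report   --metrics results/metrics.tsv
```

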