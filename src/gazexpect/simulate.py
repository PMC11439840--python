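"""Synthetic experiment designs, behavioural responses and raw gaze traces.

Everything downstream (event detection, exclusion rules, ROI metrics,
statistics) is exercised against data produced here with known ground-truth
parameters, so each generator exposes the effect sizes it plants:

* ``generate_design`` builds the full per-participant trial table for either
  experiment — a short-presentation design (three blocks of 144 trials,
  48 per condition) and a free-viewing design (four blocks of 72 trials,
  24 per condition), with pseudo-randomised prior order (no name cue more
  than twice in a row) and exact prior-by-corner counterbalancing;
* ``simulate_behavior`` draws choices and log-normal reaction times whose
  condition means, accuracies and morph-assimilation probability are direct
  parameters;
* ``simulate_gaze`` emits a 1000-Hz monocular sample stream per trial:
  stable fixations with Gaussian jitter, minimum-jerk saccades whose
  durations follow a main-sequence law, expectation-biased saccade targets,
  and a ground-truth event list for validating the detector;
* ``inject_artifacts`` overlays blinks and tracking loss so the exclusion
  rules have something to exclude.

Randomness: every public generator takes an explicit integer seed; internal
streams are derived from ``(seed, participant, purpose[, trial])`` so any
single trial can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import FEATURE_LABELS, CORNER_LABELS, ROISet, ScreenGeometry, \
    build_default_roiset

__all__ = [
    "IDENTITIES",
    "IDENTITY_FEATURE",
    "EXPERIMENTS",
    "ExperimentSpec",
    "BehaviorParams",
    "GazeSimParams",
    "generate_design",
    "score_response",
    "simulate_behavior",
    "simulate_gaze",
    "inject_artifacts",
    "simulate_cohort",
    "derive_rng",
    "gaze_angle_deg",
]

#: The four learned identities; each owns one distinctive facial feature.
IDENTITIES = ("A", "B", "C", "D")
IDENTITY_FEATURE = dict(zip(IDENTITIES, FEATURE_LABELS))
FEATURE_IDENTITY = {v: k for k, v in IDENTITY_FEATURE.items()}

CONDITIONS = ("match", "mismatch", "partial")


@dataclass(frozen=True)
class ExperimentSpec:
    """Static design constants of one experiment."""

    experiment_id: str
    n_blocks: int
    trials_per_block: int
    per_condition: int          # per block
    prior_ms: int = 750
    isi_ms: int = 0             # face-outline interval (first experiment only)
    face_ms: int | None = None  # fixed face duration; None = response-terminated
    response_ms: int = 1500     # response window from face onset
    max_face_ms: int = 4500     # cap for response-terminated presentation

    @property
    def per_prior_per_block(self) -> int:
        return self.trials_per_block // len(IDENTITIES)


EXPERIMENTS = {
    "exp1": ExperimentSpec("exp1", n_blocks=3, trials_per_block=144,
                           per_condition=48, isi_ms=1000, face_ms=100,
                           response_ms=1500),
    "exp2": ExperimentSpec("exp2", n_blocks=4, trials_per_block=72,
                           per_condition=24, face_ms=None, max_face_ms=4500),
}


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for ``(seed, *keys)``.

    String keys are hashed with CRC-32 so the scheme is stable across runs
    and platforms.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def _morph_partners(prior: str) -> list[str]:
    return [i for i in IDENTITIES if i != prior]


def _order_without_triples(labels: list[str], rng: np.random.Generator,
                           prefix: tuple = (), max_iter: int = 10_000):
    """Random order of ``labels`` with no label three times in a row.

    ``prefix`` holds the trailing labels of the preceding block so runs
    cannot continue across block boundaries.
    """
    arr = np.asarray(list(prefix) + list(labels), dtype=object)
    npre = len(prefix)
    order = np.concatenate([np.arange(npre), npre + rng.permutation(len(labels))])
    arr = arr[order]
    for _ in range(max_iter):
        bad = [i for i in range(max(2, npre), len(arr))
               if arr[i] == arr[i - 1] == arr[i - 2]]
        if not bad:
            return arr[npre:], order[npre:] - npre
        for i in bad:
            # swap the third repeat with a random position that breaks the
            # run without creating a new one
            for j in npre + rng.permutation(len(arr) - npre):
                if arr[j] == arr[i]:
                    continue
                arr[i], arr[j] = arr[j], arr[i]
                order[i], order[j] = order[j], order[i]
                ok_i = not (i >= 2 and arr[i] == arr[i - 1] == arr[i - 2])
                ok_j = all(
                    not (k >= 2 and arr[k] == arr[k - 1] == arr[k - 2])
                    for k in range(max(j, 2), min(j + 3, len(arr)))
                )
                if ok_i and ok_j:
                    break
                arr[i], arr[j] = arr[j], arr[i]   # revert
                order[i], order[j] = order[j], order[i]
        # loop re-checks from scratch
    raise RuntimeError("could not pseudo-randomise trial order")


def generate_design(experiment_id: str, participant_id: str, seed: int) -> pd.DataFrame:
    """Generate the full per-participant trial table.

    Returns a data frame with one row per trial and columns::

        experiment, participant, block, trial_index, trial_uid,
        prior_identity, prior_feature, prior_corner, condition,
        stimulus, morph_other,
        prior_on, prior_off, isi_on, isi_off, face_on, face_off, trial_end

    Timings are in ms from trial onset; ``face_off``/``trial_end`` for the
    free-viewing experiment assume the maximal presentation and are
    shortened at simulation time by the response.

    Invariants: exact condition counts per block, balanced prior x corner
    assignment per participant, balanced prior x morph combinations, and no
    prior name more than twice consecutively.
    """
    if experiment_id not in EXPERIMENTS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}; "
                         f"expected one of {sorted(EXPERIMENTS)}")
    spec = EXPERIMENTS[experiment_id]
    n_cond_per_prior = spec.per_condition // len(IDENTITIES)

    rows = []
    tail: tuple = ()
    for block in range(1, spec.n_blocks + 1):
        rng = derive_rng(seed, participant_id, "design", block)
        block_rows = []
        for prior in IDENTITIES:
            partners = _morph_partners(prior)
            per_partner = n_cond_per_prior // len(partners)
            for cond in CONDITIONS:
                if cond == "match":
                    stims = [(prior, "")] * n_cond_per_prior
                elif cond == "mismatch":
                    stims = [(p, p) for p in partners for _ in range(per_partner)]
                else:  # partial: unordered morph always contains the prior
                    stims = [("+".join(sorted((prior, p))), p)
                             for p in partners for _ in range(per_partner)]
                for stim, other in stims:
                    block_rows.append({
                        "prior_identity": prior,
                        "condition": cond,
                        "stimulus": stim,
                        "morph_other": other,
                    })
        priors = [r["prior_identity"] for r in block_rows]
        ordered, order = _order_without_triples(priors, rng, prefix=tail)
        tail = tuple(ordered[-2:])
        block_rows = [block_rows[i] for i in order]
        for idx, r in enumerate(block_rows, start=1):
            r["block"] = block
            r["trial_index"] = idx
        rows.extend(block_rows)

    # corner counterbalancing: per prior, exact equal counts over the whole
    # session (total per prior is always divisible by 4)
    rng_c = derive_rng(seed, participant_id, "corners")
    by_prior: dict[str, list[int]] = {p: [] for p in IDENTITIES}
    for i, r in enumerate(rows):
        by_prior[r["prior_identity"]].append(i)
    for prior, idxs in by_prior.items():
        n = len(idxs)
        assert n % len(CORNER_LABELS) == 0
        corners = np.repeat(CORNER_LABELS, n // len(CORNER_LABELS))
        corners = rng_c.permutation(corners)
        for i, c in zip(idxs, corners):
            rows[i]["prior_corner"] = c

    df = pd.DataFrame(rows)
    df["experiment"] = experiment_id
    df["participant"] = participant_id
    df["prior_feature"] = df["prior_identity"].map(IDENTITY_FEATURE)
    df["trial_uid"] = (df["block"] - 1) * spec.trials_per_block + df["trial_index"]

    # phase timings (ms from trial onset)
    df["prior_on"] = 0
    df["prior_off"] = spec.prior_ms
    if spec.isi_ms:
        df["isi_on"] = spec.prior_ms
        df["isi_off"] = spec.prior_ms + spec.isi_ms
    else:
        df["isi_on"] = np.nan
        df["isi_off"] = np.nan
    face_on = spec.prior_ms + spec.isi_ms
    df["face_on"] = face_on
    if spec.face_ms is not None:
        df["face_off"] = face_on + spec.face_ms
        df["trial_end"] = face_on + spec.response_ms
    else:
        df["face_off"] = face_on + spec.max_face_ms
        df["trial_end"] = face_on + spec.max_face_ms

    cols = ["experiment", "participant", "block", "trial_index", "trial_uid",
            "prior_identity", "prior_feature", "prior_corner", "condition",
            "stimulus", "morph_other", "prior_on", "prior_off", "isi_on",
            "isi_off", "face_on", "face_off", "trial_end"]
    return df[cols]


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Generative parameters of the button responses.

    ``rt_mean_per_condition`` are the target means of log-normal RT
    distributions (ms from face onset); ``assimilation_q`` is the
    probability of an expectation-compliant identity report on morph trials,
    so the perceived-face-identity index recovers ``100 * q``.
    """

    rt_mean_per_condition: dict = field(default_factory=lambda: {
        "match": 670.0, "mismatch": 720.0, "partial": 751.0})
    rt_sd: float = 100.0
    p_correct_match: float = 0.86
    p_correct_mismatch: float = 0.84
    assimilation_q: float = 0.58
    miss_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_correct_match", "p_correct_mismatch",
                     "assimilation_q", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"BehaviorParams.{name} must be in [0, 1], got {v}")
        if self.rt_sd <= 0:
            raise ValueError("BehaviorParams.rt_sd must be > 0")

    @classmethod
    def typical(cls, experiment_id: str) -> "BehaviorParams":
        """Defaults matching the observed group means of each experiment."""
        if experiment_id == "exp1":
            return cls()
        return cls(
            rt_mean_per_condition={"match": 1439.0, "mismatch": 1761.0,
                                   "partial": 2207.0},
            rt_sd=300.0, p_correct_match=0.98, p_correct_mismatch=0.88,
            assimilation_q=0.62, miss_rate=0.01,
        )


def score_response(trial: pd.Series, choice: str, identity_choice: str = "") -> bool:
    """Correctness of a response under each experiment's scoring rule.

    Match trials: "expected" is correct; in the free-viewing design an
    "unexpected" answer followed by the right name is also accepted.
    Mismatch trials: "unexpected" is correct; the free-viewing design
    additionally requires naming the shown identity (so pure guessing
    succeeds with probability 0.5 * 0.25 = 12.5%).  Morph (partial) trials:
    any response counts as correct.  Misses are never correct.
    """
    if choice == "none":
        return False
    cond = trial["condition"]
    exp2 = EXPERIMENTS[trial["experiment"]].face_ms is None
    if cond == "match":
        if choice == "expected":
            return True
        return exp2 and identity_choice == trial["stimulus"]
    if cond == "mismatch":
        if choice != "unexpected":
            return False
        return identity_choice == trial["stimulus"] if exp2 else True
    return True


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_behavior(design: pd.DataFrame, params: BehaviorParams, seed: int) -> pd.DataFrame:
    """Draw choices, identity attributions and RTs for every design row.

    Output columns: ``participant, block, trial_index, trial_uid, choice,
    identity_choice, rt_ms, correct``.  ``choice`` is ``expected`` /
    ``unexpected`` / ``none`` (miss); ``identity_choice`` is filled for
    free-viewing "unexpected" answers (which identity was then named).
    RTs exceeding the response window count as misses.
    """
    if design.empty:
        raise ValueError("design must be non-empty")
    out = []
    for (participant,), grp in design.groupby(["participant"], sort=False):
        rng = derive_rng(seed, participant, "behavior")
        exp = EXPERIMENTS[grp["experiment"].iloc[0]]
        n = len(grp)
        miss = rng.random(n) < params.miss_rate
        u = rng.random(n)
        rts = np.empty(n)
        for cond, mean in params.rt_mean_per_condition.items():
            m = (grp["condition"] == cond).to_numpy()
            rts[m] = _lognormal(rng, mean, params.rt_sd, int(m.sum()))
        window = exp.response_ms if exp.face_ms is not None else exp.max_face_ms
        miss |= rts > window

        for i, (_, t) in enumerate(grp.iterrows()):
            choice, identity = "none", ""
            if not miss[i]:
                cond = t["condition"]
                if cond == "match":
                    hit = u[i] < params.p_correct_match
                    choice = "expected" if hit else "unexpected"
                    if choice == "unexpected" and exp.experiment_id == "exp2":
                        identity = rng.choice(_morph_partners(t["prior_identity"]))
                elif cond == "mismatch":
                    hit = u[i] < params.p_correct_mismatch
                    if exp.experiment_id == "exp1":
                        choice = "unexpected" if hit else "expected"
                    elif hit:
                        # full correctness: "unexpected" plus the right name
                        choice, identity = "unexpected", t["stimulus"]
                    elif rng.random() < 0.5:
                        choice = "expected"
                    else:
                        choice = "unexpected"
                        wrong = [x for x in IDENTITIES if x != t["stimulus"]]
                        identity = rng.choice(wrong)
                else:
                    if u[i] < params.assimilation_q:
                        choice = "expected"
                    else:
                        choice = "unexpected"
                        if exp.experiment_id == "exp2":
                            identity = t["morph_other"]
            out.append({
                "participant": participant, "block": t["block"],
                "trial_index": t["trial_index"], "trial_uid": t["trial_uid"],
                "choice": choice, "identity_choice": identity,
                "rt_ms": np.nan if choice == "none" else float(rts[i]),
                "correct": score_response(t, choice, identity),
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

@dataclass
class GazeSimParams:
    """Knobs of the gaze generator.

    The main-sequence law is ``duration_ms = ms_duration_intercept_ms +
    ms_duration_slope * amplitude_deg`` with a minimum-jerk waveform, whose
    implied peak velocity ``1.875 * A / D`` is strictly increasing in
    amplitude.  ``noise_sd_px`` is per-sample Gaussian position jitter
    (0.5 px is about 0.013 deg at the default geometry, the precision class
    of a tower-mounted research tracker).
    """

    sampling_rate: float = 1000.0
    p_sacc1_expected: float = 0.5
    p_sacc2_expected: float = 0.5
    p_center_first: float = 0.6
    fixation_duration_mean: float = 250.0
    fixation_duration_sd: float = 50.0
    ms_duration_intercept_ms: float = 21.0
    ms_duration_slope: float = 2.2      # ms per degree
    noise_sd_px: float = 0.5
    blink_rate: float = 0.1             # events per second
    loss_rate: float = 0.01             # fraction of samples dropped
    endpoint_jitter_px: float = 15.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for name in ("p_sacc1_expected", "p_sacc2_expected", "p_center_first"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"GazeSimParams.{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.loss_rate < 1.0:
            raise ValueError("loss_rate must be in [0, 1)")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")

    def saccade_duration_ms(self, amplitude_deg: float) -> float:
        return self.ms_duration_intercept_ms + self.ms_duration_slope * amplitude_deg

    def peak_velocity(self, amplitude_deg: float) -> float:
        """Main-sequence peak velocity (deg/s) implied by the waveform."""
        d_s = self.saccade_duration_ms(amplitude_deg) / 1000.0
        return 1.875 * amplitude_deg / d_s


def gaze_angle_deg(x0, y0, x1, y1, screen: ScreenGeometry) -> float:
    """Visual angle between two screen points, arctangent form."""
    dx = (np.asarray(x1) - np.asarray(x0)) * screen.mm_per_px("x")
    dy = (np.asarray(y1) - np.asarray(y0)) * screen.mm_per_px("y")
    d = np.hypot(dx, dy)
    return np.degrees(2.0 * np.arctan2(d, 2.0 * screen.viewing_distance_mm))


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


class _Trajectory:
    """Accumulates fixation/saccade segments on the ms grid."""

    def __init__(self, n_ms: int, x0: float, y0: float,
                 params: GazeSimParams, screen: ScreenGeometry):
        self.n = n_ms
        self.x = np.full(n_ms, float(x0))
        self.y = np.full(n_ms, float(y0))
        self.t = 0            # time up to which the trace is written
        self.cx, self.cy = float(x0), float(y0)
        self.params = params
        self.screen = screen
        self.truth: list[dict] = []
        self._fix_start = 0

    def saccade_to(self, onset: int, tx: float, ty: float) -> None:
        """Hold the current fixation until ``onset``, then jump to (tx, ty)."""
        onset = int(onset)
        if onset >= self.n:
            return
        if onset < self.t:
            onset = self.t
        amp = gaze_angle_deg(self.cx, self.cy, tx, ty, self.screen)
        dur = max(4, int(round(self.params.saccade_duration_ms(amp))))
        end = min(onset + dur, self.n)
        # close the running fixation
        if onset > self._fix_start:
            self.truth.append({"kind": "fixation", "onset_ms": self._fix_start,
                               "offset_ms": onset, "x": self.cx, "y": self.cy})
        tau = (np.arange(onset, end) - onset + 1) / dur
        s = _minjerk(tau)
        self.x[onset:end] = self.cx + (tx - self.cx) * s
        self.y[onset:end] = self.cy + (ty - self.cy) * s
        self.x[end:] = tx
        self.y[end:] = ty
        self.truth.append({"kind": "saccade", "onset_ms": onset, "offset_ms": end,
                           "x": tx, "y": ty, "amplitude_deg": amp,
                           "peak_vel": self.params.peak_velocity(amp)})
        self.cx, self.cy = tx, ty
        self.t = end
        self._fix_start = end

    def finish(self) -> None:
        if self.n > self._fix_start:
            self.truth.append({"kind": "fixation", "onset_ms": self._fix_start,
                               "offset_ms": self.n, "x": self.cx, "y": self.cy})


def _jitter_point(rng, point, rect, sd):
    """Target point with Gaussian scatter, clipped to stay inside the rect."""
    x = np.clip(point[0] + rng.normal(0, sd), rect.x + 2, rect.x + rect.w - 2)
    y = np.clip(point[1] + rng.normal(0, sd), rect.y + 2, rect.y + rect.h - 2)
    return float(x), float(y)


def simulate_gaze(trial: pd.Series, response: pd.Series | None,
                  rois: ROISet, params: GazeSimParams, seed: int,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one trial's 1000-Hz gaze trace.

    Returns ``(samples, truth_events)``.  Samples carry one row per clock
    tick (``t_ms, x_px, y_px, valid``); truth events list the generator's
    own fixation/saccade/blink intervals for detector validation.

    The scripted trajectory: central fixation at trial start, a saccade to
    the name-prior corner, then either (short-presentation design) two
    anticipatory saccades during the face-outline interval that target the
    expected feature ROI with probabilities ``p_sacc1/2_expected``, or
    (free-viewing design) a scan of the face that starts centrally with
    probability ``p_center_first`` and visits the feature regions with the
    same expectation bias on the first two feature targets.
    """
    if params.sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if params.sampling_rate != 1000.0:
        raise NotImplementedError("the trace generator works on a 1-ms grid "
                                  "(1000 Hz sampling)")
    exp = EXPERIMENTS[trial["experiment"]]
    rng = derive_rng(seed, trial["participant"], "gaze", int(trial["trial_uid"]))

    rt = None
    if response is not None and response["choice"] != "none":
        rt = float(response["rt_ms"])

    if exp.face_ms is None:
        face_dur = exp.max_face_ms if rt is None else min(rt, exp.max_face_ms)
        n_ms = int(trial["face_on"] + np.ceil(face_dur))
    else:
        n_ms = int(trial["trial_end"])

    screen = rois.screen
    cx, cy = rois.center.center()
    traj = _Trajectory(n_ms, cx, cy, params, screen)

    # fixate the name prior
    corner_rect = rois.corners[trial["prior_corner"]]
    corner_pt = _jitter_point(rng, corner_rect.center(), corner_rect,
                              params.endpoint_jitter_px * 2)
    traj.saccade_to(int(rng.uniform(130, 230)), *corner_pt)

    expected = trial["prior_feature"]
    others = [f for f in FEATURE_LABELS if f != expected]

    def feature_target(label):
        rect = rois.features[label][0]
        pt = _jitter_point(rng, rect.center(), rect, params.endpoint_jitter_px)
        # re-targeting the currently fixated region is a refixation: keep a
        # minimum separation so the movement is a real (detectable) saccade
        best, best_d = pt, float(np.hypot(pt[0] - traj.cx, pt[1] - traj.cy))
        tries = 0
        while best_d < 60.0 and tries < 6:
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(60, 70)
            cand = (float(np.clip(traj.cx + rad * np.cos(ang), rect.x + 2,
                                  rect.x + rect.w - 2)),
                    float(np.clip(traj.cy + rad * np.sin(ang), rect.y + 2,
                                  rect.y + rect.h - 2)))
            d = float(np.hypot(cand[0] - traj.cx, cand[1] - traj.cy))
            if d > best_d:
                best, best_d = cand, d
            tries += 1
        return best

    def fix_dur():
        return max(80.0, rng.normal(params.fixation_duration_mean,
                                    params.fixation_duration_sd))

    if exp.isi_ms:
        # anticipatory saccades on the face outline
        t1 = trial["isi_on"] + rng.uniform(150, 350)
        lab1 = expected if rng.random() < params.p_sacc1_expected else rng.choice(others)
        traj.saccade_to(t1, *feature_target(lab1))
        t2 = traj.t + fix_dur()
        if rng.random() < params.p_sacc2_expected:
            lab2 = expected
        else:
            lab2 = rng.choice([f for f in others if f != lab1] or others)
        traj.saccade_to(t2, *feature_target(lab2))
        # face + response period: keep scanning (never re-target the
        # currently fixated region — a same-region jump would be a
        # sub-threshold micro-movement, not a saccade)
        t = traj.t + fix_dur()
        visited = {lab1, lab2}
        current = lab2
        while t < n_ms - 60:
            pool = [f for f in FEATURE_LABELS if f not in visited] \
                or [f for f in FEATURE_LABELS if f != current]
            lab = rng.choice(pool)
            visited.add(lab)
            current = lab
            traj.saccade_to(t, *feature_target(lab))
            t = traj.t + fix_dur()
    else:
        # free viewing of the face
        t = trial["face_on"] + rng.uniform(150, 300)
        if rng.random() < params.p_center_first:
            traj.saccade_to(t, *_jitter_point(rng, rois.center.center(),
                                              rois.center, params.endpoint_jitter_px))
            t = traj.t + fix_dur()
        order = []
        lab1 = expected if rng.random() < params.p_sacc1_expected else rng.choice(others)
        order.append(lab1)
        rest = [f for f in FEATURE_LABELS if f != lab1]
        if expected in rest and rng.random() < params.p_sacc2_expected:
            lab2 = expected
        else:
            lab2 = rng.choice([f for f in rest if f != expected] or rest)
        order.append(lab2)
        order += list(rng.permutation([f for f in rest if f != lab2]))
        i = 0
        current = None
        while t < n_ms - 60:
            if i < len(order):
                lab = order[i]
            else:
                lab = rng.choice([f for f in FEATURE_LABELS if f != current])
            traj.saccade_to(t, *feature_target(lab))
            current = lab
            t = traj.t + fix_dur()
            i += 1
    traj.finish()

    x = traj.x + rng.normal(0.0, params.noise_sd_px, n_ms)
    y = traj.y + rng.normal(0.0, params.noise_sd_px, n_ms)
    samples = pd.DataFrame({
        "participant": trial["participant"],
        "trial_uid": int(trial["trial_uid"]),
        "t_ms": np.arange(n_ms, dtype=int),
        "x_px": x, "y_px": y,
        "valid": np.ones(n_ms, dtype=bool),
    })
    samples, blink_truth = inject_artifacts(
        samples, params.loss_rate, params.blink_rate, seed,
        _rng=derive_rng(seed, trial["participant"], "artifacts",
                        int(trial["trial_uid"])))

    truth = pd.DataFrame(traj.truth + blink_truth)
    truth["participant"] = trial["participant"]
    truth["trial_uid"] = int(trial["trial_uid"])
    return samples, truth


def inject_artifacts(samples: pd.DataFrame, loss_rate: float, blink_rate: float,
                     seed: int, _rng: np.random.Generator | None = None,
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Mark blink spans and random tracking-loss spans invalid.

    Blinks arrive as a Poisson process at ``blink_rate`` events/s with
    ~150 ms closure; loss is injected as short (~20 ms) spans until the
    requested invalid fraction is reached.  Returns the modified samples
    plus the list of injected blink truth events.
    """
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError("loss_rate must be in [0, 1)")
    rng = _rng if _rng is not None else derive_rng(seed, "artifacts")
    n = len(samples)
    if n == 0 or (loss_rate == 0 and blink_rate == 0):
        return samples, []
    valid = samples["valid"].to_numpy().copy()
    truth = []
    n_blinks = rng.poisson(blink_rate * n / 1000.0)
    for _ in range(n_blinks):
        dur = max(50, int(rng.normal(150, 30)))
        start = int(rng.uniform(0, max(1, n - dur)))
        valid[start:start + dur] = False
        truth.append({"kind": "blink", "onset_ms": start,
                      "offset_ms": min(n, start + dur)})
    if loss_rate > 0:
        target = int(round(loss_rate * n))
        guard = 0
        while (~valid).sum() < target and guard < 10_000:
            dur = 1 + rng.geometric(1 / 20.0)
            start = int(rng.uniform(0, max(1, n - dur)))
            valid[start:start + dur] = False
            guard += 1
    out = samples.copy()
    out["valid"] = valid
    return out, truth


# ---------------------------------------------------------------------------
# cohort convenience
# ---------------------------------------------------------------------------

def simulate_cohort(experiment_id: str, n_participants: int, seed: int,
                    behavior: BehaviorParams | None = None,
                    gaze: GazeSimParams | None = None,
                    rois: ROISet | None = None,
                    with_gaze: bool = True):
    """Simulate a full cohort; returns (design, responses, samples, truth).

    ``samples``/``truth`` are dicts keyed by ``(participant, trial_uid)``
    (``None`` when ``with_gaze`` is false).  Participants are labelled
    ``p01 .. pNN``.
    """
    behavior = behavior or BehaviorParams.typical(experiment_id)
    gaze = gaze or GazeSimParams()
    rois = rois or build_default_roiset()
    designs, resps = [], []
    samples, truths = ({}, {}) if with_gaze else (None, None)
    for i in range(1, n_participants + 1):
        pid = f"p{i:02d}"
        d = generate_design(experiment_id, pid, seed)
        r = simulate_behavior(d, behavior, seed)
        designs.append(d)
        resps.append(r)
        if with_gaze:
            r_idx = r.set_index("trial_uid")
            for _, t in d.iterrows():
                resp = r_idx.loc[t["trial_uid"]]
                s, tr = simulate_gaze(t, resp, rois, gaze, seed)
                samples[(pid, int(t["trial_uid"]))] = s
                truths[(pid, int(t["trial_uid"]))] = tr
    return (pd.concat(designs, ignore_index=True),
            pd.concat(resps, ignore_index=True), samples, truths)
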