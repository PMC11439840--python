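"""Trial- and participant-level exclusion rules.

Rule-based screening applied before any metric:

* trial level — the name prior must have been fixated (awareness of the
  cue is a precondition for expectation effects), a response must exist,
  and the eye-tracking data in the analysis window of interest must be
  sufficiently complete: for the short-presentation design at most 30%
  sample loss during the face-outline interval, for the free-viewing
  design at least 50% of the face presentation covered by fixation;
* participant level — a dataset is dropped when more than 30% of its
  trials were excluded, or when match/mismatch accuracy is at or below
  the experiment's chance level (50% in both designs, used conservatively
  for the free-viewing design whose strict mismatch chance would be
  12.5% = 0.5 * 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geometry import ROISet

__all__ = ["ExclusionRules", "TrialValidity", "validate_trial",
           "validate_participant", "validate_trials"]

#: machine-readable exclusion reason codes
PRIOR_NOT_FIXATED = "prior_not_fixated"
NO_RESPONSE = "no_response"
ISI_LOSS = "isi_loss"
LOW_VALID_FIXATION = "low_valid_fixation"
TOO_MANY_INVALID_TRIALS = "too_many_invalid_trials"
CHANCE_ACCURACY = "chance_accuracy"


@dataclass
class ExclusionRules:
    require_prior_fixation: bool = True
    require_response: bool = True
    exp1_isi_loss_max: float = 0.30
    exp2_valid_fixation_min: float = 0.50
    participant_invalid_max: float = 0.30
    chance_accuracy: dict = field(default_factory=lambda: {"exp1": 0.5, "exp2": 0.5})
    #: window for the ISI-loss rule, ms from outline onset (None = full ISI)
    isi_loss_window_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("exp1_isi_loss_max", "exp2_valid_fixation_min",
                     "participant_invalid_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"ExclusionRules.{name} must be in (0, 1)")


@dataclass
class TrialValidity:
    included: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.included == (len(self.reasons) == 0)


def _fixated_prior(trial, events, rois: ROISet) -> bool:
    corner = rois.corners[trial["prior_corner"]]
    fx = events[(events["kind"] == "fixation")
                & (events["onset_ms"] < trial["prior_off"])
                & (events["offset_ms"] > trial["prior_on"])]
    for _, f in fx.iterrows():
        if pd.notna(f["x_centroid"]) and corner.contains(f["x_centroid"], f["y_centroid"]):
            return True
    return False


def validate_trial(trial: pd.Series, samples: pd.DataFrame,
                   events: pd.DataFrame, rules: ExclusionRules,
                   rois: ROISet) -> TrialValidity:
    """Apply the trial-level exclusion rules, in order.

    ``samples``/``events`` must belong to the trial (checked via
    ``trial_uid`` when present).
    """
    for other in (samples, events):
        if "trial_uid" in other.columns and len(other):
            if int(other["trial_uid"].iloc[0]) != int(trial["trial_uid"]):
                raise ValueError("samples/events do not belong to this trial")
    reasons: list[str] = []
    if rules.require_prior_fixation and not _fixated_prior(trial, events, rois):
        reasons.append(PRIOR_NOT_FIXATED)
    if rules.require_response and trial.get("choice", "none") == "none":
        reasons.append(NO_RESPONSE)

    if trial["experiment"] == "exp1":
        lo = trial["isi_on"]
        hi = lo + rules.isi_loss_window_ms if rules.isi_loss_window_ms else trial["isi_off"]
        window = samples[(samples["t_ms"] >= lo) & (samples["t_ms"] < hi)]
        if len(window):
            loss = 1.0 - window["valid"].mean()
            if loss > rules.exp1_isi_loss_max:
                reasons.append(ISI_LOSS)
    else:
        lo, hi = trial["face_on"], min(trial["face_off"], samples["t_ms"].iloc[-1] + 1)
        dur = hi - lo
        if dur > 0:
            fx = events[events["kind"] == "fixation"]
            cover = (fx["offset_ms"].clip(upper=hi)
                     - fx["onset_ms"].clip(lower=lo)).clip(lower=0).sum()
            if cover / dur < rules.exp2_valid_fixation_min:
                reasons.append(LOW_VALID_FIXATION)
    return TrialValidity(included=not reasons, reasons=reasons)


def validate_trials(trials: pd.DataFrame, samples_by_trial: dict,
                    events_by_trial: dict, rules: ExclusionRules,
                    rois: ROISet) -> pd.DataFrame:
    """Vector version of :func:`validate_trial` over a trials table.

    ``samples_by_trial``/``events_by_trial`` are keyed by
    ``(participant, trial_uid)``.  Returns the trials table augmented with
    ``included`` and ``reasons`` columns.
    """
    rec = []
    for _, t in trials.iterrows():
        key = (t["participant"], int(t["trial_uid"]))
        v = validate_trial(t, samples_by_trial[key], events_by_trial[key],
                           rules, rois)
        rec.append({"participant": t["participant"], "trial_uid": t["trial_uid"],
                    "included": v.included, "reasons": ";".join(v.reasons)})
    return trials.merge(pd.DataFrame(rec), on=["participant", "trial_uid"])


def validate_participant(trial_validities: pd.DataFrame,
                         trials: pd.DataFrame,
                         rules: ExclusionRules) -> TrialValidity:
    """Participant-level screening from per-trial validities and behaviour.

    ``trial_validities`` needs ``included``; ``trials`` needs ``condition``,
    ``correct`` and ``experiment`` for the included trials.  Accuracy is the
    mean of ``correct`` over included match and mismatch trials.
    """
    reasons: list[str] = []
    frac_invalid = 1.0 - trial_validities["included"].mean()
    if frac_invalid > rules.participant_invalid_max + 1e-12:
        reasons.append(TOO_MANY_INVALID_TRIALS)
    exp = trials["experiment"].iloc[0]
    merged = trials.merge(
        trial_validities[["trial_uid", "included"]], on="trial_uid",
        suffixes=("", "_v")) if "included" not in trials.columns else trials
    mm = merged[merged["condition"].isin(["match", "mismatch"]) & merged["included"]]
    if len(mm):
        accuracy = mm["correct"].mean()
        if accuracy <= rules.chance_accuracy[exp]:
            reasons.append(CHANCE_ACCURACY)
    return TrialValidity(included=not reasons, reasons=reasons)
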