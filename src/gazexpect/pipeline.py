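"""End-to-end pipeline: simulate -> detect -> validate -> metrics -> stats.

`run_synthetic_experiment` streams the cohort trial by trial (samples are
discarded once events are extracted) so full-size cohorts stay cheap in
memory; `run_pipeline` is the config-driven entry point behind the CLI
that also writes every intermediate table plus a provenance record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .events import DetectionParams, compute_kinematics, detect_events
from .geometry import ROISet, build_default_roiset, load_roi_config
from .metrics import (assimilation_index, fixation_order, last_fixation_bias,
                      onset_roi_linkage, predictive_saccade_table, roi_class_map,
                      rt_summary, sampling_proportions)
from .preprocess import ExclusionRules, validate_participant, validate_trial
from .simulate import (BehaviorParams, GazeSimParams, derive_rng,
                       generate_design, simulate_behavior, simulate_gaze)

log = logging.getLogger("gazexpect")

__all__ = ["RunConfig", "run_synthetic_experiment", "run_pipeline"]


@dataclass
class RunConfig:
    experiment: str = "exp1"
    n_participants: int = 4
    seed: int = 0
    out_dir: str = "results"
    roi_config: str | None = None      # None = package default geometry
    detection: DetectionParams = field(default_factory=DetectionParams)
    rules: ExclusionRules = field(default_factory=ExclusionRules)
    behavior: BehaviorParams | None = None
    gaze: GazeSimParams = field(default_factory=GazeSimParams)

    def as_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "n_participants": self.n_participants,
            "seed": self.seed,
            "roi_config": self.roi_config,
            "detection": vars(self.detection),
            "rules": vars(self.rules),
            "behavior": vars(self.behavior) if self.behavior else None,
            "gaze": vars(self.gaze),
        }


def process_trial(trial: pd.Series, samples: pd.DataFrame, rois: ROISet,
                  detection: DetectionParams, rules: ExclusionRules):
    """Detect events for one trial and apply the trial-level screening."""
    kin = compute_kinematics(samples, rois.screen)
    events = detect_events(samples, kin, detection, rois.screen)
    events["participant"] = trial["participant"]
    events["trial_uid"] = int(trial["trial_uid"])
    validity = validate_trial(trial, samples, events, rules, rois)
    return events, validity


def run_synthetic_experiment(experiment: str, n_participants: int, seed: int,
                             rois: ROISet | None = None,
                             behavior: BehaviorParams | None = None,
                             gaze: GazeSimParams | None = None,
                             detection: DetectionParams | None = None,
                             rules: ExclusionRules | None = None,
                             keep_truth: bool = False):
    """Simulate a cohort and run detection + screening trial by trial.

    Returns a dict with ``trials`` (design + response + validity columns),
    ``events_by_trial`` (detected events keyed by (participant,
    trial_uid)), ``participants`` (per-participant inclusion) and, when
    ``keep_truth``, the generator's ground-truth events.
    """
    rois = rois or build_default_roiset()
    behavior = behavior or BehaviorParams.typical(experiment)
    gaze = gaze or GazeSimParams()
    detection = detection or DetectionParams()
    rules = rules or ExclusionRules()

    all_trials, events_by_trial, truth_by_trial = [], {}, {}
    participants = []
    for i in range(1, n_participants + 1):
        pid = f"p{i:02d}"
        design = generate_design(experiment, pid, seed)
        responses = simulate_behavior(design, behavior, seed)
        trials = design.merge(
            responses[["trial_uid", "choice", "identity_choice", "rt_ms", "correct"]],
            on="trial_uid")
        validities = []
        for _, t in trials.iterrows():
            samples, truth = simulate_gaze(t, t, rois, gaze, seed)
            events, v = process_trial(t, samples, rois, detection, rules)
            key = (pid, int(t["trial_uid"]))
            events_by_trial[key] = events
            if keep_truth:
                truth_by_trial[key] = truth
            validities.append({"trial_uid": t["trial_uid"], "included": v.included,
                               "reasons": ";".join(v.reasons)})
        vdf = pd.DataFrame(validities)
        trials = trials.merge(vdf, on="trial_uid")
        pv = validate_participant(vdf, trials, rules)
        participants.append({"participant": pid, "included": pv.included,
                             "reasons": ";".join(pv.reasons)})
        log.info("%s %s: %d/%d trials included, participant %s", experiment,
                 pid, int(trials["included"].sum()), len(trials),
                 "included" if pv.included else f"EXCLUDED ({pv.reasons})")
        all_trials.append(trials)

    out = {
        "trials": pd.concat(all_trials, ignore_index=True),
        "events_by_trial": events_by_trial,
        "participants": pd.DataFrame(participants),
    }
    if keep_truth:
        out["truth_by_trial"] = truth_by_trial
    return out


def participant_metrics(bundle: dict, rois: ROISet,
                        detection: DetectionParams) -> pd.DataFrame:
    """Participant-grain summary metrics for included participants/trials."""
    trials = bundle["trials"]
    events = bundle["events_by_trial"]
    ok_participants = set(
        bundle["participants"].loc[bundle["participants"]["included"], "participant"])
    rows = []
    for pid, grp in trials.groupby("participant"):
        if pid not in ok_participants:
            continue
        inc = grp[grp["included"]]
        row = {"participant": pid,
               "n_included": len(inc), "n_trials": len(grp),
               "assimilation_index": assimilation_index(inc)}
        row.update({f"rt_{k}": v for k, v in rt_summary(inc).items()})
        exp = grp["experiment"].iloc[0]
        if exp == "exp1":
            tbl = predictive_saccade_table(inc, events, rois, detection)
            row.update({f"sacc_{s}_{e}": v for (s, e), v in tbl.items()})
            link = onset_roi_linkage(inc, events, rois)
            row.update({f"acc_{c}_{w}": v for (c, w), v in link.items()})
        else:
            rng = derive_rng(0, pid, "ordinal_fill")
            ranks = []
            props = []
            for _, t in inc.iterrows():
                ev = events[(pid, int(t["trial_uid"]))]
                o = fixation_order(ev, t, rois, rng)
                if o is not None:
                    ranks.append(o[t["prior_feature"]])
                if t["condition"] == "partial":
                    sp = sampling_proportions(ev, t, rois)
                    if sp is not None:
                        props.append(sp)
            for k in range(1, 5):
                row[f"expected_rank{k}_pct"] = (
                    100.0 * np.mean([r == k for r in ranks]) if ranks else np.nan)
            if props:
                pdf = pd.DataFrame(props)
                for c in pdf.columns:
                    row[c] = float(pdf[c].mean())
            row["last_fixation_bias_pct"] = last_fixation_bias(inc, events, rois)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline per config and write all result tables.

    Writes under ``config.out_dir``: trials.tsv (design + responses +
    validity), events.tsv, participants.tsv, metrics.tsv and
    provenance.json.  Deterministic given (config, seed).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rois = load_roi_config(config.roi_config) if config.roi_config \
        else build_default_roiset()

    bundle = run_synthetic_experiment(
        config.experiment, config.n_participants, config.seed, rois=rois,
        behavior=config.behavior, gaze=config.gaze,
        detection=config.detection, rules=config.rules)

    metrics_df = participant_metrics(bundle, rois, config.detection)

    gio.write_table(bundle["trials"], out_dir / "trials.tsv")
    gio.write_table(pd.concat(bundle["events_by_trial"].values(),
                              ignore_index=True), out_dir / "events.tsv")
    gio.write_table(bundle["participants"], out_dir / "participants.tsv")
    gio.write_table(metrics_df, out_dir / "metrics.tsv")
    gio.write_provenance(out_dir / "provenance.json", config.as_dict(), config.seed)
    log.info("pipeline finished: %d participants, %d trials -> %s",
             config.n_participants, len(bundle["trials"]), out_dir)
    return {"bundle": bundle, "metrics": metrics_df, "out_dir": out_dir}
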