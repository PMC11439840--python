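"""Derived eye-movement and behavioural measures.

All metrics are expressed per participant and classify the four
facial-feature regions per trial as

* ``expected`` — the feature of the identity announced by the name prior;
* ``unexpected`` — the feature of the *other* identity shown (the second
  morph member on partial trials, the shown identity on mismatch trials;
  undefined on match trials where no unexpected identity exists);
* ``others`` — the remaining regions.

Proportions are percentages in [0, 100].  Fixations are assigned to a
region via their centroid; dwell time accumulates fixation-event overlap
with the analysis window, so a fixation spanning a boundary contributes
only its inside part.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import DetectionParams, predictive_saccades
from .geometry import FEATURE_LABELS, ROISet, classify_point
from .simulate import IDENTITY_FEATURE

__all__ = [
    "roi_class_map",
    "predictive_saccade_table",
    "fixation_order",
    "first_between",
    "sampling_proportions",
    "binned_sampling",
    "mean_fixation_durations",
    "assimilation_index",
    "rt_summary",
    "onset_roi_linkage",
    "last_fixation_bias",
]


def roi_class_map(trial: pd.Series) -> dict:
    """Expected / unexpected / other feature labels for one trial."""
    expected = trial["prior_feature"]
    if trial["condition"] == "match":
        unexpected = None
    elif trial["condition"] == "mismatch":
        unexpected = IDENTITY_FEATURE[trial["stimulus"]]
    else:
        unexpected = IDENTITY_FEATURE[trial["morph_other"]]
    others = [f for f in FEATURE_LABELS if f not in (expected, unexpected)]
    return {"expected": expected, "unexpected": unexpected, "others": others}


def _face_window(trial: pd.Series) -> tuple[float, float]:
    """Actual face-presentation window: the design offset, shortened by the
    response when presentation is response-terminated."""
    lo, hi = float(trial["face_on"]), float(trial["face_off"])
    rt = trial.get("rt_ms", None)
    if rt is not None and pd.notna(rt):
        hi = min(hi, lo + float(rt))
    return lo, hi


def _feature_fixations(events: pd.DataFrame, rois: ROISet,
                       lo: float | None = None, hi: float | None = None) -> pd.DataFrame:
    """Fixation events (optionally clipped to a window) with an ``roi`` column."""
    fx = events[events["kind"] == "fixation"].copy()
    if lo is not None:
        fx = fx[fx["offset_ms"] > lo]
    if hi is not None:
        fx = fx[fx["onset_ms"] < hi]
    if fx.empty:
        fx["roi"] = pd.Series(dtype=object)
        return fx
    fx["roi"] = [classify_point(r["x_centroid"], r["y_centroid"], rois)
                 if pd.notna(r["x_centroid"]) else None
                 for _, r in fx.iterrows()]
    return fx


# ---------------------------------------------------------------------------
# anticipatory saccades (short-presentation design)
# ---------------------------------------------------------------------------

def predictive_saccade_table(trials: pd.DataFrame, events_by_trial: dict,
                             rois: ROISet, params: DetectionParams) -> dict:
    """2 x 2 table of anticipatory-saccade landing percentages.

    For each feature region and each of the first two qualifying saccades
    during the outline interval, the landing rate is computed separately
    over trials where that region's feature was expected and where it was
    not (relative frequencies, since the two trial sets differ 1:3 in
    size); the four per-region rates are then averaged.  Returns
    ``{(saccade, expectation): percentage_or_nan}`` with saccade in
    {"first", "second"} and expectation in {"expected", "unexpected"}.
    """
    hits = {(s, e, r): 0 for s in (0, 1) for e in ("expected", "unexpected")
            for r in FEATURE_LABELS}
    denom = {(s, e, r): 0 for s in (0, 1) for e in ("expected", "unexpected")
             for r in FEATURE_LABELS}
    for _, t in trials.iterrows():
        ev = events_by_trial[(t["participant"], int(t["trial_uid"]))]
        qs = predictive_saccades(ev, t["isi_on"], t["face_on"], params)
        for s in range(len(qs)):
            land = classify_point(qs.iloc[s]["x_end"], qs.iloc[s]["y_end"], rois)
            for r in FEATURE_LABELS:
                e = "expected" if t["prior_feature"] == r else "unexpected"
                denom[(s, e, r)] += 1
                if land == r:
                    hits[(s, e, r)] += 1
    out = {}
    for s, name in ((0, "first"), (1, "second")):
        for e in ("expected", "unexpected"):
            rates = [100.0 * hits[(s, e, r)] / denom[(s, e, r)]
                     for r in FEATURE_LABELS if denom[(s, e, r)] > 0]
            out[(name, e)] = float(np.mean(rates)) if len(rates) == len(FEATURE_LABELS) \
                else float("nan")
    return out


# ---------------------------------------------------------------------------
# fixation order (free-viewing design)
# ---------------------------------------------------------------------------

def _first_onsets(events: pd.DataFrame, rois: ROISet, lo: float, hi: float) -> dict:
    """First-fixation onset per feature region within [lo, hi), NaN if never."""
    fx = _feature_fixations(events, rois, lo, hi)
    onsets = {r: float("nan") for r in FEATURE_LABELS}
    for _, f in fx.sort_values("onset_ms").iterrows():
        r = f["roi"]
        if r is not None and np.isnan(onsets[r]):
            onsets[r] = max(float(f["onset_ms"]), lo)
    return onsets


def fixation_order(events: pd.DataFrame, trial: pd.Series, rois: ROISet,
                   rng: np.random.Generator) -> dict | None:
    """Ordinal (1-4) of each feature region by first-fixation time.

    Regions actually fixated during face presentation are ranked by their
    first fixation onset; regions never fixated are assigned the remaining
    ordinals uniformly at random.  Returns ``None`` when no feature region
    was fixated at all (the trial drops out of the order analysis).
    """
    lo, hi = _face_window(trial)
    onsets = _first_onsets(events, rois, lo, hi)
    fixated = sorted((t, r) for r, t in onsets.items() if not np.isnan(t))
    if not fixated:
        return None
    ordinals = {}
    for rank, (_, r) in enumerate(fixated, start=1):
        ordinals[r] = rank
    missing = [r for r in FEATURE_LABELS if r not in ordinals]
    free = [k for k in range(1, 5) if k not in ordinals.values()]
    for r, k in zip(missing, rng.permutation(free)):
        ordinals[r] = int(k)
    return ordinals


def first_between(events: pd.DataFrame, trial: pd.Series, rois: ROISet,
                  group_a: list[str], group_b: list[str]) -> str:
    """Which region group was fixated first: 'a_first', 'b_first' or
    'not_applicable' (neither group fixated)."""
    lo, hi = _face_window(trial)
    onsets = _first_onsets(events, rois, lo, hi)

    def earliest(group):
        vals = [onsets[r] for r in group if not np.isnan(onsets[r])]
        return min(vals) if vals else float("nan")

    ta, tb = earliest(group_a), earliest(group_b)
    if np.isnan(ta) and np.isnan(tb):
        return "not_applicable"
    if np.isnan(tb) or (not np.isnan(ta) and ta <= tb):
        return "a_first"
    return "b_first"


# ---------------------------------------------------------------------------
# sampling proportions, bins, durations
# ---------------------------------------------------------------------------

def _overlap(onset, offset, lo, hi):
    return np.clip(np.minimum(offset, hi) - np.maximum(onset, lo), 0, None)


def sampling_proportions(events: pd.DataFrame, trial: pd.Series,
                         rois: ROISet, presentation_ms: float | None = None) -> dict | None:
    """Fixation-count and dwell-time proportions per region class.

    Count proportion: fixations centred in the class's region(s) as a
    percentage of all fixations during face presentation.  Dwell
    proportion: summed fixation overlap with the presentation window as a
    percentage of presentation duration.  Multi-region classes ("others")
    report the per-region average.  Returns ``None`` when the trial has no
    fixation during presentation.
    """
    lo, hi = _face_window(trial)
    if presentation_ms is not None:
        hi = lo + presentation_ms
    dur = hi - lo
    fx = _feature_fixations(events, rois, lo, hi)
    if fx.empty or dur <= 0:
        return None
    total = len(fx)
    cmap = roi_class_map(trial)
    out = {}
    for cls in ("expected", "unexpected", "others"):
        labels = cmap[cls] if cls == "others" else \
            ([cmap[cls]] if cmap[cls] else [])
        if not labels:
            out[f"count_pct_{cls}"] = float("nan")
            out[f"dwell_pct_{cls}"] = float("nan")
            continue
        counts, dwells = [], []
        for lab in labels:
            sub = fx[fx["roi"] == lab]
            counts.append(100.0 * len(sub) / total)
            dwells.append(100.0 * _overlap(sub["onset_ms"], sub["offset_ms"],
                                           lo, hi).sum() / dur)
        out[f"count_pct_{cls}"] = float(np.mean(counts))
        out[f"dwell_pct_{cls}"] = float(np.mean(dwells))
    return out


def binned_sampling(events: pd.DataFrame, trial: pd.Series, rois: ROISet,
                    bin_ms: float = 500.0, n_bins: int = 4) -> pd.DataFrame:
    """Per-bin count and dwell proportions for the three region classes.

    The presentation window is cut into ``n_bins`` consecutive bins of
    ``bin_ms``; a fixation contributes to every bin it overlaps, dwell is
    split at bin boundaries.  Bins not fully covered by the presentation
    (response came earlier) are flagged missing (NaN).
    """
    lo, present_end = _face_window(trial)
    fx = _feature_fixations(events, rois, lo, present_end)
    cmap = roi_class_map(trial)
    rows = []
    for b in range(n_bins):
        b_lo, b_hi = lo + b * bin_ms, lo + (b + 1) * bin_ms
        row = {"bin": b + 1}
        if b_hi > present_end:
            for cls in ("expected", "unexpected", "others"):
                row[f"count_pct_{cls}"] = float("nan")
                row[f"dwell_pct_{cls}"] = float("nan")
            rows.append(row)
            continue
        in_bin = fx[(fx["offset_ms"] > b_lo) & (fx["onset_ms"] < b_hi)]
        total = len(in_bin)
        for cls in ("expected", "unexpected", "others"):
            labels = cmap[cls] if cls == "others" else \
                ([cmap[cls]] if cmap[cls] else [])
            if not labels or total == 0:
                row[f"count_pct_{cls}"] = float("nan")
                row[f"dwell_pct_{cls}"] = float("nan")
                continue
            counts, dwells = [], []
            for lab in labels:
                sub = in_bin[in_bin["roi"] == lab]
                counts.append(100.0 * len(sub) / total)
                dwells.append(100.0 * _overlap(sub["onset_ms"], sub["offset_ms"],
                                               b_lo, b_hi).sum() / bin_ms)
            row[f"count_pct_{cls}"] = float(np.mean(counts))
            row[f"dwell_pct_{cls}"] = float(np.mean(dwells))
        rows.append(row)
    return pd.DataFrame(rows)


def mean_fixation_durations(events: pd.DataFrame, trial: pd.Series,
                            rois: ROISet) -> dict:
    """Mean fixation duration (ms) per region class; NaN when unvisited."""
    fx = _feature_fixations(events, rois, *_face_window(trial))
    cmap = roi_class_map(trial)
    out = {}
    for cls in ("expected", "unexpected", "others"):
        labels = cmap[cls] if cls == "others" else \
            ([cmap[cls]] if cmap[cls] else [])
        durs = fx[fx["roi"].isin(labels)]["duration_ms"] if labels else []
        out[cls] = float(np.mean(durs)) if len(durs) else float("nan")
    return out


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def assimilation_index(trials: pd.DataFrame) -> float:
    """Perceived-face-identity index over morph (partial) trials, 0-100%.

    For each of the 12 prior-by-morph combinations, the count of
    expectation-noncompliant identity reports is subtracted from the count
    of compliant ones and normalised by that combination's attributed
    trials; the combination scores are averaged and mapped linearly so a
    zero difference is 50%, all-compliant is 100% and all-noncompliant 0%.
    Returns NaN when no partial response is attributable.
    """
    part = trials[(trials["condition"] == "partial")
                  & (trials["choice"].isin(["expected", "unexpected"]))].copy()
    if part.empty:
        return float("nan")
    compliant = part["choice"] == "expected"
    if "identity_choice" in part.columns:
        attributed = compliant | (part["identity_choice"] == "") \
            | (part["identity_choice"] == part["morph_other"])
        noncompliant = (~compliant) & attributed
    else:
        noncompliant = ~compliant
        attributed = pd.Series(True, index=part.index)
    part = part[attributed]
    compliant, noncompliant = compliant[attributed], noncompliant[attributed]
    combo = part["prior_identity"] + "|" + part["stimulus"]
    scores = []
    for _, idx in combo.groupby(combo).groups.items():
        n = len(idx)
        scores.append((compliant.loc[idx].sum() - noncompliant.loc[idx].sum()) / n)
    if not scores:
        return float("nan")
    return float((np.mean(scores) + 1.0) / 2.0 * 100.0)


def rt_summary(trials: pd.DataFrame, correct_only: bool = False) -> dict:
    """Mean RT (ms) per condition over responded trials."""
    resp = trials[trials["choice"] != "none"]
    if correct_only:
        resp = resp[resp["correct"]]
    out = {}
    for cond in ("match", "mismatch", "partial"):
        r = resp.loc[resp["condition"] == cond, "rt_ms"]
        out[cond] = float(r.mean()) if len(r) else float("nan")
    return out


# ---------------------------------------------------------------------------
# eye-behaviour linkage
# ---------------------------------------------------------------------------

def _onset_roi(events: pd.DataFrame, t_onset: float, rois: ROISet) -> str | None:
    """Region of the fixation active at a timestamp (None if a saccade or
    blink is in flight)."""
    cur = events[(events["onset_ms"] <= t_onset) & (events["offset_ms"] > t_onset)]
    if cur.empty or cur.iloc[0]["kind"] != "fixation":
        return None
    f = cur.iloc[0]
    if pd.isna(f["x_centroid"]):
        return None
    return classify_point(f["x_centroid"], f["y_centroid"], rois)


def onset_roi_linkage(trials: pd.DataFrame, events_by_trial: dict,
                      rois: ROISet) -> dict:
    """Accuracy / expected-choice rates conditional on the face-onset fixation.

    For match and mismatch trials: accuracy among trials whose fixation at
    face onset lay in the expected region versus not.  For partial trials:
    the proportion choosing the expected identity given an expected-region
    onset fixation (and its complement).  Cells without trials are NaN.
    """
    buckets: dict[tuple, list] = {}
    for _, t in trials.iterrows():
        if t["choice"] == "none":
            continue
        ev = events_by_trial[(t["participant"], int(t["trial_uid"]))]
        roi = _onset_roi(ev, t["face_on"], rois)
        on_expected = roi == t["prior_feature"]
        if t["condition"] in ("match", "mismatch"):
            buckets.setdefault((t["condition"], on_expected), []).append(bool(t["correct"]))
        else:
            buckets.setdefault(("partial", on_expected), []).append(
                t["choice"] == "expected")
    out = {}
    for cond in ("match", "mismatch", "partial"):
        for flag, name in ((True, "on_expected"), (False, "off_expected")):
            vals = buckets.get((cond, flag))
            out[(cond, name)] = 100.0 * float(np.mean(vals)) if vals else float("nan")
    return out


def last_fixation_bias(trials: pd.DataFrame, events_by_trial: dict,
                       rois: ROISet) -> float:
    """Proportion of morph trials whose chosen identity's region was the
    last feature region fixated before the response (percentage).

    Eligible trials are partial trials with an identity attribution and at
    least one feature-region fixation before the response; NaN otherwise.
    """
    hits, n = 0, 0
    for _, t in trials.iterrows():
        if t["condition"] != "partial" or t["choice"] == "none":
            continue
        if t["choice"] == "expected":
            chosen = t["prior_identity"]
        elif t.get("identity_choice", ""):
            chosen = t["identity_choice"]
        else:
            continue
        if chosen not in IDENTITY_FEATURE:
            continue
        ev = events_by_trial[(t["participant"], int(t["trial_uid"]))]
        fx = _feature_fixations(ev, rois, *_face_window(t))
        fx = fx[fx["roi"].notna()]
        if fx.empty:
            continue
        last_roi = fx.sort_values("onset_ms").iloc[-1]["roi"]
        n += 1
        if last_roi == IDENTITY_FEATURE[chosen]:
            hits += 1
    return 100.0 * hits / n if n else float("nan")
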