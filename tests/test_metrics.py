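import numpy as np
import pandas as pd
import pytest

import gazexpect as gx
from gazexpect.metrics import roi_class_map
from conftest import make_events


def trial_row(rois, condition="partial", prior="A", other="B",
              exp="exp2", face_on=750, face_off=5250, choice="expected",
              identity="", rt=2000.0, participant="p01", uid=1):
    stim = "+".join(sorted([prior, other])) if condition == "partial" else \
        (prior if condition == "match" else other)
    return pd.Series({
        "experiment": exp, "participant": participant, "trial_uid": uid,
        "condition": condition, "prior_identity": prior,
        "prior_feature": gx.IDENTITY_FEATURE[prior],
        "morph_other": other if condition == "partial" else
        (other if condition == "mismatch" else ""),
        "stimulus": stim, "face_on": face_on, "face_off": face_off,
        "isi_on": 750, "isi_off": 1750,
        "choice": choice, "identity_choice": identity, "rt_ms": rt,
        "correct": True,
    })


def centers(rois):
    return {lab: rois.feature_center(lab) for lab in gx.FEATURE_LABELS}


def test_roi_class_map_partition(rois):
    t = trial_row(rois, condition="partial", prior="A", other="C")
    m = roi_class_map(t)
    assert m["expected"] == "forehead" and m["unexpected"] == "ears"
    assert sorted([m["expected"], m["unexpected"], *m["others"]]) \
        == sorted(gx.FEATURE_LABELS)
    t2 = trial_row(rois, condition="match", prior="B")
    m2 = roi_class_map(t2)
    assert m2["expected"] == "chin" and m2["unexpected"] is None
    assert len(m2["others"]) == 3


# ---------------------------------------------------------------------------
# predictive saccade table
# ---------------------------------------------------------------------------

def saccade_event(onset, land_xy):
    return ("saccade", onset, onset + 40, land_xy[0], land_xy[1])


def test_predictive_table_all_expected(rois):
    """Every first saccade to the expected region -> 100% / 0% cells."""
    c = centers(rois)
    trials, events = [], {}
    for uid, prior in enumerate(gx.IDENTITIES):
        t = trial_row(rois, condition="match", prior=prior, exp="exp1",
                      face_on=1750, face_off=1850, uid=uid)
        feat = gx.IDENTITY_FEATURE[prior]
        events[("p01", uid)] = make_events([
            ("fixation", 0, 900, 100, 100),
            saccade_event(900, c[feat]),
            ("fixation", 940, 1300, *c[feat]),
            saccade_event(1300, c[feat]),
            ("fixation", 1340, 1850, *c[feat]),
        ])
        trials.append(t)
    table = gx.predictive_saccade_table(pd.DataFrame(trials), events, rois,
                                        gx.DetectionParams())
    assert table[("first", "expected")] == 100.0
    assert table[("first", "unexpected")] == 0.0
    assert table[("second", "expected")] == 100.0


def test_predictive_table_matches_hand_enumeration(rois):
    """Unequal per-region trial counts: the statistic averages per-region
    relative frequencies rather than pooling saccades."""
    c = centers(rois)
    # 8 trials: priors A,A,A,A,B,B,C,D; all first saccades land on forehead
    priors = ["A", "A", "A", "A", "B", "B", "C", "D"]
    trials, events = [], {}
    for uid, prior in enumerate(priors):
        t = trial_row(rois, condition="match", prior=prior, exp="exp1",
                      face_on=1750, face_off=1850, uid=uid)
        events[("p01", uid)] = make_events([
            ("fixation", 0, 900, 100, 100),
            saccade_event(900, c["forehead"]),
            ("fixation", 940, 1850, *c["forehead"]),
        ])
        trials.append(t)
    table = gx.predictive_saccade_table(pd.DataFrame(trials), events, rois,
                                        gx.DetectionParams())
    # per region, share of first saccades landing in it when expected:
    # forehead 4/4, chin 0/2, ears 0/1, nose 0/1 -> mean 25%
    assert table[("first", "expected")] == pytest.approx(25.0)
    # when not expected: forehead 4/4, chin 0/6, ears 0/7, nose 0/7 -> 25%
    assert table[("first", "unexpected")] == pytest.approx(25.0)
    # pooled frequency would have been 100% of 8 saccades on one region:
    # the per-region average is deliberately different
    assert table[("second", "expected")] != table[("second", "expected")]  # NaN


def test_predictive_table_random_endpoints_near_null(rois):
    """Uniformly random landing points: expected and unexpected rates
    converge to the same region hit rate."""
    rng = np.random.default_rng(5)
    trials, events = [], {}
    uid = 0
    for rep in range(150):
        for prior in gx.IDENTITIES:
            t = trial_row(rois, condition="match", prior=prior, exp="exp1",
                          face_on=1750, face_off=1850, uid=uid)
            land = (rng.uniform(0, 1600), rng.uniform(0, 1200))
            events[("p01", uid)] = make_events([
                ("fixation", 0, 900, 100, 100),
                saccade_event(900, land),
                ("fixation", 940, 1850, *land),
            ])
            trials.append(t)
            uid += 1
    table = gx.predictive_saccade_table(pd.DataFrame(trials), events, rois,
                                        gx.DetectionParams())
    diff = table[("first", "expected")] - table[("first", "unexpected")]
    assert abs(diff) < 5.0


# ---------------------------------------------------------------------------
# fixation order / first-between
# ---------------------------------------------------------------------------

def test_fixation_order_full_ranking(rois):
    c = centers(rois)
    t = trial_row(rois, prior="D", other="B")   # expected = nose
    ev = make_events([
        ("fixation", 950, 1150, *c["nose"]),
        ("fixation", 1250, 1450, *c["chin"]),
        ("fixation", 1650, 1850, *c["forehead"]),
        ("fixation", 2050, 2250, *c["ears"]),
    ])
    rng = np.random.default_rng(0)
    o = gx.fixation_order(ev, t, rois, rng)
    assert o == {"nose": 1, "chin": 2, "forehead": 3, "ears": 4}


def test_fixation_order_random_fill(rois):
    c = centers(rois)
    t = trial_row(rois, prior="D", other="B")
    ev = make_events([("fixation", 950, 1150, *c["nose"])])
    rng = np.random.default_rng(0)
    seen = set()
    for _ in range(50):
        o = gx.fixation_order(ev, t, rois, rng)
        assert o["nose"] == 1
        assert sorted(o.values()) == [1, 2, 3, 4]
        seen.add((o["forehead"], o["chin"], o["ears"]))
    assert len(seen) == 6          # all 3! permutations of {2,3,4} appear


def test_fixation_order_none_when_no_feature_fixated(rois):
    t = trial_row(rois)
    ev = make_events([("fixation", 950, 1500, 800, 460)])  # central only
    assert gx.fixation_order(ev, t, rois, np.random.default_rng(0)) is None


def test_fixation_order_uniform_under_null(rois):
    """Uniformly random single-region fixations give each region a flat
    ordinal distribution."""
    rng = np.random.default_rng(11)
    c = centers(rois)
    t = trial_row(rois, prior="A", other="B")
    counts = np.zeros(4)
    n = 4000
    for _ in range(n):
        lab = gx.FEATURE_LABELS[rng.integers(4)]
        ev = make_events([("fixation", 950, 1150, *c[lab])])
        o = gx.fixation_order(ev, t, rois, rng)
        counts[o["forehead"] - 1] += 1
    props = counts / n
    assert np.allclose(props, 0.25, atol=0.03)


def test_first_between(rois):
    c = centers(rois)
    t = trial_row(rois, prior="A", other="B")
    ev = make_events([
        ("fixation", 1050, 1250, *c["forehead"]),   # expected at 300 ms
        ("fixation", 1200 + 750, 2150, *c["chin"]),
    ])
    assert gx.first_between(ev, t, rois, ["forehead"], ["chin"]) == "a_first"
    assert gx.first_between(ev, t, rois, ["chin"], ["forehead"]) == "b_first"
    # group b never fixated
    assert gx.first_between(ev, t, rois, ["forehead"], ["nose"]) == "a_first"
    assert gx.first_between(ev, t, rois, ["ears"], ["nose"]) == "not_applicable"


# ---------------------------------------------------------------------------
# proportions / bins / durations
# ---------------------------------------------------------------------------

def test_sampling_proportions_single_fixation(rois):
    c = centers(rois)
    t = trial_row(rois, prior="A", other="B", face_on=750, face_off=2750)
    ev = make_events([("fixation", 1000, 1400, *c["forehead"])])
    out = gx.sampling_proportions(ev, t, rois)
    assert out["count_pct_expected"] == 100.0
    assert out["dwell_pct_expected"] == pytest.approx(20.0)   # 400 of 2000 ms
    assert out["count_pct_unexpected"] == 0.0
    assert out["dwell_pct_others"] == 0.0


def test_sampling_proportions_no_feature_fixation(rois):
    t = trial_row(rois)
    ev = make_events([("fixation", 1000, 1400, 800, 460)])    # central
    out = gx.sampling_proportions(ev, t, rois)
    assert out["count_pct_expected"] == 0.0
    assert out["dwell_pct_unexpected"] == 0.0


def test_sampling_proportions_none_when_no_fixations(rois):
    t = trial_row(rois)
    ev = make_events([("saccade", 1000, 1040, 800, 460)])
    assert gx.sampling_proportions(ev, t, rois) is None


def test_dwell_matches_per_sample_oracle(rois, screen, exp2_trials):
    """Event-based dwell equals brute-force per-sample ROI counting."""
    t = exp2_trials[exp2_trials["condition"] == "partial"].iloc[0]
    smp, _ = gx.simulate_gaze(t, t, rois, gx.GazeSimParams(blink_rate=0,
                                                           loss_rate=0), 3)
    kin = gx.compute_kinematics(smp, screen)
    ev = gx.detect_events(smp, kin, gx.DetectionParams(), screen)
    out = gx.sampling_proportions(ev, t, rois)

    # oracle: per-sample membership during fixation events only
    cmap = roi_class_map(t)
    lo, hi = t["face_on"], min(t["face_off"], len(smp))
    dwell = {lab: 0 for lab in gx.FEATURE_LABELS}
    fx = ev[ev["kind"] == "fixation"]
    n_events = {lab: 0 for lab in gx.FEATURE_LABELS}
    for _, f in fx.iterrows():
        lab = gx.classify_point(f["x_centroid"], f["y_centroid"], rois) \
            if pd.notna(f["x_centroid"]) else None
        if lab is None:
            continue
        ov = min(f["offset_ms"], hi) - max(f["onset_ms"], lo)
        if f["offset_ms"] > lo and f["onset_ms"] < hi:
            dwell[lab] += max(0, ov)
    dur = hi - lo
    exp_lab = cmap["expected"]
    assert out["dwell_pct_expected"] == pytest.approx(
        100.0 * dwell[exp_lab] / dur, abs=0.1)


def test_binned_dwell_split_across_boundary(rois):
    c = centers(rois)
    # fixation spanning 400-700 ms after face onset: 100 ms in bin 1,
    # 200 ms in bin 2
    t = trial_row(rois, prior="A", other="B", face_on=0, face_off=2000)
    ev = make_events([("fixation", 400, 700, *c["forehead"])])
    out = gx.binned_sampling(ev, t, rois)
    assert out.loc[0, "dwell_pct_expected"] == pytest.approx(100 * 100 / 500)
    assert out.loc[1, "dwell_pct_expected"] == pytest.approx(100 * 200 / 500)


def test_bins_beyond_presentation_missing(rois):
    c = centers(rois)
    t = trial_row(rois, prior="A", other="B", face_on=0, face_off=1200)
    ev = make_events([("fixation", 100, 400, *c["forehead"])])
    out = gx.binned_sampling(ev, t, rois)
    assert np.isnan(out.loc[2, "dwell_pct_expected"])
    assert np.isnan(out.loc[3, "count_pct_expected"])
    # per-bin class dwell sums stay <= 100
    s = out.loc[0, ["dwell_pct_expected", "dwell_pct_unexpected"]].sum() \
        + 2 * out.loc[0, "dwell_pct_others"]
    assert s <= 100.0 + 1e-9


def test_mean_fixation_durations(rois):
    c = centers(rois)
    t = trial_row(rois, prior="A", other="B", face_on=0, face_off=3000)
    ev = make_events([
        ("fixation", 100, 300, *c["forehead"]),    # 200 ms expected
        ("fixation", 400, 700, *c["forehead"]),    # 300 ms expected
        ("fixation", 800, 1000, *c["chin"]),       # unexpected
    ])
    out = gx.mean_fixation_durations(ev, t, rois)
    assert out["expected"] == 250.0
    assert out["unexpected"] == 200.0
    assert np.isnan(out["others"])


# ---------------------------------------------------------------------------
# behavioural indices
# ---------------------------------------------------------------------------

def balanced_partial_trials(n_per_combo=4):
    rows = []
    uid = 0
    for prior in gx.IDENTITIES:
        for other in [i for i in gx.IDENTITIES if i != prior]:
            stim = "+".join(sorted([prior, other]))
            for j in range(n_per_combo):
                compliant = j < n_per_combo // 2
                rows.append({
                    "trial_uid": uid, "condition": "partial",
                    "prior_identity": prior, "stimulus": stim,
                    "morph_other": other,
                    "choice": "expected" if compliant else "unexpected",
                    "identity_choice": "" if compliant else other,
                })
                uid += 1
    return pd.DataFrame(rows)


def test_assimilation_index_balanced_is_fifty():
    assert gx.assimilation_index(balanced_partial_trials()) == 50.0


def test_assimilation_index_all_compliant_is_hundred():
    t = balanced_partial_trials()
    t["choice"] = "expected"
    assert gx.assimilation_index(t) == 100.0


def test_assimilation_index_hand_enumeration():
    """12 combinations x 12 trials, 9 compliant / 3 noncompliant each:
    score per combination = (9 - 3) / 12 = 0.5 -> index 75%."""
    rows = []
    uid = 0
    for prior in gx.IDENTITIES:
        for other in [i for i in gx.IDENTITIES if i != prior]:
            stim = "+".join(sorted([prior, other]))
            for j in range(12):
                rows.append({
                    "trial_uid": uid, "condition": "partial",
                    "prior_identity": prior, "stimulus": stim,
                    "morph_other": other,
                    "choice": "expected" if j < 9 else "unexpected",
                    "identity_choice": "" if j < 9 else other,
                })
                uid += 1
    assert gx.assimilation_index(pd.DataFrame(rows)) == pytest.approx(75.0)


def test_assimilation_index_empty_is_nan():
    empty = balanced_partial_trials().iloc[0:0]
    assert np.isnan(gx.assimilation_index(empty))


def test_assimilation_recovers_generating_probability():
    for q in (0.25, 0.5, 0.75):
        d = gx.generate_design("exp2", "p01", 17)
        r = gx.simulate_behavior(d, gx.BehaviorParams(assimilation_q=q,
                                                      miss_rate=0.0), 17)
        t = d.merge(r, on="trial_uid", suffixes=("", "_r"))
        idx = gx.assimilation_index(t)
        n = (t["condition"] == "partial").sum()
        mc = 300 * np.sqrt(q * (1 - q) / n)     # 3 sigma in percent
        assert abs(idx - 100 * q) < mc


def test_rt_summary_means_and_missing(rois):
    t = pd.DataFrame({
        "condition": ["match", "match", "mismatch", "partial"],
        "choice": ["expected", "expected", "none", "expected"],
        "rt_ms": [600.0, 700.0, np.nan, 900.0],
        "correct": [True, True, False, True],
    })
    out = gx.rt_summary(t)
    assert out["match"] == 650.0
    assert np.isnan(out["mismatch"])       # only a no-response trial
    assert out["partial"] == 900.0


# ---------------------------------------------------------------------------
# eye-behaviour linkage
# ---------------------------------------------------------------------------

def test_onset_roi_linkage_hand_enumeration(rois):
    c = centers(rois)
    trials, events = [], {}
    # 4 match trials (prior A): onset fixation on expected region in 2,
    # correct only when on expected
    specs = [("forehead", True), ("forehead", True),
             ("chin", False), ("chin", False)]
    for uid, (lab, correct) in enumerate(specs):
        t = trial_row(rois, condition="match", prior="A", exp="exp1",
                      face_on=1750, face_off=1850, uid=uid)
        t["correct"] = correct
        events[("p01", uid)] = make_events([
            ("fixation", 0, 1850, *c[lab]),
        ])
        trials.append(t)
    out = gx.onset_roi_linkage(pd.DataFrame(trials), events, rois)
    assert out[("match", "on_expected")] == 100.0
    assert out[("match", "off_expected")] == 0.0
    assert np.isnan(out[("mismatch", "on_expected")])


def test_onset_roi_saccade_in_flight_counts_as_off(rois):
    trials, events = [], {}
    t = trial_row(rois, condition="match", prior="A", exp="exp1",
                  face_on=1750, face_off=1850, uid=0)
    t["correct"] = True
    events[("p01", 0)] = make_events([
        ("fixation", 0, 1740, 100, 100),
        ("saccade", 1740, 1790, 800, 460),
        ("fixation", 1790, 1850, 800, 460),
    ])
    out = gx.onset_roi_linkage(pd.DataFrame([t]), events, rois)
    assert np.isnan(out[("match", "on_expected")])
    assert out[("match", "off_expected")] == 100.0


def test_last_fixation_bias_hand_count(rois):
    c = centers(rois)
    trials, events = [], {}
    # 4 partial trials, chosen identity's region fixated last in 3
    specs = [("A", "expected", "forehead"), ("A", "expected", "forehead"),
             ("A", "expected", "forehead"), ("A", "expected", "chin")]
    for uid, (prior, choice, last_lab) in enumerate(specs):
        t = trial_row(rois, condition="partial", prior=prior, other="B",
                      choice=choice, rt=2000.0, uid=uid)
        events[("p01", uid)] = make_events([
            ("fixation", 900, 1400, *c["ears"]),
            ("fixation", 1500, 2200, *c[last_lab]),
        ])
        trials.append(t)
    assert gx.last_fixation_bias(pd.DataFrame(trials), events, rois) == 75.0


def test_last_fixation_bias_no_eligible_trials(rois):
    t = trial_row(rois, condition="match", prior="A")
    assert np.isnan(gx.last_fixation_bias(pd.DataFrame([t]), {}, rois))
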