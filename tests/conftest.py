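import numpy as np
import pandas as pd
import pytest

import gazexpect as gx


@pytest.fixture(scope="session")
def screen():
    return gx.ScreenGeometry()


@pytest.fixture(scope="session")
def rois():
    return gx.build_default_roiset()


@pytest.fixture(scope="session")
def exp1_design():
    return gx.generate_design("exp1", "p01", 7)


@pytest.fixture(scope="session")
def exp2_design():
    return gx.generate_design("exp2", "p01", 7)


@pytest.fixture(scope="session")
def exp1_trials(exp1_design):
    """Design joined with simulated responses."""
    resp = gx.simulate_behavior(exp1_design, gx.BehaviorParams(), 7)
    return exp1_design.merge(
        resp[["trial_uid", "choice", "identity_choice", "rt_ms", "correct"]],
        on="trial_uid")


@pytest.fixture(scope="session")
def exp2_trials(exp2_design):
    resp = gx.simulate_behavior(exp2_design, gx.BehaviorParams.typical("exp2"), 7)
    return exp2_design.merge(
        resp[["trial_uid", "choice", "identity_choice", "rt_ms", "correct"]],
        on="trial_uid")


def make_events(rows):
    """Hand-written events table for metric unit tests.

    rows: (kind, onset, offset, x, y) — x/y used as both endpoint and
    centroid.
    """
    rec = []
    for kind, onset, offset, x, y in rows:
        rec.append({
            "kind": kind, "onset_ms": onset, "offset_ms": offset,
            "duration_ms": offset - onset,
            "x_start": x, "y_start": y, "x_end": x, "y_end": y,
            "amplitude_deg": 5.0 if kind == "saccade" else np.nan,
            "peak_vel_deg_s": 300.0 if kind == "saccade" else np.nan,
            "x_centroid": x if kind == "fixation" else np.nan,
            "y_centroid": y if kind == "fixation" else np.nan,
        })
    return pd.DataFrame(rec)


@pytest.fixture(scope="session")
def clean_gaze_params():
    """Artifact-free gaze generation (no blinks, no loss)."""
    return gx.GazeSimParams(blink_rate=0.0, loss_rate=0.0)
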