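"""Saccade / fixation / blink detection from raw gaze samples.

The detector follows the velocity-acceleration scheme of tower-mounted
research trackers: a sample belongs to a saccade candidate when its angular
velocity exceeds 30 deg/s OR its acceleration exceeds 8000 deg/s^2;
candidate runs whose total displacement stays below the 0.1-deg motion
threshold are discarded as jitter.  Runs of invalid samples become blinks,
and whatever remains is fixation.  Detected events partition the trial
timeline: every millisecond belongs to exactly one event.

Velocity is estimated with a five-sample symmetric difference
(``v[t] = (x[t+2] + x[t+1] - x[t-1] - x[t-2]) / (6 dt)``), which trades a
little latency for strong noise suppression; acceleration applies the same
operator to the speed trace.  Because the hard velocity crossing happens a
few milliseconds after motion onset, detected saccade boundaries are
extended outward while the speed stays above a lower extension threshold,
which brings onsets within a couple of samples of the true movement start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "DetectionParams",
    "compute_kinematics",
    "detect_events",
    "predictive_saccades",
]


@dataclass
class DetectionParams:
    """Thresholds of the event detector (all configurable).

    ``velocity_threshold`` (deg/s), ``acceleration_threshold`` (deg/s^2) and
    ``motion_threshold`` (deg) define a saccade; ``min_predictive_latency``
    (ms) is the anticipatory-saccade latency criterion used downstream.
    The remaining fields are implementation details: the onset/offset
    extension threshold, the minimum saccade duration (debounce) and the
    blink run-length / padding.
    """

    velocity_threshold: float = 30.0
    acceleration_threshold: float = 8000.0
    motion_threshold: float = 0.1
    min_predictive_latency: float = 100.0
    extension_threshold: float = 10.0     # deg/s
    min_saccade_ms: float = 4.0
    merge_gap_ms: float = 30.0
    blink_min_ms: float = 50.0
    blink_pad_ms: float = 10.0

    def __post_init__(self) -> None:
        for name in ("velocity_threshold", "acceleration_threshold",
                     "motion_threshold", "min_predictive_latency",
                     "extension_threshold", "min_saccade_ms", "blink_min_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DetectionParams.{name} must be > 0")


def _to_deg_coords(samples: pd.DataFrame, screen: ScreenGeometry):
    """Map pixel coordinates to angular coordinates about the screen centre."""
    cx, cy = screen.width_px / 2.0, screen.height_px / 2.0
    d = screen.viewing_distance_mm
    x_mm = (samples["x_px"].to_numpy() - cx) * screen.mm_per_px("x")
    y_mm = (samples["y_px"].to_numpy() - cy) * screen.mm_per_px("y")
    return np.degrees(np.arctan2(x_mm, d)), np.degrees(np.arctan2(y_mm, d))


def compute_kinematics(samples: pd.DataFrame, screen: ScreenGeometry) -> pd.DataFrame:
    """Per-sample angular speed (deg/s) and acceleration (deg/s^2).

    Samples must be time-ordered at a uniform 1-ms spacing.  Windows that
    touch an invalid sample (or run off the trace edge) yield NaN and are
    flagged invalid.  Fewer than five samples produce an empty result.
    """
    n = len(samples)
    if n < 5:
        return pd.DataFrame(columns=["t_ms", "vel_deg_s", "acc_deg_s2", "valid"])
    t = samples["t_ms"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("samples must be strictly time-ordered")
    dt = 0.001
    xd, yd = _to_deg_coords(samples, screen)
    valid = samples["valid"].to_numpy().astype(bool)

    def d5(a: np.ndarray) -> np.ndarray:
        out = np.full_like(a, np.nan, dtype=float)
        out[2:-2] = (a[4:] + a[3:-1] - a[1:-3] - a[:-4]) / (6.0 * dt)
        return out

    vx, vy = d5(xd), d5(yd)
    speed = np.hypot(vx, vy)
    acc = d5(np.nan_to_num(speed, nan=0.0))
    # a window touching an invalid sample is itself invalid
    bad = ~valid
    k_vel = np.convolve(bad.astype(int), np.ones(5, dtype=int), mode="same") > 0
    k_acc = np.convolve(k_vel.astype(int), np.ones(5, dtype=int), mode="same") > 0
    speed[k_vel] = np.nan
    acc[k_acc] = np.nan
    edge = np.zeros(n, dtype=bool)
    edge[:2] = edge[-2:] = True
    acc_edge = np.zeros(n, dtype=bool)
    acc_edge[:4] = acc_edge[-4:] = True
    speed[edge] = np.nan
    acc[acc_edge] = np.nan
    return pd.DataFrame({
        "t_ms": t,
        "vel_deg_s": speed,
        "acc_deg_s2": acc,
        "valid": valid & ~k_vel,
    })


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    stops = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _event_row(kind, onset, offset, samples, xd=None, yd=None, vel=None):
    x = samples["x_px"].to_numpy()
    y = samples["y_px"].to_numpy()
    valid = samples["valid"].to_numpy()
    sl = slice(onset, offset)
    row = {
        "kind": kind, "onset_ms": int(onset), "offset_ms": int(offset),
        "duration_ms": int(offset - onset),
        "x_start": float(x[onset]), "y_start": float(y[onset]),
        "x_end": float(x[offset - 1]), "y_end": float(y[offset - 1]),
        "amplitude_deg": np.nan, "peak_vel_deg_s": np.nan,
        "x_centroid": np.nan, "y_centroid": np.nan,
    }
    if kind == "fixation":
        v = valid[sl]
        if v.any():
            row["x_centroid"] = float(np.mean(x[sl][v]))
            row["y_centroid"] = float(np.mean(y[sl][v]))
    if kind == "saccade" and vel is not None:
        vv = vel[sl]
        if np.isfinite(vv).any():
            row["peak_vel_deg_s"] = float(np.nanmax(vv))
    return row


def detect_events(samples: pd.DataFrame, kinematics: pd.DataFrame,
                  params: DetectionParams, screen: ScreenGeometry) -> pd.DataFrame:
    """Segment one trial's samples into blink / saccade / fixation events.

    Returns an events table sorted by onset whose intervals exactly tile
    ``[0, n)`` ms.  Blink events are maximal invalid runs of at least
    ``blink_min_ms``, padded by ``blink_pad_ms`` on each side; saccades are
    extended supra-threshold runs passing the motion and duration checks;
    fixations fill the remaining gaps.
    """
    n = len(samples)
    if n == 0:
        return pd.DataFrame(columns=[
            "kind", "onset_ms", "offset_ms", "duration_ms", "x_start",
            "y_start", "x_end", "y_end", "amplitude_deg", "peak_vel_deg_s",
            "x_centroid", "y_centroid"])
    if len(kinematics) != n:
        raise ValueError("kinematics must align with samples")
    valid = samples["valid"].to_numpy().astype(bool)
    vel = kinematics["vel_deg_s"].to_numpy() if n >= 5 else np.full(n, np.nan)
    acc = kinematics["acc_deg_s2"].to_numpy() if n >= 5 else np.full(n, np.nan)

    # blinks: long invalid runs, padded
    blink = np.zeros(n, dtype=bool)
    pad = int(params.blink_pad_ms)
    for start, stop in _runs(~valid):
        if stop - start >= params.blink_min_ms:
            blink[max(0, start - pad):min(n, stop + pad)] = True

    # saccade candidates
    with np.errstate(invalid="ignore"):
        cand = ((vel > params.velocity_threshold)
                | (np.abs(acc) > params.acceleration_threshold))
    cand &= ~np.isnan(vel)
    cand &= ~blink

    sacc = np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        above_ext = vel >= params.extension_threshold
    above_ext &= ~np.isnan(vel)
    for start, stop in _runs(cand):
        while start > 0 and above_ext[start - 1] and not blink[start - 1]:
            start -= 1
        while stop < n and above_ext[stop] and not blink[stop]:
            stop += 1
        sacc[start:stop] = True

    # bridge short gaps (e.g. a few lost samples mid-flight) between runs
    gap = int(params.merge_gap_ms)
    if gap > 0:
        runs = _runs(sacc)
        for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
            if s1 - e0 <= gap and not blink[e0:s1].any():
                sacc[e0:s1] = True

    # displacement (motion threshold) and duration checks per merged run
    from .simulate import gaze_angle_deg  # local import to avoid cycle at import time
    x = samples["x_px"].to_numpy()
    y = samples["y_px"].to_numpy()
    for start, stop in _runs(sacc):
        amp = gaze_angle_deg(x[start], y[start], x[stop - 1], y[stop - 1], screen)
        if amp < params.motion_threshold or stop - start < params.min_saccade_ms:
            sacc[start:stop] = False

    rows = []
    for start, stop in _runs(blink):
        rows.append(_event_row("blink", start, stop, samples))
    for start, stop in _runs(sacc):
        row = _event_row("saccade", start, stop, samples, vel=vel)
        row["amplitude_deg"] = float(gaze_angle_deg(
            x[start], y[start], x[stop - 1], y[stop - 1], screen))
        rows.append(row)
    taken = blink | sacc
    for start, stop in _runs(~taken):
        rows.append(_event_row("fixation", start, stop, samples))
    ev = pd.DataFrame(rows).sort_values("onset_ms", ignore_index=True)
    return ev


def predictive_saccades(events: pd.DataFrame, outline_onset_ms: float,
                        face_onset_ms: float, params: DetectionParams) -> pd.DataFrame:
    """First two anticipatory saccades during the face-outline interval.

    Qualifying saccades start at or after ``outline_onset + latency
    criterion`` (to drop reflexive movements still tied to the prior) and
    before face onset; at most the first two, in temporal order.
    """
    sac = events[events["kind"] == "saccade"]
    lo = outline_onset_ms + params.min_predictive_latency
    q = sac[(sac["onset_ms"] >= lo) & (sac["onset_ms"] < face_onset_ms)]
    return q.sort_values("onset_ms").head(2).reset_index(drop=True)
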