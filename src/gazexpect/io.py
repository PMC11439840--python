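"""Tabular file formats of the pipeline (TSV with documented headers).

Three table kinds circulate between stages:

* samples — ``participant  trial_uid  t_ms  x_px  y_px  valid``
* trials  — the design table, optionally joined with response and
  validity columns
* events  — detector (or ground-truth) output per trial

Writers produce canonical TSV (tab-separated, ``\\n`` newlines, header
line, floats via ``repr``-faithful pandas formatting) so that
write -> read round-trips values exactly.  Readers validate the header
and basic integrity (monotone timestamps per trial) and report offending
line numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "SAMPLE_COLUMNS",
    "read_samples",
    "write_samples",
    "read_table",
    "write_table",
    "config_hash",
]

SAMPLE_COLUMNS = ["participant", "trial_uid", "t_ms", "x_px", "y_px", "valid"]


class FormatError(ValueError):
    """Raised for malformed table files; message carries the line number."""


def write_samples(samples: pd.DataFrame, path) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"samples table lacks columns {missing}")
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: line 1: missing columns {missing}")
    for (participant, trial), grp in df.groupby(["participant", "trial_uid"]):
        t = grp["t_ms"].to_numpy()
        bad = (t[1:] <= t[:-1]).nonzero()[0]
        if bad.size:
            # +2: header line and 0-based offset
            line = int(grp.index[bad[0] + 1]) + 2
            raise FormatError(
                f"{path}: line {line}: non-monotone timestamps in trial "
                f"{participant}/{trial}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: line 1: missing columns {missing}")
    return df


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (for provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_provenance(path, config: dict, seed: int) -> None:
    from . import __version__
    rec = {"seed": seed, "version": __version__, "config_hash": config_hash(config),
           "config": config}
    Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True, default=str))
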