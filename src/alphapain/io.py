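"""Reading and writing of the pipeline's on-disk formats.

EEG goes to disk as plain ``channels x samples`` numeric arrays (one ``.npy``
per trial) with a JSON sidecar carrying channel names, sampling rate and
units, plus a BIDS-style tab-separated ``events.tsv`` (onset, duration,
trial_type, rating and condition columns).  Feedback traces and feature
tables are tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import TrialSet

__all__ = [
    "write_trialset",
    "read_trialset",
    "write_feedback_trace",
    "read_feedback_trace",
    "write_feature_table",
    "read_feature_table",
]


def write_trialset(directory: str | Path, ts: TrialSet, name: str = "trials") -> Path:
    """Write a TrialSet: per-trial arrays, JSON sidecar, events.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}_signal.npy", ts.signal)
    np.save(directory / f"{name}_visibility.npy", ts.visibility)
    np.save(directory / f"{name}_aai_trace.npy", ts.aai_trace)
    np.save(directory / f"{name}_rewards.npy", ts.rewards)
    sidecar = {
        "channel_names": list(ts.channels),
        "sampling_rate_hz": ts.fs,
        "units": "uV",
        "t_start_s": float(ts.times[0]),
        "n_trials": int(ts.n_trials),
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    ev = ts.events.copy()
    ev["onset"] = ev["stim_onset"]
    ev["duration"] = 0.004
    ev["trial_type"] = "laser"
    ev.to_csv(directory / f"{name}_events.tsv", sep="\t", index=False)
    return directory


def read_trialset(directory: str | Path, name: str = "trials") -> TrialSet:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    signal = np.load(directory / f"{name}_signal.npy")
    fs = sidecar["sampling_rate_hz"]
    times = sidecar["t_start_s"] + np.arange(signal.shape[-1]) / fs
    events = pd.read_csv(directory / f"{name}_events.tsv", sep="\t")
    return TrialSet(signal=signal, times=times,
                    channels=tuple(sidecar["channel_names"]), fs=fs, events=events,
                    visibility=np.load(directory / f"{name}_visibility.npy"),
                    aai_trace=np.load(directory / f"{name}_aai_trace.npy"),
                    rewards=np.load(directory / f"{name}_rewards.npy"))


def write_feedback_trace(path: str | Path, timestamps, aai, faai, c) -> Path:
    """Tab-separated feedback trace: t, aai, faai, c."""
    path = Path(path)
    pd.DataFrame({"t": timestamps, "aai": aai, "faai": faai, "c": c}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    return path


def read_feedback_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
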