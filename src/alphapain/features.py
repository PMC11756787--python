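"""Offline single-trial EEG quantification.

Mirrors the real-time analysis on the recorded data and adds the evoked /
oscillatory response measures used as secondary outcomes:

* per-trial alpha asymmetry: the last 12 s of the regulation period are cut
  into 1,000 ms epochs at a 100 ms stride (111 epochs), artefact-marked
  epochs are dropped, the remaining epochs are scored with the identical
  windowed-FFT asymmetry index used online, and the trial value is their
  mean;
* laser-evoked potentials N1 (C4 re-referenced to Fz), N2 and P2 (Cz):
  band-pass 1-30 Hz, baseline 2.0-2.5 s after fixation onset, two-stage
  scoring (group-average peak latency, then single-trial mean amplitude over
  a 30 ms window around that latency);
* induced oscillations: alpha (8-12 Hz) and beta (14-30 Hz) power 500-900 ms
  post-stimulus over a central-parietal channel set, gamma (70-90 Hz) power
  150-350 ms at Cz, from Hanning sliding-window spectra;
* the printed exclusion rules (artefact fraction, invalid ratings, minimum
  trials per condition, wrong-hand flag) and the artefact / blinding control
  indices.

Preprocessing beyond this is out of scope; artefacts are detected by a
configurable amplitude-threshold stub, which does not claim to replicate a
full automatic pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import realtime
from .synthdata import TrialSet

__all__ = [
    "ErpSpec",
    "ERP_SPECS",
    "amplitude_artefact_mask",
    "epoch_starts",
    "extract_trial_aai",
    "quantify_evoked",
    "quantify_oscillatory",
    "build_feature_table",
    "apply_exclusions",
    "control_index",
]

AAI_SPAN_S = 12.0       #: regulation seconds entering the offline AAI
EPOCH_S = 1.0
STRIDE_S = 0.1
MAX_ARTEFACT_FRACTION = 0.5
POSTSTIM_GUARD_S = 1.5  #: post-stimulus interval protected for ERP/TFR
BASELINE_WINDOW = (2.0, 2.5)  #: seconds after fixation onset


@dataclass(frozen=True)
class ErpSpec:
    """Search window, channel and polarity of one evoked component."""

    name: str
    window_ms: tuple[float, float]
    channel: str
    polarity: str              # "min" or "max"
    reref: str | None = None   # channel subtracted before scoring
    amp_window_ms: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.window_ms[0] < self.window_ms[1] <= 1500.0):
            raise ValueError("search window must lie within the 1.5 s post-stimulus interval")


ERP_SPECS = (
    ErpSpec("N1", (120.0, 200.0), "C4", "min", reref="Fz"),
    ErpSpec("N2", (180.0, 300.0), "Cz", "min"),
    ErpSpec("P2", (250.0, 500.0), "Cz", "max"),
)

ALPHA_BETA_CHANNELS = ("Cz", "CPz", "C2", "C4", "CP2", "CP4")


def amplitude_artefact_mask(trialset: TrialSet, threshold_uv: float = 150.0) -> np.ndarray:
    """Boolean (n_trials, n_samples) mask: any channel exceeding the threshold.

    Stand-in for a full artefact pipeline: marks samples whose absolute
    amplitude on any channel exceeds ``threshold_uv``.
    """
    return np.abs(trialset.signal).max(axis=1) > threshold_uv


def epoch_starts(span_s: float = AAI_SPAN_S, epoch_s: float = EPOCH_S,
                 stride_s: float = STRIDE_S) -> np.ndarray:
    """Epoch onset times (s, stimulus at 0) over the last ``span_s`` seconds.

    12 s at a 1 s window and 0.1 s stride gives (12 - 1) / 0.1 + 1 = 111
    epochs starting at -12.0, -11.9, ..., -1.0.
    """
    n = int(round((span_s - epoch_s) / stride_s)) + 1
    return -span_s + stride_s * np.arange(n)


def extract_trial_aai(signal: np.ndarray, times: np.ndarray, channels, fs: float,
                      artefact_mask: np.ndarray | None = None) -> tuple[float, int, str]:
    """Single-trial AAI: mean over surviving 1,000 ms epochs.

    Returns ``(aai, n_epochs_used, reason)``; ``aai`` is NaN with a reason
    code when more than 50% of epochs are artefact-marked (or none survive).
    """
    starts = epoch_starts()
    n_epoch = int(round(EPOCH_S * fs))
    vals = []
    n_rejected = 0
    for t0 in starts:
        i0 = int(round((t0 - times[0]) * fs))
        if artefact_mask is not None and artefact_mask[i0:i0 + n_epoch].any():
            n_rejected += 1
            continue
        vals.append(realtime.compute_aai(signal[:, i0:i0 + n_epoch], channels, fs))
    if n_rejected > MAX_ARTEFACT_FRACTION * starts.size or not vals:
        return float("nan"), len(vals), "artefact_fraction_gt_50"
    return float(np.mean(vals)), len(vals), ""


def _butter_sos(fs: float, kind: str, freqs) -> np.ndarray:
    return sps.butter(4, freqs, btype=kind, fs=fs, output="sos")


def _filter_erp(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 1-30 Hz band-pass (4th-order Butterworth)."""
    return sps.sosfiltfilt(_butter_sos(fs, "bandpass", (1.0, 30.0)), signal, axis=-1)


def _filter_tfr(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 1 Hz high-pass plus 41-51 Hz band-stop."""
    out = sps.sosfiltfilt(_butter_sos(fs, "highpass", 1.0), signal, axis=-1)
    return sps.sosfiltfilt(_butter_sos(fs, "bandstop", (41.0, 51.0)), out, axis=-1)


def quantify_evoked(trialset: TrialSet, spec: ErpSpec,
                    trial_mask: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Two-stage single-trial ERP amplitudes.

    Stage 1 locates the local extremum of the across-trial average waveform
    inside the component's search window (after re-referencing for N1);
    stage 2 averages each single trial over a 30 ms window centred on that
    latency.  Returns ``(per-trial amplitudes uV, group peak latency s)``.
    If no interior local extremum exists, the window-edge extremum is used
    and a warning is emitted.
    """
    fs = trialset.fs
    times = trialset.times
    ch = list(trialset.channels)
    data = trialset.signal[:, ch.index(spec.channel), :]
    if spec.reref is not None:
        data = data - trialset.signal[:, ch.index(spec.reref), :]
    filt = _filter_erp(data, fs)
    b0 = trialset.events["fixation_onset"].to_numpy()[:, None] + BASELINE_WINDOW[0]
    bl_mask = (times >= b0) & (times < b0 + (BASELINE_WINDOW[1] - BASELINE_WINDOW[0]))
    baseline = np.where(bl_mask, filt, np.nan)
    filt = filt - np.nanmean(baseline, axis=-1, keepdims=True)

    use = np.ones(trialset.n_trials, dtype=bool) if trial_mask is None else trial_mask
    avg = filt[use].mean(axis=0)
    w0, w1 = spec.window_ms[0] / 1e3, spec.window_ms[1] / 1e3
    widx = np.flatnonzero((times >= w0) & (times <= w1))
    seg = avg[widx]
    if spec.polarity == "min":
        cand = np.flatnonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:])) + 1
        pick = cand[np.argmin(seg[cand])] if cand.size else None
        edge = int(np.argmin(seg))
    else:
        cand = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        pick = cand[np.argmax(seg[cand])] if cand.size else None
        edge = int(np.argmax(seg))
    if pick is None:
        warnings.warn(f"{spec.name}: no interior local extremum in window; "
                      "falling back to window-edge extremum", stacklevel=2)
        pick = edge
    latency = float(times[widx[pick]])
    half = spec.amp_window_ms / 2e3
    amp_mask = (times >= latency - half) & (times <= latency + half)
    amps = filt[:, amp_mask].mean(axis=-1)
    return amps, latency


def _sliding_band_power(data: np.ndarray, fs: float, times: np.ndarray,
                        win_s: float, step_s: float, band: tuple[float, float],
                        t_window: tuple[float, float]) -> np.ndarray:
    """Mean Hanning-spectrum band power over sliding windows in a time range.

    ``data`` is (n_trials, n_samples); windows whose centre falls inside
    ``t_window`` contribute.  Power in uV**2 from the one-sided spectrum.
    """
    n_win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    taper = np.hanning(n_win)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    centers = []
    i = 0
    while i + n_win <= data.shape[-1]:
        c = times[i] + win_s / 2.0
        if t_window[0] <= c <= t_window[1]:
            centers.append(i)
        i += step
    if not centers:
        raise ValueError("trial too short for the requested analysis span")
    acc = np.zeros(data.shape[0])
    for i in centers:
        seg = data[:, i:i + n_win]
        seg = seg - seg.mean(axis=-1, keepdims=True)
        spec = np.fft.rfft(seg * taper, axis=-1)
        acc += (np.abs(spec) ** 2)[:, fsel].mean(axis=-1)
    return acc / len(centers)


def quantify_oscillatory(trialset: TrialSet) -> pd.DataFrame:
    """Per-trial induced alpha, beta and gamma power.

    Alpha/beta: 500 ms windows, 20 ms steps, 500-900 ms post-stimulus,
    averaged over the central-parietal set {Cz, CPz, C2, C4, CP2, CP4}.
    Gamma: 250 ms windows, 20 ms steps, 70-90 Hz, 150-350 ms, at Cz.
    """
    fs = trialset.fs
    times = trialset.times
    ch = list(trialset.channels)
    filt = _filter_tfr(trialset.signal, fs)
    ab_idx = [ch.index(c) for c in ALPHA_BETA_CHANNELS]
    ab_data = filt[:, ab_idx, :]
    out = {}
    for name, band in (("alpha", (8.0, 12.0)), ("beta", (14.0, 30.0))):
        per_ch = [
            _sliding_band_power(ab_data[:, k, :], fs, times, 0.5, 0.02, band, (0.5, 0.9))
            for k in range(len(ab_idx))
        ]
        out[name] = np.mean(per_ch, axis=0)
    out["gamma"] = _sliding_band_power(filt[:, ch.index("Cz"), :], fs, times,
                                       0.25, 0.02, (70.0, 90.0), (0.15, 0.35))
    return pd.DataFrame(out)


def build_feature_table(trialset: TrialSet, artefact_threshold_uv: float = 150.0) -> pd.DataFrame:
    """Assemble the per-trial feature table for one TrialSet.

    Columns: trial metadata, trial AAI (+ epoch bookkeeping), N1/N2/P2
    amplitudes, alpha/beta/gamma power, rating, artefact fractions and the
    per-family artefact flags consumed by :func:`apply_exclusions`.
    """
    fs = trialset.fs
    times = trialset.times
    sample_mask = amplitude_artefact_mask(trialset, artefact_threshold_uv)
    tab = trialset.events.reset_index(drop=True).copy()

    aais, fracs, reasons = [], [], []
    n_epochs = epoch_starts().size
    for i in range(trialset.n_trials):
        aai, used, reason = extract_trial_aai(trialset.signal[i], times,
                                              trialset.channels, fs, sample_mask[i])
        aais.append(aai)
        fracs.append(1.0 - used / n_epochs)
        reasons.append(reason)
    tab["aai"] = aais
    tab["artefact_fraction"] = fracs
    tab["reason"] = reasons

    for spec in ERP_SPECS:
        amps, lat = quantify_evoked(trialset, spec)
        tab[spec.name.lower()] = amps
        tab[f"{spec.name.lower()}_latency"] = lat
    tab = pd.concat([tab, quantify_oscillatory(trialset)], axis=1)

    # artefacts inside the baseline or the protected post-stimulus interval
    b0 = trialset.events["fixation_onset"].to_numpy()[:, None] + BASELINE_WINDOW[0]
    bl = (times >= b0) & (times < b0 + (BASELINE_WINDOW[1] - BASELINE_WINDOW[0]))
    post = (times >= 0.0) & (times <= POSTSTIM_GUARD_S)
    tab["artefact_in_baseline"] = (sample_mask & bl).any(axis=1)
    tab["artefact_in_poststim"] = (sample_mask & post[None, :]).any(axis=1)
    tab["wrong_hand"] = False
    return tab


def apply_exclusions(table: pd.DataFrame, min_trials: int = 10) -> pd.DataFrame:
    """Apply the study's exclusion rules; returns a copy with include flags.

    Trial level: >50% artefact-marked training epochs, or a missing /
    out-of-range rating, drop the trial everywhere.  ERP/TFR level: an
    artefact in the baseline or the 1,500 ms post-stimulus interval drops the
    trial from evoked and oscillatory features only.  Subject level: fewer
    than ``min_trials`` surviving trials in any condition, or a wrong-hand
    flag, drop the subject from all primary analyses.  Exclusion reasons are
    recorded in ``reason``; adding artefacts can only remove trials, never
    restore them.
    """
    out = table.copy()
    reason = out.get("reason", pd.Series("", index=out.index)).fillna("").astype(str)

    bad_artefact = out["artefact_fraction"] > MAX_ARTEFACT_FRACTION
    rating = out["rating"].astype(float)
    bad_rating = rating.isna() | (rating < 0.0) | (rating > 100.0)
    include = ~(bad_artefact | bad_rating)
    reason = reason.where(~bad_artefact | (reason != ""), "artefact_fraction_gt_50")
    reason = reason.where(~bad_rating, "invalid_rating")

    wrong = out.get("wrong_hand", pd.Series(False, index=out.index)).astype(bool)
    bad_subj = set(out.loc[wrong, "subject"].unique())
    counts = out[include].groupby(["subject", "attention", "feedback"]).size()
    for (subj, att, fb), _ in out.groupby(["subject", "attention", "feedback"]).size().items():
        if counts.get((subj, att, fb), 0) < min_trials:
            bad_subj.add(subj)
    subj_excluded = out["subject"].isin(bad_subj)
    reason = reason.where(~(subj_excluded & include), "subject_excluded")
    include &= ~subj_excluded

    out["include"] = include
    false = pd.Series(False, index=out.index)
    in_bl = out["artefact_in_baseline"] if "artefact_in_baseline" in out else false
    in_ps = out["artefact_in_poststim"] if "artefact_in_poststim" in out else false
    out["include_erp"] = include & ~in_bl.astype(bool) & ~in_ps.astype(bool)
    out["reason"] = reason
    return out


def control_index(verum: float, sham: float) -> float:
    """Normalized verum-sham difference ``(v - s) / (v + s)``.

    Serves both the artefact index (rejected-trial counts) and the blinding
    index (mean blinding scores).  A zero denominator leaves the index
    undefined (NaN).
    """
    total = verum + sham
    if total == 0:
        return float("nan")
    return (verum - sham) / total
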