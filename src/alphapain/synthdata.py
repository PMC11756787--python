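"""Synthetic neurofeedback experiments with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at two levels of fidelity:

* :func:`generate_cohort_features` draws per-trial asymmetry indices and pain
  ratings directly from the hierarchical trial model (subject random effects,
  attention / neurofeedback / time effects, optional mediation of ratings by
  the trial-wise AAI).  It is cheap enough for cohort-scale simulation
  studies (dozens of subjects, dozens of seeds).
* :func:`generate_dataset` additionally synthesizes the multichannel EEG
  waveforms that realize those trial-level parameters: pink-noise background,
  a lateralized 10 Hz alpha rhythm over the somatosensory channel groups,
  laser-evoked N1/N2/P2 deflections, post-stimulus alpha/beta suppression and
  a gamma burst — everything the real-time engine and the offline feature
  extraction consume.

Both levels share the same trial model and per-subject random substreams
(spawned from one global seed), so a cohort can be extended without
reshuffling earlier subjects.

Trial timeline (seconds, stimulus at t = 0): fixation onset at -18, the
15 s regulation period spans [-15, 0), the noxious stimulus hits at 0 and
post-stimulus activity is simulated up to +2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import realtime
from .realtime import Condition

__all__ = [
    "SimConfig",
    "TrialSet",
    "REQUIRED_CHANNELS",
    "generate_cohort_features",
    "generate_dataset",
    "generate_yoked_sham",
]

REQUIRED_CHANNELS = (
    "C3", "C4", "CP3", "CP4", "CP5", "CP6", "Cz", "CPz", "C2", "CP2", "Fz",
)

#: trial timeline (s relative to the noxious stimulus)
T_FIXATION = -18.0
T_REGULATION = -15.0
T_STIM = 0.0
T_END = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.

    Effect sizes (``attention_effect``, ``neurofeedback_gain``) are specified
    in Cohen's-d units of the paired subject-level contrast and mapped to
    raw index units through ``aai_subject_sd``, the between-subject SD of
    condition-mean AAI differences.  ``time_slope`` is a raw AAI drift per
    trial.  Setting ``beta_M = beta_X = 0`` yields a null pain model: ratings
    carry no condition or asymmetry information (the regime the analysis is
    screened against).
    """

    n_subjects: int = 10
    n_trials_per_condition: int = 40
    sampling_rate: float = 500.0
    channel_names: tuple[str, ...] = REQUIRED_CHANNELS
    # trial-model effects
    attention_effect: float = 0.6     # d units: ART - ALT asymmetry shift
    neurofeedback_gain: float = 0.6   # d units: extra shift for verum vs sham
    time_slope: float = 0.002         # AAI units per trial (signed by condition)
    aai_subject_sd: float = 0.15      # between-subject SD of contrast effects (AAI units)
    aai_baseline_sd: float = 0.10     # between-subject SD of baseline asymmetry
    aai_trial_sd: float = 0.20        # within-subject trial-to-trial SD
    # waveform parameters
    alpha_amplitude: float = 6.0      # uV, regulation-period 10 Hz rhythm
    alpha_freq: float = 10.0          # Hz
    beta_amplitude: float = 2.0       # uV, 20 Hz central rhythm
    erp_amplitudes: dict = field(default_factory=lambda: {"N1": -3.0, "N2": -8.0, "P2": 10.0})
    erp_latencies: dict = field(default_factory=lambda: {"N1": 160.0, "N2": 220.0, "P2": 350.0})
    alpha_suppression: float = 0.5    # fractional post-stimulus amplitude drop
    beta_suppression: float = 0.4
    gamma_burst_power: float = 1.0    # burst amplitude relative to noise_sd
    gamma_freq: float = 80.0          # Hz
    noise_sd: float = 8.0             # uV RMS of the pink-noise background
    # rating model
    rating_mean: float = 50.0         # NRS units
    rating_subject_sd: float = 8.0
    beta_X: float = 0.0               # NRS shift per condition code (ART=-1, ALT=+1)
    beta_M: float = 0.0               # NRS units per AAI unit (mediation strength)
    rating_noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        highest = max(self.gamma_freq, self.alpha_freq, 20.0)
        if self.sampling_rate <= 2.0 * highest:
            raise ValueError("sampling_rate must exceed twice the highest synthesized frequency")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_names]
        if missing:
            raise ValueError(f"channel_names missing required labels: {missing}")


@dataclass
class TrialSet:
    """Multichannel EEG trials with events, condition labels and ratings.

    ``signal`` is (n_trials, n_channels, n_samples) in uV; ``times`` is the
    shared time axis in seconds with the noxious stimulus at t = 0 and the
    regulation period spanning [-15, 0).  ``events`` holds one row per trial
    (stimulus onset, fixation onset, rating).  ``visibility`` and
    ``aai_trace`` carry the per-trial feedback traces (the replayed donor
    trace for sham trials).
    """

    signal: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    fs: float
    events: pd.DataFrame            # per-trial metadata
    visibility: np.ndarray          # (n_trials, n_steps)
    aai_trace: np.ndarray           # (n_trials, n_steps) raw realtime AAI
    rewards: np.ndarray             # (n_trials,)

    def __post_init__(self) -> None:
        n = self.signal.shape[0]
        if len(self.events) != n:
            raise ValueError("events must have one row per trial")
        if not np.all((self.events["stim_onset"] == 0.0)):
            raise ValueError("every trial must carry exactly one stimulus marker at t = 0")
        r = self.events["rating"].to_numpy(dtype=float)
        ok = np.isnan(r) | ((r >= 0.0) & (r <= 100.0))
        if not ok.all():
            raise ValueError("ratings must lie in [0, 100] or be flagged missing")

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    def select(self, mask: np.ndarray) -> "TrialSet":
        idx = np.flatnonzero(mask)
        return TrialSet(self.signal[idx], self.times, self.channels, self.fs,
                        self.events.iloc[idx].reset_index(drop=True),
                        self.visibility[idx], self.aai_trace[idx], self.rewards[idx])


# ---------------------------------------------------------------------------
# trial-level statistical model
# ---------------------------------------------------------------------------

_CONDITIONS = [("ART", "verum"), ("ALT", "verum"), ("ART", "sham"), ("ALT", "sham")]


def _subject_trials(cfg: SimConfig, rng: np.random.Generator, subject: int) -> pd.DataFrame:
    """Draw the per-trial latent table (target AAI + rating) for one subject."""
    T = cfg.n_trials_per_condition
    mu = rng.normal(0.0, cfg.aai_baseline_sd)
    theta_att = rng.normal(cfg.attention_effect, 1.0) * cfg.aai_subject_sd
    theta_nf = rng.normal(cfg.neurofeedback_gain, 1.0) * cfg.aai_subject_sd
    rating_icpt = rng.normal(0.0, cfg.rating_subject_sd)
    rows = []
    for att, fb in _CONDITIONS:
        s = 1.0 if att == "ART" else -1.0
        v = 1.0 if fb == "verum" else 0.0
        trial_idx = np.arange(T)
        drift = s * cfg.time_slope * (trial_idx - (T - 1) / 2.0)
        aai = (mu + s * theta_att / 2.0 + s * v * theta_nf / 2.0 + drift
               + rng.normal(0.0, cfg.aai_trial_sd, size=T))
        aai = np.clip(aai, -1.0, 1.0)
        x = -s  # condition code: ART = -1, ALT = +1
        rating = (cfg.rating_mean + rating_icpt + cfg.beta_X * x + cfg.beta_M * aai
                  + rng.normal(0.0, cfg.rating_noise_sd, size=T))
        rating = np.clip(rating, 0.0, 100.0)
        for k in range(T):
            rows.append(dict(subject=subject, attention=att, feedback=fb,
                             trial=k, half="first" if k < T // 2 else "second",
                             aai_target=aai[k], rating=rating[k]))
    return pd.DataFrame(rows)


def _subject_rngs(cfg: SimConfig, extra: int = 0) -> list[np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects + extra)
    return [np.random.default_rng(c) for c in children]


def generate_cohort_features(cfg: SimConfig) -> pd.DataFrame:
    """Per-trial AAI / rating table for the whole cohort (no waveforms).

    The ``aai`` column equals the latent target asymmetry; when waveforms are
    synthesized (``generate_dataset``) the offline feature extraction recovers
    this value up to estimation noise.
    """
    rngs = _subject_rngs(cfg)
    frames = [_subject_trials(cfg, rngs[j], j) for j in range(cfg.n_subjects)]
    out = pd.concat(frames, ignore_index=True)
    out["aai"] = out["aai_target"]
    return out


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit-calibrated to RMS ``sd`` per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    shape[0] = 0.0
    pink = np.fft.irfft(spec * shape, n=n_samp, axis=-1)
    rms = pink.std(axis=-1, keepdims=True)
    return pink / rms * sd


def _erp_template(times: np.ndarray, latency_ms: float, amplitude: float, width_ms: float = 35.0) -> np.ndarray:
    center = latency_ms / 1e3
    return amplitude * np.exp(-0.5 * ((times - center) / (width_ms / 1e3)) ** 2)


def _synth_trial(cfg: SimConfig, rng: np.random.Generator, times: np.ndarray,
                 aai_target: float) -> np.ndarray:
    """One trial of (n_channels, n_samples) EEG realizing ``aai_target``."""
    ch = list(cfg.channel_names)
    fs = cfg.sampling_rate
    n_samp = times.size
    sig = _pink_noise(rng, len(ch), n_samp, fs, cfg.noise_sd)

    reg = (times >= T_REGULATION) & (times < T_STIM)
    post = times >= T_STIM
    # post-stimulus suppression ramp (0.3-1.2 s window, smooth edges)
    supp = np.ones(n_samp)
    win = (times >= 0.3) & (times <= 1.2)
    supp[win] = 1.0 - cfg.alpha_suppression
    supp_beta = np.ones(n_samp)
    supp_beta[win] = 1.0 - cfg.beta_suppression

    a = float(np.clip(aai_target, -0.999, 0.999))
    amp_r = cfg.alpha_amplitude * np.sqrt(1.0 + a)
    amp_l = cfg.alpha_amplitude * np.sqrt(1.0 - a)
    phase_r, phase_l = rng.uniform(0, 2 * np.pi, size=2)
    carrier_r = np.sin(2 * np.pi * cfg.alpha_freq * times + phase_r)
    carrier_l = np.sin(2 * np.pi * cfg.alpha_freq * times + phase_l)
    gate = np.where(reg, 1.0, np.where(post, supp, 0.7))
    alpha_r = amp_r * carrier_r * gate
    alpha_l = amp_l * carrier_l * gate
    alpha_mid = 0.5 * (amp_r + amp_l) * 0.7 * np.sin(
        2 * np.pi * cfg.alpha_freq * times + rng.uniform(0, 2 * np.pi)) * gate

    beta = cfg.beta_amplitude * np.sin(2 * np.pi * 20.0 * times + rng.uniform(0, 2 * np.pi))
    beta = beta * np.where(post, supp_beta, 1.0)

    gamma_env = np.exp(-0.5 * ((times - 0.25) / 0.05) ** 2)
    gamma = (cfg.gamma_burst_power * cfg.noise_sd * 0.5
             * np.sin(2 * np.pi * cfg.gamma_freq * times + rng.uniform(0, 2 * np.pi)) * gamma_env)

    n1 = _erp_template(times, cfg.erp_latencies["N1"], cfg.erp_amplitudes["N1"], 25.0)
    n2 = _erp_template(times, cfg.erp_latencies["N2"], cfg.erp_amplitudes["N2"])
    p2 = _erp_template(times, cfg.erp_latencies["P2"], cfg.erp_amplitudes["P2"], 60.0)

    for name, wave in (("C4", alpha_r), ("CP4", alpha_r), ("CP6", alpha_r),
                       ("C3", alpha_l), ("CP3", alpha_l), ("CP5", alpha_l),
                       ("Cz", alpha_mid), ("CPz", alpha_mid), ("C2", alpha_mid),
                       ("CP2", alpha_mid)):
        sig[ch.index(name)] += wave
    for name in ("Cz", "CPz", "C2", "C4", "CP2", "CP4"):
        sig[ch.index(name)] += beta
    sig[ch.index("Cz")] += gamma
    # laser-evoked potentials: N1 contralateral-central (C4, not on the Fz
    # reference), N2/P2 at the vertex with spread to neighbours
    sig[ch.index("C4")] += n1
    vertex = n2 + p2
    sig[ch.index("Cz")] += vertex
    for name in ("CPz", "C2", "CP2"):
        sig[ch.index(name)] += 0.8 * vertex
    return sig


def _make_events(table: pd.DataFrame, session: np.ndarray) -> pd.DataFrame:
    ev = table.reset_index(drop=True).copy()
    ev["stim_onset"] = 0.0
    ev["fixation_onset"] = T_FIXATION
    ev["session"] = session
    return ev


def generate_dataset(cfg: SimConfig, subjects: list[int] | None = None,
                     include_sham_eeg: bool = True) -> dict[int, dict[str, TrialSet]]:
    """Synthesize full EEG for each subject and condition.

    Returns ``{subject: {"verum": TrialSet, "sham": TrialSet}}``.  Verum
    trials carry the feedback traces produced by running the real-time engine
    on the synthesized EEG.  Sham trials have independently generated EEG and
    replay the verum traces of the *previous* subject (yoked feedback); the
    first subject replays a dedicated "participant zero" verum run that is
    not part of the cohort.

    ``subjects`` restricts generation to a subset (seeding is per-subject, so
    results match a full-cohort run).
    """
    fs = cfg.sampling_rate
    times = np.arange(T_FIXATION, T_END, 1.0 / fs)
    rngs = _subject_rngs(cfg, extra=1)
    p0_rng = rngs[-1]
    if subjects is None:
        subjects = list(range(cfg.n_subjects))

    def _verum_run(rng: np.random.Generator, table: pd.DataFrame, subject: int):
        ver = table[table["feedback"] == "verum"]
        sigs, vis, aai_tr, rew = [], [], [], []
        for _, row in ver.iterrows():
            sig = _synth_trial(cfg, rng, times, row["aai_target"])
            sigs.append(sig)
            reg_sig = sig[:, (times >= T_REGULATION) & (times < T_STIM)]
            fb = realtime.run_feedback_loop(reg_sig, cfg.channel_names,
                                            Condition(row["attention"]), fs=fs)
            vis.append(fb.visibility)
            aai_tr.append(fb.series.aai)
            rew.append(fb.reward)
        ts = TrialSet(np.asarray(sigs), times, cfg.channel_names, fs,
                      _make_events(ver, np.ones(len(ver), dtype=int)),
                      np.asarray(vis), np.asarray(aai_tr), np.asarray(rew))
        return ts

    # participant zero: verum-only donor for the first subject's sham
    donor = _verum_run(p0_rng, _subject_trials(cfg, p0_rng, -1), -1)
    out: dict[int, dict[str, TrialSet]] = {}
    for j in range(max(subjects) + 1):
        rng = rngs[j]
        table = _subject_trials(cfg, rng, j)
        verum = _verum_run(rng, table, j)
        entry: dict[str, TrialSet] = {"verum": verum}
        if include_sham_eeg:
            entry["sham"] = generate_yoked_sham(donor, cfg, table, rng, times)
        if j in subjects:
            out[j] = entry
        donor = verum
    return out


def generate_yoked_sham(verum: TrialSet, cfg: SimConfig, recipient_table: pd.DataFrame,
                        rng: np.random.Generator, times: np.ndarray | None = None) -> TrialSet:
    """Sham trials: independent EEG, donor's feedback trace replayed.

    ``recipient_table`` holds the sham rows of the recipient's trial table;
    the donor must provide one verum trial per recipient sham trial of the
    same attention condition.
    """
    if times is None:
        times = verum.times
    sham = recipient_table[recipient_table["feedback"] == "sham"]
    sigs, vis, aai_tr, rew = [], [], [], []
    for att in ("ART", "ALT"):
        rec = sham[sham["attention"] == att]
        don_idx = np.flatnonzero(verum.events["attention"].to_numpy() == att)
        if len(rec) != don_idx.size:
            raise ValueError("trial-count mismatch between donor and recipient")
        for k, (_, row) in enumerate(rec.iterrows()):
            sig = _synth_trial(cfg, rng, times, row["aai_target"])
            sigs.append(sig)
            reg_sig = sig[:, (times >= T_REGULATION) & (times < T_STIM)]
            fb = realtime.run_feedback_loop(
                reg_sig, cfg.channel_names, Condition(att), fs=cfg.sampling_rate,
                replay_visibility=verum.visibility[don_idx[k]])
            vis.append(fb.visibility)
            aai_tr.append(fb.series.aai)
            rew.append(verum.rewards[don_idx[k]])  # yoked: reward replayed too
    # generated arrays are grouped ART-then-ALT; restore recipient row order
    sham_att = sham["attention"].to_numpy()
    gen_order = np.concatenate([np.flatnonzero(sham_att == "ART"),
                                np.flatnonzero(sham_att == "ALT")])
    inv = np.argsort(gen_order)
    events = _make_events(sham, np.full(len(sham), 2, dtype=int))
    return TrialSet(np.asarray(sigs)[inv], times, cfg.channel_names, cfg.sampling_rate,
                    events, np.asarray(vis)[inv], np.asarray(aai_tr)[inv],
                    np.asarray(rew)[inv])
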