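import numpy as np
import pandas as pd
import pytest

from alphapain import synthdata as sd
from alphapain.synthdata import TrialSet

MONTAGE = list(sd.REQUIRED_CHANNELS)


@pytest.fixture(scope="session")
def montage():
    return MONTAGE


def make_trialset(signal, fs=500.0, t_start=-18.0, ratings=None, attention=None,
                  feedback="verum", subject=0):
    """Minimal TrialSet around a raw (n_trials, n_ch, n_samp) array."""
    n_trials, _, n_samp = signal.shape
    times = t_start + np.arange(n_samp) / fs
    half = ["first" if k < n_trials // 2 else "second" for k in range(n_trials)]
    events = pd.DataFrame({
        "subject": subject,
        "attention": attention if attention is not None else ["ART"] * n_trials,
        "feedback": feedback,
        "trial": np.arange(n_trials),
        "half": half,
        "rating": ratings if ratings is not None else np.full(n_trials, 50.0),
        "stim_onset": 0.0,
        "fixation_onset": t_start,
        "session": 1,
    })
    n_steps = 141
    return TrialSet(signal=signal, times=times, channels=tuple(MONTAGE), fs=fs,
                    events=events, visibility=np.zeros((n_trials, n_steps)),
                    aai_trace=np.zeros((n_trials, n_steps)),
                    rewards=np.zeros(n_trials))


@pytest.fixture(scope="session")
def small_eeg_dataset():
    """One subject, 4 trials per condition, full EEG with verum + yoked sham."""
    cfg = sd.SimConfig(n_subjects=1, n_trials_per_condition=4, seed=11)
    return cfg, sd.generate_dataset(cfg)
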