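"""Offline feature-extraction tests.

Oracles: template injection into noise-free or white-noise trials with known
amplitudes, latencies and band content; equivalence of the offline epoching
path with the real-time engine on identical data; direct evaluation of the
printed exclusion rules and control indices.
"""

import numpy as np
import pandas as pd
import pytest

from alphapain import features as ft
from alphapain import realtime as rt
from alphapain import synthdata as sd
from conftest import make_trialset

FS = 500.0
MONTAGE = list(sd.REQUIRED_CHANNELS)


def _blank_trials(n_trials, t_start=-18.0, t_end=2.0, noise=0.0, seed=0):
    n = int(round((t_end - t_start) * FS))
    rng = np.random.default_rng(seed)
    sig = noise * rng.standard_normal((n_trials, len(MONTAGE), n))
    return sig, t_start + np.arange(n) / FS


class TestEpoching:
    def test_twelve_seconds_yield_111_epochs(self):
        assert ft.epoch_starts().size == 111
        assert ft.epoch_starts()[0] == pytest.approx(-12.0)
        assert ft.epoch_starts()[-1] == pytest.approx(-1.0)

    def test_offline_equals_realtime_mean(self):
        """Offline trial AAI == mean of the realtime per-step AAIs (same data)."""
        rng = np.random.default_rng(7)
        sig, times = _blank_trials(1, noise=1.0, seed=7)
        t = times
        lat = 0.4 * np.sin(2 * np.pi * 10 * t)
        for c in ("C4", "CP4", "CP6"):
            sig[0, MONTAGE.index(c)] += 5.0 * np.sin(2 * np.pi * 10 * t + 0.2)
        for c in ("C3", "CP3", "CP5"):
            sig[0, MONTAGE.index(c)] += 3.0 * np.sin(2 * np.pi * 10 * t + 1.4)
        offline, used, reason = ft.extract_trial_aai(sig[0], times, MONTAGE, FS)
        assert used == 111 and reason == ""
        reg = sig[0][:, (times >= -15.0) & (times < 0.0)]
        res = rt.run_feedback_loop(reg, MONTAGE, rt.Condition.ART, fs=FS)
        assert offline == pytest.approx(res.series.aai[-111:].mean(), abs=1e-6)

    def test_majority_artefact_rule(self):
        sig, times = _blank_trials(1, noise=1.0, seed=1)
        mask = np.zeros(times.size, dtype=bool)
        # corrupt 60 of the 111 epochs: samples covering starts -12 .. -6.1
        mask[(times >= -11.5) & (times < -5.6)] = True
        aai, used, reason = ft.extract_trial_aai(sig[0], times, MONTAGE, FS, mask)
        assert np.isnan(aai)
        assert reason == "artefact_fraction_gt_50"

    def test_stationary_lateralization_recovered(self):
        """Generated EEG with known target asymmetry: offline AAI within 0.05."""
        errs = []
        for seed in range(10):
            cfg = sd.SimConfig(n_subjects=1, n_trials_per_condition=1,
                               noise_sd=1.0, aai_trial_sd=0.0, aai_baseline_sd=0.0,
                               attention_effect=2.0, neurofeedback_gain=0.0,
                               time_slope=0.0, seed=seed)
            data = sd.generate_dataset(cfg, include_sham_eeg=False)
            ts = data[0]["verum"]
            for i in range(ts.n_trials):
                target = ts.events["aai_target"].iloc[i]
                aai, _, _ = ft.extract_trial_aai(ts.signal[i], ts.times, ts.channels, ts.fs)
                errs.append(abs(aai - target))
        assert np.median(errs) < 0.05


class TestEvoked:
    def test_injected_template_recovered(self):
        sig, times = _blank_trials(6)
        # oscillatory (band-limited) vertex deflection peaking at 220 ms
        wave = (-8.0 * np.exp(-0.5 * ((times - 0.22) / 0.08) ** 2)
                * np.cos(2 * np.pi * 5 * (times - 0.22)))
        sig[:, MONTAGE.index("Cz"), :] += wave
        ts = make_trialset(sig)
        spec = [s for s in ft.ERP_SPECS if s.name == "N2"][0]
        amps, lat = ft.quantify_evoked(ts, spec)
        assert lat == pytest.approx(0.22, abs=0.01)
        assert np.all(np.abs(amps - (-8.0)) < 1.0)

    def test_n1_uses_fz_reference(self):
        sig, times = _blank_trials(4)
        wave = -3.0 * np.exp(-0.5 * ((times - 0.16) / 0.02) ** 2)
        # identical deflection on C4 and Fz cancels under re-referencing
        sig[:, MONTAGE.index("C4"), :] += wave
        sig[:, MONTAGE.index("Fz"), :] += wave
        ts = make_trialset(sig)
        spec = [s for s in ft.ERP_SPECS if s.name == "N1"][0]
        amps, _ = ft.quantify_evoked(ts, spec)
        assert np.all(np.abs(amps) < 0.3)

    def test_null_signal_gives_null_amplitudes(self):
        sig, _ = _blank_trials(4)
        ts = make_trialset(sig)
        for spec in ft.ERP_SPECS:
            with pytest.warns(UserWarning, match="extremum"):
                amps, _ = ft.quantify_evoked(ts, spec)
            assert np.all(np.abs(amps) < 1e-9)

    def test_latency_invariant_to_trial_order(self):
        sig, times = _blank_trials(8, noise=2.0, seed=3)
        sig[:, MONTAGE.index("Cz"), :] += 10.0 * np.exp(
            -0.5 * ((times - 0.35) / 0.06) ** 2)
        ts = make_trialset(sig)
        perm = np.random.default_rng(0).permutation(8)
        ts_perm = make_trialset(sig[perm])
        spec = [s for s in ft.ERP_SPECS if s.name == "P2"][0]
        _, lat1 = ft.quantify_evoked(ts, spec)
        _, lat2 = ft.quantify_evoked(ts_perm, spec)
        assert lat1 == lat2


class TestOscillatory:
    def test_gamma_burst_elevates_gamma_feature(self):
        sig, times = _blank_trials(16, noise=1.0, seed=4)
        burst = np.sin(2 * np.pi * 80 * times) * np.exp(-0.5 * ((times - 0.25) / 0.05) ** 2)
        sig[:8, MONTAGE.index("Cz"), :] += 3.0 * burst
        osc = ft.quantify_oscillatory(make_trialset(sig))
        assert osc["gamma"][:8].mean() >= 3.0 * osc["gamma"][8:].mean()

    def test_poststim_alpha_suppression_detected(self):
        sig, times = _blank_trials(4, noise=0.5, seed=5)
        alpha = np.sin(2 * np.pi * 10 * times)
        gate = np.where((times >= 0.4) & (times <= 1.0), 0.2, 1.0)
        for c in ft.ALPHA_BETA_CHANNELS:
            sig[:, MONTAGE.index(c), :] += 4.0 * alpha * gate
        ts = make_trialset(sig)
        osc = ft.quantify_oscillatory(ts)
        # reference: same analysis on a pre-stimulus copy of the signal
        pre = ft._sliding_band_power(sig[:, MONTAGE.index("Cz"), :], FS, times,
                                     0.5, 0.02, (8.0, 12.0), (-2.0, -1.6))
        assert np.all(osc["alpha"].to_numpy() < pre)

    def test_white_noise_uncorrelated_with_labels(self):
        sig, _ = _blank_trials(160, t_start=-18.0, t_end=2.0, noise=1.0, seed=6)
        labels = np.tile([0, 1], 80)
        osc = ft.quantify_oscillatory(make_trialset(sig))
        for band in ("alpha", "beta", "gamma"):
            r = np.corrcoef(osc[band], labels)[0, 1]
            assert abs(r) < 0.2


class TestExclusions:
    def _table(self):
        return pd.DataFrame({
            "subject": [0] * 4 + [1] * 4,
            "attention": ["ART", "ART", "ALT", "ALT"] * 2,
            "feedback": ["verum", "sham"] * 4,
            "trial": range(8),
            "rating": [50, 101, 30, 40, 50, 60, 70, np.nan],
            "artefact_fraction": [0.0, 0.0, 0.6, 0.0, 0.1, 0.0, 0.0, 0.0],
            "artefact_in_baseline": [False] * 8,
            "artefact_in_poststim": [False, False, False, True] + [False] * 4,
            "wrong_hand": [False] * 8,
            "reason": [""] * 8,
        })

    def test_invalid_rating_excluded_everywhere(self):
        out = ft.apply_exclusions(self._table(), min_trials=0)
        assert not out.loc[1, "include"]
        assert out.loc[1, "reason"] == "invalid_rating"
        assert not out.loc[7, "include"]

    def test_artefact_fraction_rule(self):
        out = ft.apply_exclusions(self._table(), min_trials=0)
        assert not out.loc[2, "include"]

    def test_poststim_artefact_drops_erp_only(self):
        out = ft.apply_exclusions(self._table(), min_trials=0)
        assert out.loc[3, "include"]
        assert not out.loc[3, "include_erp"]

    def test_min_trials_per_condition_excludes_subject(self):
        tab = self._table()
        out = ft.apply_exclusions(tab, min_trials=2)
        # subject 0 retains <2 trials in several cells -> whole subject out
        assert not out.loc[out["subject"] == 0, "include"].any()

    def test_exclusion_monotone_under_added_artefacts(self):
        tab = self._table()
        base = ft.apply_exclusions(tab, min_trials=0)["include"]
        worse = tab.copy()
        worse.loc[0, "artefact_fraction"] = 0.9
        after = ft.apply_exclusions(worse, min_trials=0)["include"]
        assert np.all(after <= base)

    def test_wrong_hand_excludes_subject(self):
        tab = self._table()
        tab.loc[4, "wrong_hand"] = True
        out = ft.apply_exclusions(tab, min_trials=0)
        assert not out.loc[out["subject"] == 1, "include"].any()


class TestControlIndex:
    @pytest.mark.parametrize("v, s, expected", [
        (3, 3, 0.0),
        (3, 1, 0.5),
        (80, 40, 1 / 3),
    ])
    def test_normalized_difference(self, v, s, expected):
        assert ft.control_index(v, s) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        assert np.isnan(ft.control_index(0, 0))


def test_feature_table_roundtrip_on_generated_data(small_eeg_dataset, tmp_path):
    from alphapain import io as apio

    _, data = small_eeg_dataset
    tab = ft.build_feature_table(data[0]["verum"])
    assert {"aai", "n1", "n2", "p2", "alpha", "beta", "gamma", "rating"} <= set(tab.columns)
    assert tab["aai"].between(-1, 1).all()
    out = ft.apply_exclusions(tab, min_trials=1)
    p = apio.write_feature_table(tmp_path / "features.tsv", out)
    back = apio.read_feature_table(p)
    assert len(back) == len(out)
    np.testing.assert_allclose(back["aai"], out["aai"], atol=1e-9)
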