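"""Feedback-engine unit and property tests.

Oracles: the asymmetry index is checked against hand-constructed amplitude
ratios; the temporal smoother against brute-force trapezoid quadrature of
its defining integral at 1 ms resolution; the scrambler against conservation
laws that hold exactly for pure phase perturbations.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphapain import realtime as rt
from alphapain.realtime import AAISeries, Condition, VisibilityParams
from alphapain.synthdata import REQUIRED_CHANNELS

FS = 500.0


def _alpha_window(montage, amp_right, amp_left, freq=10.0, phase=0.3):
    t = np.arange(0, 1, 1 / FS)
    sig = np.zeros((len(montage), t.size))
    for c in ("C4", "CP4", "CP6"):
        sig[montage.index(c)] = amp_right * np.sin(2 * np.pi * freq * t + phase)
    for c in ("C3", "CP3", "CP5"):
        sig[montage.index(c)] = amp_left * np.sin(2 * np.pi * freq * t + 1.1)
    return sig


class TestComputeAai:
    @pytest.mark.parametrize("amp_r, amp_l, expected", [
        (3.0, 3.0, 0.0),            # mirror-symmetric -> 0
        (4.0, 0.0, 1.0),            # purely right-lateralized -> +1
        (0.0, 4.0, -1.0),           # purely left-lateralized -> -1
        (np.sqrt(2.0), 1.0, 1 / 3),  # power ratio 2:1 -> (2-1)/(2+1)
    ])
    def test_constructed_lateralization(self, montage, amp_r, amp_l, expected):
        sig = _alpha_window(montage, amp_r, amp_l)
        assert rt.compute_aai(sig, montage) == pytest.approx(expected, abs=1e-6)

    def test_zero_power_signalled(self, montage):
        with pytest.raises(rt.ZeroPowerError):
            rt.compute_aai(np.zeros((len(montage), 500)), montage)

    def test_dc_offset_removed_by_demeaning(self, montage):
        sig = _alpha_window(montage, 2.0, 2.0)
        base = rt.compute_aai(sig, montage)
        assert rt.compute_aai(sig + 40.0, montage) == pytest.approx(base, abs=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        montage = list(REQUIRED_CHANNELS)
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((len(montage), 500))
        a = rt.compute_aai(sig, montage)
        assert rt.compute_aai(sig * scale, montage) == pytest.approx(a, abs=1e-9)

    def test_missing_channel_rejected(self, montage):
        bad = [c for c in montage if c != "CP6"]
        with pytest.raises(ValueError, match="CP6"):
            rt.compute_aai(np.ones((len(bad), 500)), bad)


def _trapezoid_oracle(t, a, ti, delta_tau=3.0, dt=1e-3):
    """1 ms trapezoid quadrature of the smoothing integral with renormalization."""
    if ti - t[0] < dt:
        return float(np.interp(ti, t, a))
    tau = np.arange(0.0, min(delta_tau, ti - t[0]) + dt / 2, dt)
    w = 2 * (delta_tau - tau) / delta_tau ** 2
    vals = np.interp(ti - tau, t, a)
    return np.trapezoid(vals * w, tau) / np.trapezoid(w, tau)


class TestSmoothAai:
    def test_constant_series_fixed_point(self):
        t = 1.0 + 0.1 * np.arange(60)
        out = rt.smooth_aai(AAISeries(t, np.full(60, 0.37)))
        assert np.allclose(out.smoothed, 0.37, atol=1e-12)

    def test_first_sample_equals_raw(self):
        t = 1.0 + 0.1 * np.arange(10)
        a = np.linspace(-0.5, 0.5, 10)
        out = rt.smooth_aai(AAISeries(t, a))
        assert out.smoothed[0] == pytest.approx(a[0])

    @pytest.mark.parametrize("kind", ["step", "ramp", "noise"])
    def test_matches_trapezoid_quadrature(self, kind):
        t = 1.0 + 0.1 * np.arange(80)
        if kind == "step":
            a = np.where(t > t[-1] - 1.5, 1.0, 0.0)
        elif kind == "ramp":
            a = np.linspace(-1, 1, t.size)
        else:
            a = np.random.default_rng(3).uniform(-1, 1, t.size)
        out = rt.smooth_aai(AAISeries(t, a))
        for i in (0, 5, 29, 40, 79):
            assert out.smoothed[i] == pytest.approx(
                _trapezoid_oracle(t, a, t[i]), abs=1e-4)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-1, 1, 70)
        t = 1.0 + 0.1 * np.arange(70)
        base = rt.smooth_aai(AAISeries(t, a)).smoothed
        shifted = rt.smooth_aai(AAISeries(t + 5.0, a)).smoothed
        assert np.allclose(base, shifted, atol=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rt.smooth_aai(AAISeries(np.array([]), np.array([])))


class TestVisibility:
    @pytest.mark.parametrize("cond, aai, expected", [
        (Condition.ART, 0.7, 1.0),     # beyond saturation
        (Condition.ART, -0.7, 0.0),    # beyond opposite saturation
        (Condition.ART, 0.0, 0.2),     # floor
        (Condition.ART, 0.3, 0.6),     # rewarded slope 4/3
        (Condition.ART, -0.3, 0.1),    # punished slope -1/3
        (Condition.ALT, -0.3, 0.6),    # mirrored rewarded side
        (Condition.ALT, 0.3, 0.1),
        (Condition.ALT, -0.7, 1.0),
        (Condition.ART, 0.6, 1.0),     # continuous at saturation
        (Condition.ART, -0.6, 0.0),
    ])
    def test_printed_piecewise_cases(self, cond, aai, expected):
        assert rt.visibility(aai, VisibilityParams(condition=cond)) == pytest.approx(expected)

    @given(a=st.floats(-1.0, 1.0), b=st.floats(-1.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_aai(self, a, b):
        lo, hi = min(a, b), max(a, b)
        art = VisibilityParams(condition=Condition.ART)
        alt = VisibilityParams(condition=Condition.ALT)
        assert rt.visibility(lo, art) <= rt.visibility(hi, art) + 1e-12
        assert rt.visibility(lo, alt) >= rt.visibility(hi, alt) - 1e-12


class TestScramble:
    def test_energy_conserved(self):
        rng = np.random.default_rng(2)
        img = rng.random((48, 40)) * 255
        state = rt.make_scramble_state(img, rng)
        for c in (0.0, 0.4, 0.9):
            out = rt.scramble_image(img, c, state)
            e_in = np.sum((img - img.mean()) ** 2)
            e_out = np.sum((out - out.mean()) ** 2)
            assert e_out == pytest.approx(e_in, rel=1e-6)

    def test_excluded_low_frequencies_unperturbed(self):
        rng = np.random.default_rng(4)
        img = rng.random((32, 32))
        state = rt.make_scramble_state(img, rng)
        assert np.all(state.delta_phi[state.excluded] == 0.0)
        spec_in = np.fft.fft2(img - img.mean())
        spec_out = np.fft.fft2(rt.scramble_image(img, 0.0, state) - img.mean())
        assert np.allclose(spec_out[state.excluded], spec_in[state.excluded], atol=1e-8)

    def test_phase_antisymmetry(self):
        rng = np.random.default_rng(6)
        state = rt.make_scramble_state(np.zeros((17, 24)), rng)
        dphi = state.delta_phi
        rolled = -dphi[(-np.arange(17)) % 17][:, (-np.arange(24)) % 24]
        assert np.allclose(dphi, rolled, atol=1e-12)

    def test_non_2d_input_rejected(self):
        state = rt.make_scramble_state(np.zeros((8, 8)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            rt.scramble_image(np.zeros(8), 0.5, state)
        with pytest.raises(ValueError):
            rt.scramble_image(np.zeros((8, 8), dtype=complex), 0.5, state)


class TestReward:
    @pytest.mark.parametrize("cond, aai, expected", [
        (Condition.ART, -0.2, 0.0),    # no reward for the punished side
        (Condition.ART, 0.0, 0.0),
        (Condition.ART, 0.3, 0.125),   # halfway up the ramp
        (Condition.ART, 0.6, 0.25),    # ramp cap
        (Condition.ART, 0.7, 0.50),    # cap + bonus
        (Condition.ALT, -0.3, 0.125),  # mirrored
        (Condition.ALT, -0.7, 0.50),
        (Condition.ALT, 0.5, 0.0),
    ])
    def test_reward_schedule(self, cond, aai, expected):
        assert rt.compute_reward(aai, cond) == pytest.approx(expected)


class TestFeedbackLoop:
    def test_standard_period_has_141_steps(self, montage):
        rng = np.random.default_rng(1)
        stream = rng.standard_normal((len(montage), int(15 * FS)))
        res = rt.run_feedback_loop(stream, montage, Condition.ART)
        assert len(res.series) == 141
        assert res.series.timestamps[0] == pytest.approx(1.0)
        assert res.series.timestamps[-1] == pytest.approx(15.0)
        assert res.visibility.shape == (141,)

    def test_stationary_input_converges_to_static_visibility(self, montage):
        t = np.arange(0, 15, 1 / FS)
        stream = np.zeros((len(montage), t.size))
        for c in ("C4", "CP4", "CP6"):
            stream[montage.index(c)] = 5 * np.sin(2 * np.pi * 10 * t)
        for c in ("C3", "CP3", "CP5"):
            stream[montage.index(c)] = 1 * np.sin(2 * np.pi * 10 * t + 0.7)
        res = rt.run_feedback_loop(stream, montage, Condition.ART)
        static = rt.visibility(res.series.aai[-1], VisibilityParams(condition=Condition.ART))
        assert res.visibility[-1] == pytest.approx(static, abs=1e-6)

    def test_sham_mode_replays_trace(self, montage):
        rng = np.random.default_rng(3)
        stream = rng.standard_normal((len(montage), int(15 * FS)))
        replay = rng.uniform(0, 1, 141)
        res = rt.run_feedback_loop(stream, montage, Condition.ALT,
                                   replay_visibility=replay)
        np.testing.assert_array_equal(res.visibility, replay)

    def test_short_stream_rejected(self, montage):
        with pytest.raises(ValueError):
            rt.run_feedback_loop(np.zeros((len(montage), 300)), montage, Condition.ART)
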