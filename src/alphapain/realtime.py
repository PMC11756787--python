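"""Real-time neurofeedback engine.

Implements the causal processing chain that turns a multichannel EEG stream
into a visual feedback signal:

1. every 100 ms a 1,000 ms window is demeaned, Hanning-tapered and Fourier
   transformed at 1 Hz resolution; alpha power (8-12 Hz) is averaged over the
   right ({C4, CP4, CP6}) and left ({C3, CP3, CP5}) somatosensory channel
   groups and combined into the alpha asymmetry index
   ``AAI = (alpha_r - alpha_l) / (alpha_r + alpha_l)``;
2. the AAI series is smoothed with a trailing linear-decay kernel
   ``W(tau) = 2 (dtau - tau) / dtau**2`` over a 3 s support;
3. the smoothed value is mapped to an image-visibility coefficient
   ``c`` in [0, 1] via a condition-dependent piecewise-linear function;
4. the feedback image is rendered by perturbing the Fourier phases of a
   grayscale image proportionally to ``1 - c`` (amplitude spectrum and mean
   luminance are conserved, so only phase structure — and hence recognisable
   content — varies with performance);
5. the per-trial monetary reward is a clipped linear function of the mean AAI.

"Real time" here means causal operation on a buffered stream; there is no
hardware or rendering loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Condition",
    "AAISeries",
    "VisibilityParams",
    "ScrambleState",
    "FeedbackResult",
    "ZeroPowerError",
    "RIGHT_CHANNELS",
    "LEFT_CHANNELS",
    "compute_aai",
    "smooth_aai",
    "visibility",
    "make_scramble_state",
    "scramble_image",
    "compute_reward",
    "run_feedback_loop",
]

#: Somatosensory channel groups used for the asymmetry index.
RIGHT_CHANNELS = ("C4", "CP4", "CP6")
LEFT_CHANNELS = ("C3", "CP3", "CP5")

#: Alpha band: integer FFT bins at 1 Hz resolution, 8-12 Hz inclusive.
ALPHA_BINS_HZ = (8, 9, 10, 11, 12)

WINDOW_S = 1.0  #: analysis window length (s)
STEP_S = 0.1  #: feedback update step (s)
REGULATION_S = 15.0  #: regulation-period length (s)


class Condition(str, Enum):
    """Attention-training condition: attend-right (ART) or attend-left (ALT).

    Noxious stimuli are always delivered to the left hand; ART rewards
    positive AAI (right > left alpha power), ALT rewards negative AAI.
    """

    ART = "ART"
    ALT = "ALT"


class ZeroPowerError(ValueError):
    """Raised when total alpha power vanishes and the AAI is undefined."""


@dataclass
class AAISeries:
    """Time-indexed asymmetry values for one trial.

    ``timestamps`` are window-end times in seconds at 100 ms steps; ``aai``
    is the raw index and ``smoothed`` the kernel-filtered version; both lie
    in [-1, 1].
    """

    timestamps: np.ndarray
    aai: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.aai = np.asarray(self.aai, dtype=float)
        if self.timestamps.shape != self.aai.shape:
            raise ValueError("timestamps and aai must have equal length")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class VisibilityParams:
    """Parameters of the AAI -> visibility map.

    ``saturation`` is the |AAI| at which visibility reaches 1 on the rewarded
    side (0.6), ``floor`` the visibility at AAI = 0 (0.2).  The printed slopes
    4/3 (rewarded side) and -1/3 (punished side) follow from these defaults.
    """

    saturation: float = 0.6
    floor: float = 0.2
    condition: Condition = Condition.ART

    def __post_init__(self) -> None:
        if not 0.0 < self.saturation <= 1.0:
            raise ValueError("saturation must be in (0, 1]")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("floor must be in [0, 1)")


def _group_indices(montage: Sequence[str], group: Sequence[str]) -> np.ndarray:
    idx = []
    for name in group:
        try:
            idx.append(list(montage).index(name))
        except ValueError:
            raise ValueError(f"montage is missing required channel {name!r}") from None
    return np.asarray(idx)


def band_power(window: np.ndarray, fs: float, bins_hz: Sequence[int] = ALPHA_BINS_HZ) -> np.ndarray:
    """Per-channel mean band power of a demeaned, Hanning-tapered window.

    The window must span exactly 1 s so that FFT bins fall on integer
    frequencies (1 Hz resolution).  Returns one-sided power (arbitrary
    units proportional to uV**2) per channel, averaged over ``bins_hz``.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    n = window.shape[-1]
    if abs(n / fs - WINDOW_S) > 1e-9:
        raise ValueError(f"window must span exactly {WINDOW_S * 1e3:.0f} ms")
    demeaned = window - window.mean(axis=-1, keepdims=True)
    taper = np.hanning(n)
    spec = np.fft.rfft(demeaned * taper, axis=-1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    cols = [int(np.argmin(np.abs(freqs - f))) for f in bins_hz]
    return power[..., cols].mean(axis=-1)


def compute_aai(window: np.ndarray, montage: Sequence[str], fs: float = 500.0) -> float:
    """Alpha asymmetry index of one 1,000 ms window.

    Parameters
    ----------
    window : array, shape (n_channels, n_samples)
        Raw EEG segment (uV); must contain the six somatosensory channels.
    montage : sequence of str
        Channel name per row of ``window``.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    float
        ``(alpha_r - alpha_l) / (alpha_r + alpha_l)`` in [-1, 1].

    Raises
    ------
    ZeroPowerError
        If total alpha power is zero; the index is undefined and never
        silently reported as 0.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != len(montage):
        raise ValueError("window must be (n_channels, n_samples) matching montage")
    right = _group_indices(montage, RIGHT_CHANNELS)
    left = _group_indices(montage, LEFT_CHANNELS)
    chan_power = band_power(window, fs)
    alpha_r = float(chan_power[right].mean())
    alpha_l = float(chan_power[left].mean())
    total = alpha_r + alpha_l
    if total <= 0.0:
        raise ZeroPowerError("total alpha power is zero; AAI undefined")
    return (alpha_r - alpha_l) / total


def smooth_aai(series: AAISeries, delta_tau: float = 3.0) -> AAISeries:
    """Causal linear-decay smoothing of the AAI series.

    ``fAAI(t) = int_0^dtau AAI(t - tau) W(tau) dtau`` with
    ``W(tau) = 2 (dtau - tau) / dtau**2`` (triangular, integrates to one) and
    the discrete AAI samples joined by piecewise-linear interpolation.  Where
    the available history is shorter than ``delta_tau`` the kernel mass falling
    before the first sample is renormalized away, so the very first output
    equals the first raw sample.

    The integral of (linear signal segment) x (linear kernel) is evaluated in
    closed form per segment, i.e. the result is exact for the interpolated
    signal, not a quadrature approximation.
    """
    if len(series) == 0:
        raise ValueError("cannot smooth an empty series")
    t = series.timestamps
    a = series.aai
    out = np.empty_like(a)
    for i in range(len(a)):
        ti = t[i]
        t0 = max(t[0], ti - delta_tau)
        if ti - t[0] < 1e-12:
            out[i] = a[i]
            continue
        # integrate AAI(ti - tau) * W(tau) over tau in [0, ti - t0]
        j0 = int(np.searchsorted(t, t0, side="left"))
        knots = np.concatenate(([t0], t[j0 : i + 1])) if t[j0] > t0 else t[j0 : i + 1]
        vals = np.interp(knots, t, a)
        acc = 0.0
        norm = 0.0
        for k in range(len(knots) - 1):
            # tau runs from ti - knots[k+1] to ti - knots[k]
            ta, tb = ti - knots[k + 1], ti - knots[k]
            va, vb = vals[k + 1], vals[k]  # AAI at tau = ta, tb
            h = tb - ta
            if h <= 0:
                continue
            # AAI(ti - tau) linear in tau: v(tau) = va + (vb - va) (tau - ta)/h
            # W(tau) = 2 (dt - tau)/dt^2 ; integrate v * W on [ta, tb]
            dt = delta_tau

            def _iw(x: float) -> float:  # int W dtau
                return (2 * dt * x - x * x) / (dt * dt)

            def _iwt(x: float) -> float:  # int tau W dtau
                return (dt * x * x - 2 * x**3 / 3) / (dt * dt)

            w0 = _iw(tb) - _iw(ta)
            w1 = _iwt(tb) - _iwt(ta)
            slope = (vb - va) / h
            acc += va * w0 + slope * (w1 - ta * w0)
            norm += w0
        out[i] = acc / norm if norm > 0 else a[i]
    return AAISeries(t.copy(), a.copy(), smoothed=out)


def visibility(aai: float, params: VisibilityParams) -> float:
    """Map an AAI value to the image-visibility coefficient ``c`` in [0, 1].

    Under ART the rewarded side is positive AAI: ``c`` rises linearly from the
    floor (0.2) at AAI = 0 to 1 at +saturation and falls with slope
    -floor/saturation on the negative side, reaching 0 at -saturation.  Under
    ALT the map is mirrored.  The default parameters reproduce the printed
    cases: c = 1 beyond +-0.6, c = 0.2 + (4/3)|AAI| on the rewarded side,
    c = 0.2 - (1/3)|AAI| on the punished side, c = 0 beyond the opposite
    saturation.
    """
    a = float(aai)
    if params.condition == Condition.ALT:
        a = -a
    s, f = params.saturation, params.floor
    if a >= s:
        return 1.0
    if a >= 0.0:
        return f + (1.0 - f) / s * a
    if a > -s:
        return f - f / s * (-a)
    return 0.0


@dataclass
class ScrambleState:
    """Frozen randomness of the Fourier phase scrambler for one trial.

    ``delta_phi`` holds uniform [-pi, pi] phase perturbations with Hermitian
    antisymmetry ``delta_phi[k, l] = -delta_phi[-k, -l]`` (indices mod image
    size) so the scrambled image stays real; self-conjugate bins and the
    excluded low-frequency set carry zero perturbation.  ``image_mean`` is the
    mean luminance, removed before scrambling and restored afterwards.
    """

    delta_phi: np.ndarray
    image_mean: float
    excluded: np.ndarray = field(repr=False, default=None)  # boolean mask


def make_scramble_state(
    image: np.ndarray, rng: np.random.Generator, exclude_radius: int = 1
) -> ScrambleState:
    """Draw phase perturbations for ``image`` from ``rng``.

    Antisymmetric uniform phases are obtained as the Fourier phases of a
    white-noise image (exactly Hermitian by construction).  Components with
    ``|k| <= exclude_radius`` along both axes (DC plus the first ring by
    default) are left unperturbed: scrambling them produces a striped,
    non-stationary luminance pattern rather than uniform noise.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D matrix")
    nx, ny = image.shape
    phases = np.angle(np.fft.fft2(rng.standard_normal((nx, ny))))
    kx = np.fft.fftfreq(nx, d=1.0 / nx).astype(int)
    ky = np.fft.fftfreq(ny, d=1.0 / ny).astype(int)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    excluded = (np.abs(KX) <= exclude_radius) & (np.abs(KY) <= exclude_radius)
    # self-conjugate bins (k == -k mod n): phase must be exactly 0
    self_conj = (np.mod(2 * KX, nx) == 0) & (np.mod(2 * KY, ny) == 0)
    phases[excluded | self_conj] = 0.0
    return ScrambleState(delta_phi=phases, image_mean=float(image.mean()), excluded=excluded)


def scramble_image(image: np.ndarray, c: float, state: ScrambleState) -> np.ndarray:
    """Phase-scramble ``image`` to visibility level ``c``.

    ``I_scramb(c) = IFFT2( FFT2(I - <I>) * exp(i * delta_phi * (1 - c)) ) + <I>``.
    At c = 1 the image is returned unchanged; at c = 0 phases are fully
    randomized.  The amplitude spectrum and the mean luminance are conserved
    for every c, so low-level image statistics do not co-vary with feedback.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D matrix")
    if np.iscomplexobj(image):
        raise ValueError("image must be real-valued")
    if image.shape != state.delta_phi.shape:
        raise ValueError("state does not match image dimensions")
    if not 0.0 <= c <= 1.0:
        raise ValueError("visibility c must lie in [0, 1]")
    spec = np.fft.fft2(image - state.image_mean)
    perturbed = spec * np.exp(1j * state.delta_phi * (1.0 - c))
    out = np.fft.ifft2(perturbed)
    return out.real + state.image_mean


def compute_reward(mean_aai: float, condition: Condition) -> float:
    """Per-trial monetary reward in euros from the trial-mean raw AAI.

    ART: 0 below 0, linear 0 -> 0.25 EUR as the mean AAI goes 0 -> 0.6, plus a
    0.25 EUR bonus beyond 0.6 (total cap 0.50 EUR).  ALT mirrors on negative
    values.  The linear ramp spans [0, 0.6] so that the bonus threshold
    coincides with base-reward saturation.
    """
    a = float(mean_aai)
    if condition == Condition.ALT:
        a = -a
    if a <= 0.0:
        return 0.0
    base = 0.25 * min(a, 0.6) / 0.6
    bonus = 0.25 if a > 0.6 else 0.0
    return base + bonus


@dataclass
class FeedbackResult:
    """Output of one regulation period: AAI series, visibility trace, reward."""

    series: AAISeries
    visibility: np.ndarray
    reward: float


def run_feedback_loop(
    stream: np.ndarray,
    montage: Sequence[str],
    condition: Condition,
    fs: float = 500.0,
    duration: float = REGULATION_S,
    delta_tau: float = 3.0,
    vis_params: VisibilityParams | None = None,
    replay_visibility: np.ndarray | None = None,
) -> FeedbackResult:
    """Run the causal feedback chain over one regulation period.

    ``stream`` is a (n_channels, n_samples) buffer covering at least
    ``duration`` seconds.  Every 100 ms the trailing 1,000 ms window is
    analysed; the first update occurs once a full window is available
    (t = 1.0 s), the last at t = ``duration``, giving 141 steps for the
    standard 15 s period.  In sham (yoked) mode, ``replay_visibility``
    replaces the computed visibility trace sample-for-sample while AAI
    processing still runs on the input EEG.
    """
    stream = np.asarray(stream, dtype=float)
    n_win = int(round(WINDOW_S * fs))
    if stream.ndim != 2 or stream.shape[1] < n_win:
        raise ValueError("stream must cover at least one 1,000 ms window")
    n_steps_total = int(round((min(duration, stream.shape[1] / fs) - WINDOW_S) / STEP_S)) + 1
    if vis_params is None:
        vis_params = VisibilityParams(condition=condition)
    elif vis_params.condition != condition:
        vis_params = VisibilityParams(vis_params.saturation, vis_params.floor, condition)

    times = WINDOW_S + STEP_S * np.arange(n_steps_total)
    raw = np.empty(n_steps_total)
    step = int(round(STEP_S * fs))
    for i in range(n_steps_total):
        end = n_win + i * step
        raw[i] = compute_aai(stream[:, end - n_win : end], montage, fs)
    series = smooth_aai(AAISeries(times, raw), delta_tau=delta_tau)
    if replay_visibility is not None:
        replay_visibility = np.asarray(replay_visibility, dtype=float)
        if replay_visibility.shape != (n_steps_total,):
            raise ValueError("replay trace length does not match update steps")
        vis = replay_visibility.copy()
    else:
        vis = np.array([visibility(v, vis_params) for v in series.smoothed])
    reward = compute_reward(float(raw.mean()), condition)
    return FeedbackResult(series=series, visibility=vis, reward=reward)
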