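# Methods

This note documents the models, numerical procedures and design choices
behind `alphapain`, in the order data flows through the package.

## 1. The real-time feedback chain

### Asymmetry index

Each 1,000 ms window is demeaned per channel, multiplied by a Hann taper and
Fourier transformed; with a 1 s window the FFT bins fall on integer
frequencies, and alpha power is the mean one-sided power over the bins
8, 9, 10, 11, 12 Hz. Right/left somatosensory power is the mean over
{C4, CP4, CP6} and {C3, CP3, CP5}; the index is the normalized difference
(α_r − α_l)/(α_r + α_l). Two contracts matter numerically: the index is
invariant under uniform rescaling of all channels (the scale cancels), and a
window with zero total alpha power raises `ZeroPowerError` rather than
returning 0 — a silent 0 would masquerade as "perfectly symmetric".

### Temporal smoothing

The feedback signal is fAAI(t) = ∫₀^Δτ AAI(t−τ) W(τ) dτ with the linear
kernel W(τ) = 2(Δτ−τ)/Δτ², Δτ = 3 s (configurable), and the sampled AAI
joined by piecewise-linear interpolation. Because both factors are piecewise
linear, each inter-sample segment contributes the integral of a quadratic,
which we evaluate in closed form — the smoother is exact for the
interpolated signal rather than a quadrature approximation (tests verify it
against 1 ms trapezoid quadrature to 1e-4). At trial onset, when less than
Δτ of history exists, the kernel mass before the first sample is
renormalized away; consequently the first smoothed value equals the first
raw value. This choice (rather than zero-padding) avoids a spurious
ramp-in of the feedback image at the start of every trial.

### Visibility map and reward

Visibility is piecewise linear in the smoothed index: floor 0.2 at AAI = 0,
saturating at 1 when the rewarded-side index reaches 0.6, falling with slope
floor/saturation on the punished side and clamped at 0 beyond −0.6; under
attend-left (ALT) the map is mirrored. The reward ramp is under-determined
by its verbal description ("linear increase from 0–0.25 €" for rewarded-side
index values); we map [0, 0.6] → [0, 0.25] € so that the 0.25 € bonus
threshold coincides with base-reward saturation, capping a trial at 0.50 €.
Whether the trial reward uses the raw or the smoothed index is likewise
open; we use the raw per-window mean, as the smoothed series is a display
convenience.

### Phase scrambling

Images are scrambled by multiplying the FFT of the demeaned image with
exp(iΔφ(1−c)) and inverting. The perturbation angles are the Fourier phases
of a white-noise image: this yields uniform angles with the Hermitian
antisymmetry Δφ(k, l) = −Δφ(−k, −l) exactly, so the output is real.
Self-conjugate bins (where k ≡ −k mod n) must carry zero perturbation and
are forced to 0. The lowest spatial frequencies (|k| ≤ 1 on both axes,
i.e. DC plus the first ring) are excluded from perturbation; scrambling them
produces horizontal/vertical stripe artefacts rather than uniform noise.
Because the perturbation is pure phase, the amplitude spectrum, the total
energy of the demeaned image (Parseval) and the mean luminance are conserved
at every c — properties the tests assert to 1e-6/1e-9.

## 2. Synthetic data

The generator operates at two tiers that share one hierarchical trial model
and per-subject random substreams (spawned from a single seed, so a cohort
can grow without reshuffling existing subjects).

**Trial model.** For subject j, condition side s (+1 ART, −1 ALT), feedback
arm v (1 verum, 0 sham) and trial k:

```
aai_jk = μ_j + s·θ_att,j/2 + s·v·θ_nf,j/2 + s·γ·(k − (T−1)/2) + ε_jk
rating_jk = ρ + ρ_j + β_X·x_jk + β_M·aai_jk + η_jk,  clipped to [0, 100]
```

with μ_j ~ N(0, 0.10), θ_att,j ~ N(d_att·σ, σ), θ_nf,j ~ N(d_nf·σ, σ),
σ = 0.15, trial noise ε ~ N(0, 0.20), γ the per-trial drift (default 0.002),
rating noise η ~ N(0, 12) and x the condition code (ART = −1, ALT = +1).
Effects are specified in Cohen's-d units of the paired subject-level
contrast and mapped to index units through σ, the between-subject effect
SD; with 40 trials per condition the empirical paired d is ≈ 0.96 of the
nominal value (trial noise dilutes it slightly), well inside the calibration
band the tests check. No published raw-index effect magnitudes exist for
this paradigm, so σ and the noise levels were fixed once to produce
index distributions of realistic width (subject means within roughly
±0.3); they are not tuned per test. The default β_X = β_M = 0 is the
null pain model. Note the sign convention: the hypothesized analgesic
mechanism — more right-hemisphere alpha, less left-hand pain — corresponds
to a *negative* β_M; positive-control simulations therefore use β_M < 0,
matching the reversed contrast directions of the rating pipeline.

**Waveform tier.** `generate_dataset` synthesizes EEG per trial (−18 s to
+2 s around the stimulus at 500 Hz): pink-noise background (8 µV RMS), a
10 Hz rhythm whose right/left group amplitudes are √(1±a)-scaled so the
window-FFT index recovers the target a, a 20 Hz central rhythm,
post-stimulus alpha/beta amplitude suppression (0.3–1.2 s), a Gaussian
80 Hz burst at Cz (150–350 ms), and Gaussian-envelope evoked deflections
(N1 at C4 160 ms, N2/P2 at the vertex 220/350 ms, −3/−8/+10 µV). Verum
trials are run through the actual real-time engine to produce feedback
traces; sham trials carry independently generated EEG while replaying the
previous subject's verum trace (a dedicated "participant-zero" run seeds
the chain). The waveform tier is used for signal-level tests at small trial
counts; cohort-scale simulation studies (decision-pipeline and mediation
recovery at 40 subjects × 20 seeds) draw from the trial model directly,
which is statistically identical for those analyses and orders of magnitude
cheaper.

**What the generator does not emulate:** volume conduction and realistic
channel covariance, eye/muscle artefact morphology (artefacts are modelled
only as amplitude outliers for exercising the threshold mask), non-Gaussian
rating distributions, habituation of evoked responses, and any dependence
of the EEG on the displayed feedback (no closed loop). Passing tests
therefore demonstrate correctness of the analysis code under the assumed
statistical structure, not robustness to real-data pathologies.

## 3. Feature extraction

Offline AAI uses 1 s epochs at 100 ms stride over the last 12 s of the
regulation period ([−12, 0) s; 111 epochs), anchored so that each offline
epoch coincides sample-for-sample with a real-time window — an invariant
the tests check to 1e-6. Trials lose their AAI when more than 50% of epochs
are artefact-marked. Evoked potentials: zero-phase 4th-order Butterworth
1–30 Hz (applied forward-backward so peak latencies are unbiased), baseline
2.0–2.5 s after fixation onset (fixation is emitted at −18 s), group-average
peak search in the component windows (N1 120–200 ms at C4 re-referenced to
Fz; N2 180–300 ms and P2 250–500 ms at Cz), then single-trial means over a
30 ms window at the group latency. When no interior local extremum exists
the window-edge extremum is used with a warning. Oscillatory responses use a
1 Hz high-pass plus 41–51 Hz band-stop, Hann sliding windows (500 ms/20 ms
for alpha and beta, averaged 500–900 ms over {Cz, CPz, C2, C4, CP2, CP4};
250 ms/20 ms for gamma 70–90 Hz, 150–350 ms at Cz); powers are one-sided
spectra in µV², consistent with the real-time path. Exclusion rules are
total functions producing flags and reason codes; artefacts inside the
baseline or the 1,500 ms post-stimulus guard interval drop a trial from
evoked/oscillatory features while its regulation-period AAI survives.

## 4. Bayes factors

The paired-test Bayes factor uses the JZS setup: δ ~ Cauchy(0, r),
r = √2/2, truncated to the tested direction, against the point null. With
the data reduced to (t, n), BF₁₀ = m₁(t)/m₀(t) where m₁ integrates the
noncentral-t density over the truncated prior. Substituting δ = r·tanθ
turns the Cauchy weight into a flat measure on θ, and 256-node
Gauss–Legendre quadrature on θ evaluates the integral essentially to
machine precision (the two-sided case agrees with an independent
implementation to 1e-13; the one-sided case agrees with a quadrature oracle
built on Rouder's g-representation to well under 1%). Posterior summaries
of δ come from trapezoid integration on an adaptive grid. Degenerate inputs
(zero variance) are flagged and handled by limits rather than erroring or
fabricating a value. The rank-based analogue augments the observed signs
and |difference| ranks with latent N(δ, 1) variables (Gibbs over truncated
normals), samples δ under the truncated Cauchy prior by inverse-CDF on a
grid, and estimates BF₀₁ by a Rao-Blackwellized Savage–Dickey ratio — the
posterior density at δ = 0 given the latent data is available in closed
form up to a 1-D quadrature, so no kernel density estimate is needed. Only
ranks and signs enter, so the statistic is invariant under strictly
increasing transformations.

## 5. Sequential design simulation

`simulate_sbf_maxn` grows each simulated study incrementally: standardized
differences ~ N(d, 1) accrue, and the one-sided BF (direction "greater") is
evaluated at n = 20, 25, …, 95 until it crosses 10 or 1/10; studies reaching
n = 95 are trichotomized at 3 and 1/3. Incremental growth (keeping early
participants) is the standard sequential-sampling interpretation; the whole
cohort of 10,000 studies is simulated as one vectorized array with running
sufficient statistics. Bayes factors inside the simulator come from a
lookup table — exact quadrature on a t-grid of step 0.05 per look size,
interpolated linearly in log BF — whose interpolation error is below 0.05%
(tested against direct evaluation; the budget is 0.5%). BF₁₀ is monotone in
t, so out-of-grid values are clamped far beyond both boundaries. A
10,000-study design runs in well under a minute after the one-off grid
build.

## 6. Adaptive decision pipeline

Per-subject means of the 8 design cells (2 sides × 2 arms × 2 halves) feed
ordered one-sided tests: time (verum second vs first half, per side),
neurofeedback (verum vs sham, per side), attention (ART vs ALT). A
two-contrast effect is "for" if either BF ≥ 3, "against" if both ≤ 1/3.
A time effect switches all later tests to second-half averages (for both
sides, even when only one side carried it); a neurofeedback effect switches
the attention contrast to sham cells only. For ratings and brain responses
the directions reverse and time is not tested (its category and the data
selection are inherited from the asymmetry run); when an asymmetry
neurofeedback effect exists, the attention contrast uses sham cells for
ratings but verum-minus-sham differences for brain responses — both
variants are also selectable explicitly via `attention_contrast`. Pattern
labels are an ordered pure function of the category triple (all three →
pattern 1; time+attention → 2; neurofeedback+attention → 3; attention → 4;
attention "against" → absence; else inconclusive), unit-tested over all 27
combinations. Boundary values BF = 3 and 1/3 classify as for/against. The
choice between the t-based and rank-based statistic is a caller flag;
`auto` applies a Shapiro–Wilk screen at α = 0.05 as a reproducible stand-in
for visual Q-Q inspection.

## 7. Multilevel mediation

The 1-1-1 model places both trial-level regressions (X→M; X,M→Y) inside a
joint subject-coefficient distribution u_j ~ N(θ, Σ) with full 5×5
covariance, so the population indirect effect ab = a·b + σ_ab includes the
a–b covariance. X is coded ART = −1 / ALT = +1 and M is centered within
person; Y stays in raw NRS units (coefficients are unit-bearing: b in NRS
per index unit), since standardizing Y would entangle subject-level scale
with the paths. Every full conditional of this Gaussian hierarchy is
conjugate, so we sample by Gibbs: batched precision-form normal draws for
all subjects at once, a normal draw for θ (prior N(0, 100²I)), an
inverse-Wishart draw for Σ (df p+2, diagonal scale matched to the native
units of each coefficient: 0.05² for the index paths, 25/9/100 for the
rating paths), and inverse-gamma draws for the residual variances
(IG(10⁻³, 10⁻³)). The conjugate scheme needs no tuning and runs 4 × 1,500
iterations in seconds; convergence is gated on split-R̂ < 1.05 of the group
paths (4 chains), and non-converged fits are flagged, never silently
summarized. An effect is "present" when 0 falls outside the central 95%
posterior interval. The verum-vs-sham moderation comparison tests
subject-level coefficients per path (ab one-sided verum > sham; others
two-sided) and is skipped with an explicit status when neither arm shows a
mediation effect — mirroring the conditional preregistered analysis.

## 8. Problem sizes and numerical conventions

Simulation studies in the test suite use cohorts of 40 subjects and 20
seeds per scenario (the trial-model tier), EEG-level checks use 1–2
subjects at 2–8 trials per condition, the design-analysis check uses 2,000
studies per hypothesis (the acceptance script uses the full 10,000), and
mediation recovery uses 40 subjects × 80 trials with 4 × (400 warm-up +
800 kept) Gibbs iterations. Ties in the signed-rank sampler release the
order constraint between tied values; ratings are clipped, not resampled,
at the scale bounds, mirroring floor/ceiling behaviour of a bounded rating
scale; all randomness flows through `numpy.random.Generator` objects seeded
explicitly.

## Known limitations

* The artefact stub is an amplitude threshold; it stands in for a full
  automatic preprocessing pipeline and makes no claim to replicate one.
* The EEG generator has no head model; channel signals are independent
  noise plus shared sources, so spatial-filtering analyses would be
  unrealistically easy on synthetic data.
* The signed-rank Bayes factor is Monte-Carlo (default 1,000 kept
  iterations); its evidence category is stable but its third digit is not.
* The inverse-Wishart prior on Σ weakly couples coefficient variances to
  the chosen scale matrix; with very few subjects (< ~15) the σ_ab posterior
  is prior-sensitive.
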