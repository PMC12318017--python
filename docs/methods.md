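# Methods

This note documents the models, parameter choices and numerical decisions
behind `teamfuse`, and what the synthetic test conditions do and do not
establish about real athlete data.

## Session model and conventions

Positions are planar pitch coordinates in metres, origin at pitch centre,
x toward team A's attacking direction. Time is seconds (float64) on one
master clock; each stream's mean transmission latency is metadata and is
corrected at fusion time, not in the raw files. Dropouts are an explicit
mask column (a dropped sample is NaN *and* masked); NaN anywhere else is a
structural error. Streams are one CSV each (`t`, named channels,
`dropout`), the manifest is JSON — inspectable, diff-able,
language-neutral.

## Synthetic sessions

The simulator is the package's test substrate and defines the study
conditions; it is not a tuning knob.

**Movement model.** Athlete *i* oscillates about a formation slot carried
by a slowly drifting centroid:
`pos_i(t) = centroid(t) + slot_i + a·(cos ψ_i, sin ψ_i)` with a = 1.5 m.
Phases follow intra-team Kuramoto dynamics
`dψ_i = ω_i dt + (κ/n) Σ_j sin(ψ_j − ψ_i) dt + σ_ψ dW`, integrated by
Euler–Maruyama at the 200 Hz frame rate. Defaults: movement-cycle
frequency ω/2π = 0.25 ± 0.03 Hz (positional sway during possession play,
period ≈ 4 s), phase diffusion σ_ψ = 0.3 rad/√s, coupling κ = 2,
centroid speed 0.5 m/s, formation spacing 8 m on a 40 × 30 m pitch. The
coupling κ is the coordination dial: the stationary phase spread scales
like σ_ψ²/κ, so the order parameter R, SSI and every synchrony indicator
have a known monotone relation to it — this is the parameter-recovery
surface the tests exploit. Perturbation events suppress κ to 10 % of its
value for 5 s, giving the perturbation-response indicator (CPR) a real
signal.

**Sensor network.** Each athlete carries five modalities sampled at
200 Hz (IMU), 10 Hz (GPS), 40 Hz (LPS), 10 Hz (heart rate) and 500 Hz
(insoles), observed as truth delayed by per-sample latency
(mean + Gaussian jitter per modality, 20–50 ms), plus Gaussian noise at
the stated accuracy of each deployed sensor class (GPS ±0.5 m / ±0.1 m/s,
LPS ±0.1 m / ±0.05 m/s, accelerometer ±0.02 g, gyroscope ±0.05 °/s, HR
±1 bpm, insole ±1.2 N) and Bernoulli dropouts (2 %). The frame rate is
200 Hz so that every divisible sensor grid is an exact subset of the
truth grid. Heart rate is emitted directly in bpm, driven by speed
through a 30 s first-order lag (simulating raw kHz ECG would add nothing
at this scale); the accelerometer channels carry the quasi-static gravity
component of trunk sway (±5° roll/pitch locked to the movement phase), so
inclination is recoverable but high-frequency impact content is not
modelled. Insole forces are per-step impulses
(`∝ max(0, ±sin ψ)²`, ≈ 700 N peak) used only for workload. RNG: one root
seed; per-stream child seeds derived by CRC-32 of (athlete, modality), so
any stream is reproducible in isolation.

**What this does not show.** The generator has no game AI, no opponent
interaction, no jumps/collisions, no GNSS multipath or UWB
non-line-of-sight error structure, and its noise is white. Passing tests
demonstrate that the algorithms recover known structure under realistic
rates/accuracies — not that the indicator values have the same dynamic
range on real match data.

**Outcome model.** Session-level outcome features (TCR, CPR, SSI, ICC)
are drawn from Gaussians around sport-plausible baselines; "win" sessions
are shifted by a configurable effect vector in per-metric SD units
(default (+1, −1, +1, +1): winners coordinate more tightly and recover
faster). This makes the exact Bayes error rate of the classifier
computable in closed form (accuracy Φ(‖shift‖/2)), which is what the
classifier is tested against.

## Sensor-level processing

Filtering is forward–backward (zero-phase) 4th-order Butterworth; default
cutoffs 12 Hz (IMU, insole), 2 Hz (positional fixes), 0.5 Hz (HR),
configurable per modality. Noise amplitude is operationalized as the RMS
of the out-of-band residual (raw − filtered) with 5 % edge trim to avoid
filtfilt transients; signal amplitude as the RMS of the mean-removed
filtered signal, so SNR is invariant to DC offset. A stream below 15 dB
is flagged for recalibration. Orientation uses three independent scalar
complementary filters (roll/pitch from accelerometer inclination, yaw
from magnetometer heading) with α = 0.98 — no quaternion algebra, which
is adequate for per-axis trunk orientation but not for large coupled
rotations.

## Alignment

DTW uses the plain recursion with steps {(1,0),(0,1),(1,1)}, no slope
weighting, both ends anchored; it is verified against an exhaustive
path-enumeration oracle on short series. Movement-cycle anchors are
prominent peaks of the dominant channel (minimum spacing half the
dominant period from the periodogram). Cross-stream correspondence is
order-based; a count mismatch beyond one event is an alignment error and
surplus trailing events are dropped symmetrically. The warp is piecewise
linear through matched anchors (unit slope outside), followed by an
interpolating B-spline (degree 3 by default; degree 1 reduces exactly to
linear interpolation) through all warped samples, evaluated on a uniform
20 Hz grid. Alignment quality is the phase coherence
`C = mean cos(φ_i − φ̄)` between Hilbert phases of the aligned and
reference signals, 5 % edges trimmed.

## Individual-level fusion

Positional fusion combines LPS and GPS (after latency correction and
dropout masking) with blockwise adaptive weights (2 s blocks):

* per block, each source's noise σ̂ is estimated from second differences
  (`Var(d²x) = 6σ²`; curvature enters only at O(Δt²), so the estimator is
  insensitive to smooth motion);
* quality q = clip(SNR_dB/30, 0, 1) (30 dB = saturated quality),
  relevance r from a modality-by-movement-state lookup (inertial sensing
  preferred above 2 m/s² mean acceleration, satellite positioning during
  steady locomotion, LPS always);
* the recursion w ← λw + (1−λ)qr (λ = 0.65) smooths q·r over blocks; the
  applied weight is w divided by the effective variance
  σ̂² + (0.1·nominal accuracy)², renormalized per block. The nominal-
  accuracy floor keeps the weights at the inverse-variance ratio when the
  noise estimate underflows (clean data), so for unbiased Gaussian
  sources the combination approaches the σ_opt = (Σσ_i⁻²)^{−1/2} optimum,
  and a degraded source loses weight through both q and σ̂.

Sources are resampled by quintic interpolating splines (resampling bias
≪ sensor noise; at 40 Hz LPS the 20 Hz grid points are exact sample
times). Where *every* positional source drops out for more than three
nominal intervals, the last fix is propagated at constant velocity.
Orientation, heart rate and cumulative insole load (trapezoidal force
integral) are carried onto the same grid. Team-level fusion stacks
records on the common grid (uniform team weights) and exposes the
centroid.

The zero-noise identity — truth in, truth out to < 10⁻⁶ m RMSE — is
checked with *all* stochastic terms off (sensor noise, latency, dropouts,
phase diffusion, frequency spread, and perturbation events, whose κ
switch kinks the dynamics); Brownian phase wiggle between 10 Hz GPS fixes
is not representable by any resampler, so the identity is a statement
about pipeline transparency, not about interpolating noise.

## Features, information, baselines

Wavelet packets (Daubechies-4, level 5, periodized) are computed on
signals zero-padded to a multiple of 2⁵ so the transform is exactly
orthogonal (perfect reconstruction, Parseval). Feature selection keeps
the top ⌈α·N⌉ coefficients by energy (α = 0.15) and records the
reconstruction error, which is non-increasing in α by nestedness. Tensor
fusion applies mode-n products (athletes × modalities × windows) via
einsum and is checked against the naive triple sum. `Q_info = I(X;F)/H(X)`
uses a plug-in estimator on 16 equal-frequency bins: deterministic,
simple, with the known positive MI bias at independence (≈ (B−1)²/2N
nats) — acceptable since Q_info is used comparatively. A constant input
has zero entropy and yields a flagged sentinel, not a number. Baseline
fusers: linear Kalman (constant-velocity model for positions; process
noise 0.5 m/s²), static Gaussian precision fusion, fixed-weight
averaging.

## Indicators

All windowed indicators use 10 s windows with 50 % overlap; an indicator
whose required events are absent in a window is NaN, never zero. The
one-line prose definitions behind the indicator system were
operationalized as follows (each threshold configurable):

* **SSI** — mean pairwise vector correlation of centred *positions*
  (centred inner product over centred norms; invariant to translation and
  joint rotation). Velocity-based correlation was rejected: in the
  coupled-oscillator model the drift term κ·sin(·) amplifies independent
  phase noise in the *rates*, making velocity correlation non-monotone in
  κ for κ > ω, while position correlation is monotone.
* **TCR** — fraction of acceleration-burst events (|a| crossing
  2 m/s²) co-occurring within 0.5 s in at least half the team.
* **FSQ** — 1/(1+CV) of pairwise inter-athlete distances in the window
  (larger = more stable formation).
* **TIE** — Shannon entropy of the pass-count distribution over ordered
  teammate pairs, normalized by log₂ of the pair count.
* **CPR** — seconds from a perturbation until SSI re-enters the mean ±1 SD
  band of the three preceding windows; unrecovered → NaN.
* **ICC** — mean vector correlation between each athlete's velocity and
  the centroid velocity.
* **DMS** — Kuramoto order parameter of all athletes' movement phases at
  decisive-action instants, averaged per window.
* **LDH** — 1 − Gini of per-athlete workload in the window (distance
  covered unless an insole-load series is supplied), so 1 = perfectly
  shared effort.
* **S_spatial** — Shannon entropy (bits) of jointly-normalized occupancy
  on an axis-aligned 6 × 4 pitch grid (per-athlete normalization
  available; the tactical reference frame is taken as the pitch frame).
* **RPM** — mean per-pair Pearson correlation between observed and
  reference inter-athlete distance series. The default reference is the
  session-mean distance pattern, which is constant and makes the
  covariance normalization degenerate; such pairs use the documented
  fallback 1 − mean|d−d_ref|/mean(d_ref), flagged in the output.
* **R(t)** — order parameter of Hilbert phases of each athlete's
  x-oscillation about their own mean position, band-passed 0.1–2 Hz, 5 %
  edges trimmed. (Subtracting the *team centroid* instead would cancel
  exactly the synchronized component and destroy the statistic.)

CRQA uses the state vector (x, y, vx, vy), threshold ε given in state
units, minimum line length 2, and block-mean coarse-graining at scales
{1, 2, 4}. Line statistics follow the standard census convention:
singleton diagonals (e.g. the two corner cells of an all-recurrent plot)
do not count toward DET.

## Performance models

The team–individual relationship is an observed-variable linear path
model `P_team = β₁C_spatial + β₂C_temporal + β₃Σw_iP_ind,i + ε` (no
latent constructs) solved by least squares, with zero-column and
condition-number (10⁸) identifiability checks; contribution weights w_i
are user-supplied (uniform default). The outcome classifier is logistic
regression on (TCR, CPR, SSI, ICC), standardized, fitted by IRLS with a
tiny ridge (10⁻⁸); complete separation — every training point beyond
margin 8 — triggers a ridge-1.0 refit with a warning. Evaluation is
leave-one-session-out, never window-level, to avoid leakage. Change
points use binary segmentation on mean shifts with penalty
3σ̂²·log n (σ̂ from the MAD of first differences), calibrated to ≤ 5 %
false positives on white noise while localizing a 3σ step within a few
samples. The early-warning engine evaluates conjunctive threshold/delta
rules over indicator windows (default: ΔSSI > 0.1 ∧ TCR > 0.5).

## Problem sizes

Test and acceptance runs use scaled-down sessions chosen as the smallest
sizes at which each statistic is stable: 2v2–5v5 teams, 20–120 s
sessions, 10–50 seeds per Monte-Carlo comparison, 6-point κ grid. The
demo is a full 4v4, 120 s session and runs in a few seconds.

## Known limitations

Orientation fusion is per-axis and small-angle; no magnetometer
calibration. The MI estimator is biased at small n. The Kalman baseline
assumes constant velocity between frames. DMS depends on which events
are labelled "decisive", which real data must supply. Inter-team (A vs B)
coordination indices and influence-network leadership analysis are out of
scope.
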