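# teamfuse

Multi-level wearable-sensor fusion and collaborative-dynamics analysis for
team sports.

Modern team-sport monitoring straps several sensors to every athlete — an
IMU on the trunk (200 Hz), a GNSS receiver (10 Hz, ±0.5 m), an
ultra-wideband local-positioning tag (40 Hz, ±0.1 m), a chest-strap
heart-rate monitor and force-sensing insoles (500 Hz). The streams arrive
at different rates, with different accuracies, transmission latencies and
dropouts. `teamfuse` integrates them in three stages and then quantifies
*team coordination* — the thing coaches actually care about — from the
fused trajectories:

1. **Sensor-level fusion (SLF)** — zero-lag 4th-order Butterworth
   filtering, SNR-based quality scoring with a 15 dB recalibration flag,
   and complementary-filter orientation
   `θ_t = α(θ_{t−1} + ω_t Δt) + (1−α)φ_t`.
2. **Individual-level fusion (ILF)** — per-athlete state estimation on a
   common 20 Hz clock. Positional sources are combined with adaptive
   weights `w_{i,t} = λ·w_{i,t−1} + (1−λ)·q_{i,t}·r_{i,t}` (λ = 0.65),
   where `q` is the signal-quality score and `r` a contextual relevance
   score, scaled by each source's estimated measurement precision.
   Asynchronous streams can be phase-aligned by DTW or by movement-cycle
   B-spline warping `X_aligned(t) = Σ P_i N_{i,d}(t)` (degree d = 3).
3. **Team-level fusion (TLF)** — team trajectory, centroid, and a
   windowed indicator battery: spatial entropy
   `S = −Σ p_ij log₂ p_ij`, relative-position maintenance (RPM),
   cross-recurrence quantification (RR / DET / LAM / diagonal entropy),
   Kuramoto order parameter `R(t) = |n⁻¹ Σ e^{iφ_j(t)}|` from Hilbert
   phases, and eight named indicators (SSI, TCR, FSQ, TIE, CPR, ICC, DMS,
   LDH).

Feature extraction (level-5 wavelet packets with energy-ranked selection,
mode-n tensor fusion `T = X ×₁W₁ ×₂W₂ ×₃W₃`), an information-preservation
score `Q_info = I(X;F)/H(X)`, baseline fusers (Kalman, static Bayesian,
fixed weighted average) and performance models (observed-variable path
model, logistic outcome classifier, change-point detection) round out the
toolkit.

Because public multi-athlete sensor datasets are scarce, the package ships
a first-class **session simulator**: athletes oscillate about formation
slots with Kuramoto-coupled movement phases (coupling κ is the
team-coordination dial), and each sensor observes the ground truth at its
own rate with its stated accuracy, latency jitter and dropouts. Every
downstream claim is tested against this generative truth.

## Worked example

```bash
teamfuse demo --seed 7 --out demo_out/
```

simulates a 4v4, 120 s session with nominal sensor corruption, fuses it,
computes indicators and compares fusers. `demo_out/comparison.csv`:

```
fuser,position_rmse_m,velocity_rmse_mps
multilevel,0.1002555332934165,0.07137804366772268
kalman,0.2624305623838054,0.06935676480453377
wavg,0.2501481996913383,0.08464248491313835
bayes,0.09957045660564659,0.07041037357322141
gps_only,0.48903409930536434,0.1437381885765875
```

The adaptive multi-level fuser reaches ≈ 0.10 m position RMSE — close to
the inverse-variance optimum of the 0.1 m LPS + 0.5 m GPS pair and ~5×
better than GPS alone; fixed equal weighting (`wavg`) pays heavily for
trusting the noisy GPS. The first indicator windows
(`demo_out/indicators.csv`, 10 s windows, 50 % overlap):

```
  t    SSI    TCR    FSQ    LDH  R_mean
  5  0.922  0.848  0.832  0.946   0.992
 10  0.962  0.767  0.836  0.968   0.987
 15  0.976  0.542  0.836  0.966   0.988
```

With the default coupling κ = 2 the simulated team is strongly
coordinated: spatial synchronization (SSI) and the phase order parameter
(R_mean) sit near 1, most acceleration bursts are shared (TCR), and load
is spread evenly (LDH ≈ 1). `quality_report.json` records per-stream SNR,
mean source weights, the fused-vs-truth RMSE and
`Q_info ≈ 0.64` (fraction of raw-GPS entropy preserved in the fused
trajectory).

Other subcommands: `simulate`, `fuse`, `indicators`, `perform`,
`compare` — see `teamfuse --help`.

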