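"""Hierarchical multi-level fusion (sensor -> individual -> team).

The pipeline combines, for each athlete, the positional fixes (LPS, GPS),
inertial orientation, heart rate and insole load into one common-clock
record (individual-level fusion), then stacks athletes into a team
trajectory with its centroid (team-level fusion).  Source weights follow
the exponential-smoothing recursion::

    w[i,t] = lambda * w[i,t-1] + (1 - lambda) * q[i,t] * r[i,t]

with q a normalized signal-quality score, r a contextual relevance score,
and weights renormalized across the sources of one fusion node.  Positional
sources are additionally weighted by their estimated measurement precision,
so that for unbiased Gaussian sources the combination approaches the
inverse-variance optimum.

Also provided: wavelet-packet feature extraction with energy-ranked
selection, mode-n tensor fusion, an information-preservation score
Q_info = I(X;F)/H(X), and the baseline fusers (Kalman, static Bayesian,
fixed weighted average) used in the comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.interpolate import make_interp_spline

from .errors import FusionError, ValidationError
from .preprocess import estimate_orientation
from .session import (AlignedAthleteRecord, FusionQualityReport, SensorStream,
                      TeamTrajectory)

DEFAULT_LAMBDA = 0.65          # temporal smoothing of source weights
DEFAULT_OUT_RATE_HZ = 20.0
DEFAULT_WAVELET = "db4"
DEFAULT_LEVEL = 5
DEFAULT_ALPHA_FEAT = 0.15
QUALITY_SNR_CEILING_DB = 30.0  # SNR at (or above) which quality saturates at 1


# ---------------------------------------------------------------------------
# adaptive weights
# ---------------------------------------------------------------------------

@dataclass
class WeightState:
    """Raw (pre-normalization) weights of the sources of one fusion node."""

    w: dict[str, float]
    lambda_: float = DEFAULT_LAMBDA
    t: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_ <= 1:
            raise ValidationError("lambda must be in [0, 1]")

    def normalized(self) -> dict[str, float]:
        total = sum(self.w.values())
        if total <= 0:
            n = len(self.w)
            return {k: 1.0 / n for k in self.w}
        return {k: v / total for k, v in self.w.items()}


def update_weight(state: WeightState, q: dict[str, float],
                  r: dict[str, float]) -> WeightState:
    """One step of the weight recursion for every source of the node.

    q and r must lie in [0, 1].  The raw weights keep the geometric
    convergence |w_t - c| = lambda^t |w_0 - c| under constant q*r = c;
    :meth:`WeightState.normalized` gives the sum-to-one weights actually
    applied at the fusion node.
    """
    lam = state.lambda_
    new = {}
    for k, w_prev in state.w.items():
        qk, rk = q[k], r[k]
        if not (0 <= qk <= 1 and 0 <= rk <= 1):
            raise ValidationError(f"q, r must be in [0, 1] for source {k!r}")
        new[k] = lam * w_prev + (1 - lam) * qk * rk
    return WeightState(w=new, lambda_=lam, t=state.t + 1)


def quality_from_snr(snr_db: float) -> float:
    """Map stream SNR to a [0, 1] quality score, saturating at 30 dB."""
    if np.isinf(snr_db) and snr_db > 0:
        return 1.0
    return float(np.clip(snr_db / QUALITY_SNR_CEILING_DB, 0.0, 1.0))


def contextual_relevance(modality: str, mean_accel_mps2: float) -> float:
    """Modality-by-movement-state relevance lookup.

    Inertial sensing is most informative during high-acceleration play
    (|a| > 2 m/s^2); satellite positioning is most reliable during steady
    locomotion; local positioning is trusted throughout.
    """
    high = mean_accel_mps2 > 2.0
    table = {
        "imu": 1.0 if high else 0.8,
        "gps": 0.8 if high else 1.0,
        "lps": 1.0,
        "physio": 1.0,
        "insole": 1.0,
    }
    return table.get(modality, 1.0)


# ---------------------------------------------------------------------------
# individual-level fusion
# ---------------------------------------------------------------------------

def _noise_sigma_second_diff(x: np.ndarray) -> float:
    """White-noise sigma from second differences: Var(d2) = 6 sigma^2.

    Insensitive to smooth signal content (curvature enters at O(dt^2))."""
    if x.size < 4:
        return 0.0
    d2 = x[2:] - 2 * x[1:-1] + x[:-2]
    return float(np.sqrt(max(np.mean(d2 ** 2) / 6.0, 0.0)))


def _valid_txy(stream: SensorStream, cols: list[int]
               ) -> tuple[np.ndarray, np.ndarray]:
    ok = stream.valid_mask() & np.isfinite(stream.values[:, cols]).all(axis=1)
    t = stream.t[ok] - stream.latency_s
    return t, stream.values[np.flatnonzero(ok)][:, cols]


def _positional_weights(sources: dict[str, tuple[np.ndarray, np.ndarray]],
                        nominal: dict[str, float], span: tuple[float, float],
                        lambda_: float, block_s: float,
                        accel_hint: np.ndarray | None = None
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Blockwise adaptive weights for positional sources.

    Per block: sigma estimated by second differences, quality from the
    block SNR, relevance from the movement state; the lambda recursion
    smooths q*r over blocks and the applied weight is proportional to
    w * estimated precision, renormalized.
    """
    t0, t1 = span
    n_blocks = max(1, int(np.ceil((t1 - t0) / block_s)))
    edges = t0 + np.arange(n_blocks + 1) * block_s
    names = list(sources)
    state = WeightState(w={k: 0.5 for k in names}, lambda_=lambda_)
    weights = {k: np.empty(n_blocks) for k in names}
    weights.update({f"{k}:raw": np.empty(n_blocks) for k in names})
    for b in range(n_blocks):
        q, r, prec = {}, {}, {}
        for k in names:
            ts, vs = sources[k]
            sel = (ts >= edges[b]) & (ts < edges[b + 1])
            if sel.sum() < 4:
                q[k], r[k], prec[k] = 0.0, 1.0, 1e-6
                continue
            block = vs[sel]
            sig = float(np.mean([_noise_sigma_second_diff(block[:, j])
                                 for j in range(block.shape[1])]))
            a_sig = float(np.mean(np.std(block, axis=0)))
            snr_db = np.inf if sig == 0 else 20 * np.log10(max(a_sig, 1e-12) / sig)
            q[k] = quality_from_snr(snr_db)
            amag = float(np.mean(accel_hint)) if accel_hint is not None else 0.0
            r[k] = contextual_relevance(k, amag)
            sigma_eff_sq = sig ** 2 + (0.1 * nominal.get(k, 0.1)) ** 2
            prec[k] = 1.0 / sigma_eff_sq
        state = update_weight(state, q, r)
        scaled = {k: state.w[k] * prec[k] for k in names}
        tot = sum(scaled.values())
        for k in names:
            weights[k][b] = scaled[k] / tot if tot > 0 else 1.0 / len(names)
            weights[f"{k}:raw"][b] = state.w[k]
    return edges, weights


def _block_index(t: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, t, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def fuse_individual(streams: list[SensorStream],
                    out_rate_hz: float = DEFAULT_OUT_RATE_HZ,
                    lambda_: float = DEFAULT_LAMBDA,
                    weight_block_s: float = 2.0) -> AlignedAthleteRecord:
    """Individual-level fusion of one athlete's streams onto a uniform grid.

    Position and velocity are a weight-normalized combination of the LPS
    and GPS estimates (cubic-spline resampled after latency correction);
    during dropout gaps of every positional source the last fix is
    propagated with IMU-free constant-velocity dead reckoning.  Orientation
    comes from the complementary filter on the IMU, heart rate from the
    physiological stream, cumulative load from the insole force integral.
    """
    by_mod: dict[str, SensorStream] = {}
    for s in streams:
        by_mod[s.modality] = s
    athlete_ids = {s.athlete_id for s in streams}
    if len(athlete_ids) != 1:
        raise FusionError("fuse_individual: streams from multiple athletes")
    aid = athlete_ids.pop()
    pos_mods = [m for m in ("lps", "gps") if m in by_mod]
    if not pos_mods:
        raise FusionError(f"athlete {aid!r}: no positional source (lps/gps)")

    sources_pos, sources_vel, nominal_pos, nominal_vel = {}, {}, {}, {}
    for m in pos_mods:
        s = by_mod[m]
        names = s.channel_names
        pc = [names.index("x_m"), names.index("y_m")]
        vc = [names.index("vx_mps"), names.index("vy_mps")]
        t_p, xy = _valid_txy(s, pc)
        t_v, vv = _valid_txy(s, vc)
        if t_p.size < 4:
            continue
        sources_pos[m] = (t_p, xy)
        sources_vel[m] = (t_v, vv)
        acc = s.nominal_accuracy or [0.1] * len(names)
        nominal_pos[m] = float(acc[pc[0]]) or 0.1
        nominal_vel[m] = float(acc[vc[0]]) or 0.05
    if not sources_pos:
        raise FusionError(f"athlete {aid!r}: positional sources entirely dropped out")

    t_start = max(ts[0] for ts, _ in sources_pos.values())
    t_end = min(ts[-1] for ts, _ in sources_pos.values())
    dt = 1.0 / out_rate_hz
    start = np.ceil(t_start / dt) * dt
    n = int(np.floor((t_end - start) / dt)) + 1
    if n < 4:
        raise FusionError(f"athlete {aid!r}: overlapping span too short")
    grid = start + np.arange(n) * dt

    edges, wblocks = _positional_weights(
        sources_pos, nominal_pos, (t_start, t_end), lambda_, weight_block_s)
    bidx = _block_index(grid, edges)

    pos = np.zeros((n, 2))
    vel = np.zeros((n, 2))
    wsum = np.zeros(n)
    weight_history = {"block_t": 0.5 * (edges[:-1] + edges[1:])}
    for m in sources_pos:
        ts, xy = sources_pos[m]
        k = min(5, ts.size - 1)       # quintic: negligible resampling bias
        sp_p = make_interp_spline(ts, xy, k=k, axis=0)
        tv, vv = sources_vel[m]
        sp_v = make_interp_spline(tv, vv, k=min(5, tv.size - 1), axis=0)
        w = wblocks[m][bidx]
        pos += w[:, None] * sp_p(grid)
        vel += w[:, None] * sp_v(grid)
        wsum += w
        weight_history[m] = wblocks[m]
        weight_history[f"{m}:raw"] = wblocks[f"{m}:raw"]
    pos /= wsum[:, None]
    vel /= wsum[:, None]

    # dead-reckon across intervals where every positional source is out
    gap = _all_source_gaps(sources_pos, grid)
    if gap.any():
        pos, vel = _dead_reckon(grid, pos, vel, gap)

    acc = np.gradient(vel, dt, axis=0)

    if "imu" in by_mod:
        imu = by_mod["imu"]
        ori_native = estimate_orientation(imu)
        t_imu = imu.t - imu.latency_s
        ori = np.column_stack([np.interp(grid, t_imu, ori_native[:, j])
                               for j in range(3)])
    else:
        ori = np.full((n, 3), np.nan)

    if "physio" in by_mod:
        tp, hr = _valid_txy(by_mod["physio"], [0])
        heart = np.interp(grid, tp, hr[:, 0]) if tp.size >= 2 \
            else np.full(n, np.nan)
    else:
        heart = np.full(n, np.nan)

    if "insole" in by_mod:
        s = by_mod["insole"]
        ti, forces = _valid_txy(s, list(range(len(s.channel_names))))
        if ti.size >= 2:
            total = np.clip(forces.sum(axis=1), 0, None)
            cum = np.concatenate([[0.0], np.cumsum(
                0.5 * (total[1:] + total[:-1]) * np.diff(ti))])
            load = np.interp(grid, ti, cum)
        else:
            load = np.full(n, np.nan)
    else:
        load = np.full(n, np.nan)

    return AlignedAthleteRecord(
        athlete_id=aid, t=grid, position=pos, velocity=vel, acceleration=acc,
        orientation=ori, heart_rate=heart, load=load,
        weight_history=weight_history)


def _all_source_gaps(sources: dict, grid: np.ndarray,
                     max_gap_factor: float = 3.0) -> np.ndarray:
    """Grid samples farther than max_gap_factor nominal intervals from every
    source's nearest valid fix."""
    gap = np.ones(grid.size, dtype=bool)
    for ts, _ in sources.values():
        nominal = np.median(np.diff(ts)) if ts.size > 1 else np.inf
        idx = np.searchsorted(ts, grid)
        idx = np.clip(idx, 1, ts.size - 1)
        nearest = np.minimum(np.abs(grid - ts[idx - 1]), np.abs(ts[idx] - grid))
        gap &= nearest > max_gap_factor * nominal
    return gap


def _dead_reckon(grid: np.ndarray, pos: np.ndarray, vel: np.ndarray,
                 gap: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos, vel = pos.copy(), vel.copy()
    i = 0
    n = grid.size
    while i < n:
        if gap[i] and i > 0:
            j = i
            while j < n and gap[j]:
                j += 1
            v0 = vel[i - 1]
            for k in range(i, j):
                pos[k] = pos[i - 1] + v0 * (grid[k] - grid[i - 1])
                vel[k] = v0
            i = j
        else:
            i += 1
    return pos, vel


def fuse_team(records: list[AlignedAthleteRecord],
              team_of: dict[str, str] | None = None) -> TeamTrajectory:
    """Stack individual records into a team trajectory on the common grid."""
    if len(records) < 2:
        raise FusionError("fuse_team: need >= 2 athletes")
    t0 = max(r.t[0] for r in records)
    t1 = min(r.t[-1] for r in records)
    dts = {round(float(r.t[1] - r.t[0]), 9) for r in records}
    if len(dts) != 1:
        raise FusionError("fuse_team: records on different grid rates")
    ref = records[0]
    sel_ref = (ref.t >= t0 - 1e-9) & (ref.t <= t1 + 1e-9)
    grid = ref.t[sel_ref]
    n = grid.size
    m = len(records)
    pos = np.empty((n, m, 2))
    vel = np.empty((n, m, 2))
    ids = []
    for k, r in enumerate(records):
        sel = (r.t >= t0 - 1e-9) & (r.t <= t1 + 1e-9)
        if sel.sum() != n or not np.allclose(r.t[sel], grid, atol=1e-9):
            raise FusionError(f"fuse_team: grid mismatch for {r.athlete_id!r}")
        pos[:, k] = r.position[sel]
        vel[:, k] = r.velocity[sel]
        ids.append(r.athlete_id)
    return TeamTrajectory(t=grid, athlete_ids=ids, positions=pos,
                          velocities=vel, team_of=team_of or {})


# ---------------------------------------------------------------------------
# wavelet-packet features
# ---------------------------------------------------------------------------

@dataclass
class WaveletFeatures:
    level: int
    wavelet: str
    coefficients: dict[str, np.ndarray]   # leaf-node path -> coefficient array
    n_samples: int

    def leaf_energies(self) -> dict[str, float]:
        return {k: float((v ** 2).sum()) for k, v in self.coefficients.items()}

    def total_energy(self) -> float:
        return float(sum(self.leaf_energies().values()))

    def reconstruct(self) -> np.ndarray:
        wp = pywt.WaveletPacket(data=None, wavelet=self.wavelet, mode="periodization",
                                maxlevel=self.level)
        for path, coeffs in self.coefficients.items():
            wp[path] = coeffs
        return wp.reconstruct(update=False)[: self.n_samples]


def wavelet_packet(signal: np.ndarray, level: int = DEFAULT_LEVEL,
                   wavelet: str = DEFAULT_WAVELET) -> WaveletFeatures:
    """Full wavelet-packet decomposition to the given depth.

    Periodized orthogonal transform: the inverse reconstructs the input and
    leaf energies sum to the signal energy.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1:
        raise ValidationError("wavelet_packet: signal must be 1-D")
    if x.size < 2 ** level:
        raise ValidationError(
            f"wavelet_packet: need at least 2^{level} = {2 ** level} samples, "
            f"got {x.size}")
    # zero-pad to a multiple of 2^level so the periodized transform is
    # exactly orthogonal (perfect reconstruction + Parseval)
    block = 2 ** level
    m = int(np.ceil(x.size / block)) * block
    padded = np.zeros(m)
    padded[: x.size] = x
    wp = pywt.WaveletPacket(data=padded, wavelet=wavelet, mode="periodization",
                            maxlevel=level)
    coeffs = {node.path: np.asarray(node.data, float)
              for node in wp.get_level(level, order="natural")}
    return WaveletFeatures(level=level, wavelet=wavelet, coefficients=coeffs,
                           n_samples=x.size)


@dataclass
class ReducedFeatures:
    kept: dict[str, np.ndarray]       # leaf path -> sparsified coefficients
    n_kept: int
    n_total: int
    reconstruction_error: float       # relative L2 vs the original signal
    retained_energy_fraction: float


def select_features(features: WaveletFeatures,
                    alpha_feat: float = DEFAULT_ALPHA_FEAT) -> ReducedFeatures:
    """Keep the top ``ceil(alpha_feat * total)`` packet coefficients by energy."""
    if not 0 < alpha_feat <= 1:
        raise ValidationError("alpha_feat must be in (0, 1]")
    paths = sorted(features.coefficients)
    flat = np.concatenate([features.coefficients[p] for p in paths])
    total = flat.size
    n_keep = int(np.ceil(alpha_feat * total))
    order = np.argsort(flat ** 2)[::-1]
    mask = np.zeros(total, dtype=bool)
    mask[order[:n_keep]] = True
    sparsified = np.where(mask, flat, 0.0)
    kept = {}
    pos = 0
    for p in paths:
        ln = features.coefficients[p].size
        kept[p] = sparsified[pos:pos + ln]
        pos += ln
    reduced = WaveletFeatures(level=features.level, wavelet=features.wavelet,
                              coefficients=kept, n_samples=features.n_samples)
    original = features.reconstruct()
    approx = reduced.reconstruct()
    denom = np.linalg.norm(original)
    err = float(np.linalg.norm(original - approx) / denom) if denom > 0 else 0.0
    tot_e = float((flat ** 2).sum())
    ret_e = float((sparsified ** 2).sum() / tot_e) if tot_e > 0 else 1.0
    return ReducedFeatures(kept=kept, n_kept=n_keep, n_total=total,
                           reconstruction_error=err,
                           retained_energy_fraction=ret_e)


# ---------------------------------------------------------------------------
# tensor fusion
# ---------------------------------------------------------------------------

@dataclass
class FusedTensor:
    source: np.ndarray
    projections: tuple
    result: np.ndarray


def tensor_fuse(X: np.ndarray, W1: np.ndarray, W2: np.ndarray,
                W3: np.ndarray) -> FusedTensor:
    """Mode-n products ``T = X x1 W1 x2 W2 x3 W3`` for a 3-mode feature tensor.

    Mode 1 indexes athletes, mode 2 sensor modalities, mode 3 time windows.
    """
    X = np.asarray(X, float)
    if X.ndim != 3:
        raise ValidationError("tensor_fuse: X must be a 3-mode array")
    for mode, W in ((1, W1), (2, W2), (3, W3)):
        W = np.asarray(W)
        if W.ndim != 2 or W.shape[1] != X.shape[mode - 1]:
            raise ValidationError(
                f"tensor_fuse: projection for mode {mode} must have "
                f"{X.shape[mode - 1]} columns, got {np.asarray(W).shape}")
    T = np.einsum("ijk,ai,bj,ck->abc", X, W1, W2, W3)
    return FusedTensor(source=X, projections=(W1, W2, W3), result=T)


# ---------------------------------------------------------------------------
# information-preservation score
# ---------------------------------------------------------------------------

def _equal_freq_edges(x: np.ndarray, bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, bins + 1)
    edges = np.quantile(x, qs)
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return np.unique(edges)


def q_info(X: np.ndarray, F: np.ndarray, bins: int = 16) -> FusionQualityReport:
    """Information preservation ``Q_info = I(X;F) / H(X)`` (plug-in, bits).

    Discrete estimator on equal-frequency bins.  A constant X has zero
    entropy; the score is then undefined and returned as a flagged sentinel.
    """
    X = np.asarray(X, float).ravel()
    F = np.asarray(F, float).ravel()
    if X.size != F.size or X.size < 100:
        raise ValidationError("q_info: need >= 100 paired samples")
    if np.ptp(X) == 0:
        return FusionQualityReport(q_info=None, entropy_bits=0.0,
                                   flags=["q_info undefined: constant X"])
    ex = _equal_freq_edges(X, bins)
    if ex.size < 3:
        return FusionQualityReport(q_info=None, entropy_bits=0.0,
                                   flags=["q_info undefined: constant X"])
    ef = _equal_freq_edges(F, bins)
    if ef.size < 3:
        ef = np.array([F.min() - 1e-12, F.max() + 1e-12])
    joint, _, _ = np.histogram2d(X, F, bins=(ex, ef))
    p = joint / joint.sum()
    px = p.sum(axis=1)
    pf = p.sum(axis=0)
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    nz = p > 0
    mi = float((p[nz] * np.log2(p[nz] / np.outer(px, pf)[nz])).sum())
    mi = min(max(mi, 0.0), hx)
    return FusionQualityReport(q_info=mi / hx if hx > 0 else None,
                               mutual_information_bits=mi, entropy_bits=hx)


# ---------------------------------------------------------------------------
# baseline fusers
# ---------------------------------------------------------------------------

@dataclass
class KalmanState:
    x_hat: np.ndarray
    P: np.ndarray


def kalman_fuse(z: np.ndarray, H: np.ndarray, Q_proc: np.ndarray,
                R_meas: np.ndarray, x0: np.ndarray, P0: np.ndarray,
                F: np.ndarray | None = None) -> np.ndarray:
    """Standard linear Kalman predict/update over a measurement series.

    ``z`` is (n_steps, n_meas); ``F`` defaults to identity (static state).
    Returns the (n_steps, n_state) series of posterior means.
    """
    z = np.atleast_2d(np.asarray(z, float))
    H = np.atleast_2d(np.asarray(H, float))
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    P = np.atleast_2d(np.asarray(P0, float)).copy()
    Q = np.atleast_2d(np.asarray(Q_proc, float))
    R = np.atleast_2d(np.asarray(R_meas, float))
    F = np.eye(x.size) if F is None else np.atleast_2d(np.asarray(F, float))
    out = np.empty((z.shape[0], x.size))
    for k in range(z.shape[0]):
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        if np.linalg.cond(S) > 1e14:
            raise FusionError("kalman_fuse: singular innovation covariance")
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (z[k] - H @ x)
        P = (np.eye(x.size) - K @ H) @ P
        out[k] = x
    return out


def weighted_average_fuse(sources: list[np.ndarray],
                          weights: list[float]) -> np.ndarray:
    """Fixed convex combination of equally-gridded source series."""
    weights = np.asarray(weights, float)
    if (weights < 0).any():
        raise ValidationError("weighted_average_fuse: negative weights")
    if not np.isclose(weights.sum(), 1.0):
        raise ValidationError("weighted_average_fuse: weights must sum to 1")
    stacked = np.stack([np.asarray(s, float) for s in sources])
    return np.tensordot(weights, stacked, axes=(0, 0))


def bayes_fuse(prior_mean: float, prior_var: float, means: np.ndarray,
               variances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior by precision addition; ``prior_var=inf`` is flat.

    Broadcasts over leading axes of ``means``/``variances`` (sources along
    the first axis).  Returns (posterior_mean, posterior_var).
    """
    means = np.asarray(means, float)
    variances = np.asarray(variances, float)
    if (variances <= 0).any():
        raise ValidationError("bayes_fuse: variances must be > 0")
    prec0 = 0.0 if np.isinf(prior_var) else 1.0 / prior_var
    prec = prec0 + (1.0 / variances).sum(axis=0)
    num = (prior_mean * prec0) + (means / variances).sum(axis=0)
    return num / prec, 1.0 / prec


# ---------------------------------------------------------------------------
# comparison harness
# ---------------------------------------------------------------------------

def _resample_sources(streams: list[SensorStream], grid: np.ndarray
                      ) -> dict[str, np.ndarray]:
    out = {}
    for s in streams:
        if s.modality not in ("gps", "lps"):
            continue
        names = s.channel_names
        cols = [names.index(c) for c in ("x_m", "y_m", "vx_mps", "vy_mps")]
        t, v = _valid_txy(s, cols)
        sp = make_interp_spline(t, v, k=min(5, t.size - 1), axis=0)
        out[s.modality] = sp(np.clip(grid, t[0], t[-1]))
    return out


def compare_fusers(manifest, streams: list[SensorStream], truth,
                   fusers: tuple = ("multilevel", "kalman", "wavg", "bayes",
                                    "gps_only"),
                   out_rate_hz: float = DEFAULT_OUT_RATE_HZ) -> pd.DataFrame:
    """Position/velocity RMSE of each fuser against ground truth, per session.

    The ``truth`` object must expose ``team`` (a :class:`TeamTrajectory` at
    the simulation frame rate).
    """
    team = truth.team
    by_ath: dict[str, list[SensorStream]] = {}
    for s in streams:
        by_ath.setdefault(s.athlete_id, []).append(s)
    sig = {"gps": 0.5, "lps": 0.1}
    pos_err = {name: [] for name in fusers}
    vel_err = {name: [] for name in fusers}
    for aid, group in by_ath.items():
        k = team.athlete_ids.index(aid)
        rec = fuse_individual(group, out_rate_hz=out_rate_hz)
        grid = rec.t
        true_pos = np.column_stack([
            np.interp(grid, team.t, team.positions[:, k, j]) for j in (0, 1)])
        true_vel = np.column_stack([
            np.interp(grid, team.t, team.velocities[:, k, j]) for j in (0, 1)])
        src = _resample_sources(group, grid)
        for name in fusers:
            if name == "multilevel":
                est_p, est_v = rec.position, rec.velocity
            else:
                if name == "gps_only":
                    est = src["gps"]
                elif name == "wavg":
                    est = weighted_average_fuse(list(src.values()),
                                                [1 / len(src)] * len(src))
                elif name == "bayes":
                    mods = list(src)
                    means = np.stack([src[m] for m in mods])
                    var = np.stack([np.full_like(src[m], sig[m] ** 2)
                                    for m in mods])
                    est, _ = bayes_fuse(0.0, np.inf, means, var)
                elif name == "kalman":
                    est = _kalman_position(src, grid, sig)
                else:
                    raise ValidationError(f"unknown fuser {name!r}")
                est_p, est_v = est[:, :2], est[:, 2:]
            pos_err[name].append(np.sqrt(np.mean((est_p - true_pos) ** 2)))
            vel_err[name].append(np.sqrt(np.mean((est_v - true_vel) ** 2)))
    return pd.DataFrame(
        [{"fuser": name,
          "position_rmse_m": float(np.mean(pos_err[name])),
          "velocity_rmse_mps": float(np.mean(vel_err[name]))}
         for name in fusers])


def _kalman_position(src: dict[str, np.ndarray], grid: np.ndarray,
                     sig: dict[str, float]) -> np.ndarray:
    """Constant-velocity Kalman baseline on stacked positional fixes."""
    dt = float(grid[1] - grid[0])
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    q = 0.5  # process noise intensity, m/s^2
    Q = q ** 2 * np.diag([dt ** 3 / 3, dt ** 3 / 3, dt, dt])
    mods = list(src)
    H = np.vstack([np.eye(4) for _ in mods])
    R = np.diag(sum(([sig[m] ** 2, sig[m] ** 2,
                      (sig[m] / 5) ** 2, (sig[m] / 5) ** 2] for m in mods), []))
    z = np.column_stack([src[m] for m in mods])
    x0 = z[0, :4]
    return kalman_fuse(z, H, Q, R, x0, np.eye(4) * 10.0, F=F)


def fusion_quality_report(streams: list[SensorStream],
                          record: AlignedAthleteRecord,
                          truth=None) -> FusionQualityReport:
    """Stream SNRs, information preservation and (if truth given) RMSE."""
    from .preprocess import estimate_stream_quality
    report = FusionQualityReport()
    for s in streams:
        try:
            qual = estimate_stream_quality(s)
            report.snr_db[s.sensor_id] = float(qual.snr_db)
            if qual.needs_recalibration:
                report.flags.append(f"{s.sensor_id}: needs recalibration")
        except Exception as exc:  # degenerate stream: record, don't abort
            report.flags.append(f"{s.sensor_id}: quality unavailable ({exc})")
    gps = [s for s in streams if s.modality == "gps"]
    if gps and record.t.size >= 100:
        t, xy = _valid_txy(gps[0], [gps[0].channel_names.index("x_m")])
        x_res = np.interp(record.t, t, xy[:, 0])
        qi = q_info(x_res, record.position[:, 0])
        report.q_info = qi.q_info
        report.mutual_information_bits = qi.mutual_information_bits
        report.entropy_bits = qi.entropy_bits
    if truth is not None:
        team = truth.team
        k = team.athlete_ids.index(record.athlete_id)
        tp = np.column_stack([np.interp(record.t, team.t, team.positions[:, k, j])
                              for j in (0, 1)])
        report.position_rmse_m = float(np.sqrt(np.mean((record.position - tp) ** 2)))
    for m, w in record.weight_history.items():
        if m != "block_t":
            report.weights[m] = float(np.mean(w))
    return report
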