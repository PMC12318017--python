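"""Collaborative-dynamics indicator system.

Team coordination is quantified along three dimensions:

* **spatial** — team spatial entropy over a pitch zone grid, the relative
  position maintenance index (RPM), formation stability;
* **temporal** — cross-recurrence quantification (RR, DET, LAM, diagonal
  entropy), Hilbert-phase synchrony and the Kuramoto order parameter R(t),
  the temporal coordination rate of shared acceleration bursts;
* **functional** — passing-network entropy, perturbation recovery time,
  individual-collective coupling, decision synchronicity, and load
  distribution harmony.

The windowed indicator battery (:func:`compute_indicators`) emits one row
per sliding analysis window; an indicator whose required events are absent
in a window is NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .session import EventTable, IndicatorSeries, TeamTrajectory


# ---------------------------------------------------------------------------
# zone occupancy and spatial entropy
# ---------------------------------------------------------------------------

@dataclass
class ZoneGrid:
    """Occupancy probabilities of athletes over an axis-aligned pitch grid."""

    n_x: int
    n_y: int
    pitch_extent: tuple
    occupancy: np.ndarray             # (n_athletes, n_x * n_y)
    normalization: str = "joint"      # "joint": sums to 1 overall; "per_athlete"


def occupancy_grid(team: TeamTrajectory, n_x: int, n_y: int,
                   pitch_extent: tuple, normalization: str = "joint",
                   frames: slice | np.ndarray = slice(None)) -> ZoneGrid:
    x0, x1, y0, y1 = pitch_extent
    pos = team.positions[frames]
    m = pos.shape[1]
    counts = np.zeros((m, n_x * n_y))
    ix = np.clip(((pos[:, :, 0] - x0) / (x1 - x0) * n_x).astype(int), 0, n_x - 1)
    iy = np.clip(((pos[:, :, 1] - y0) / (y1 - y0) * n_y).astype(int), 0, n_y - 1)
    zone = ix * n_y + iy
    for k in range(m):
        counts[k] = np.bincount(zone[:, k], minlength=n_x * n_y)
    if normalization == "joint":
        occ = counts / counts.sum()
    elif normalization == "per_athlete":
        occ = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return ZoneGrid(n_x=n_x, n_y=n_y, pitch_extent=tuple(pitch_extent),
                    occupancy=occ, normalization=normalization)


def spatial_entropy(grid: ZoneGrid) -> float:
    """Team spatial entropy ``-sum_ij p_ij log2 p_ij`` in bits (0 log 0 := 0)."""
    p = np.asarray(grid.occupancy, float)
    total = p.sum()
    expected = 1.0 if grid.normalization == "joint" else p.shape[0]
    if not np.isclose(total, expected, atol=1e-6):
        raise ValidationError(
            f"occupancy not normalized: sums to {total}, expected {expected}")
    if (p < -1e-12).any():
        raise ValidationError("occupancy has negative entries")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# relative position maintenance
# ---------------------------------------------------------------------------

def rpm(d: np.ndarray, d_ref: np.ndarray) -> tuple[float, list[str]]:
    """Relative position maintenance index: mean over athlete pairs of the
    Pearson correlation between observed and reference inter-athlete
    distance series.

    A pair whose observed series is constant is excluded with a warning; a
    constant *reference* series makes the covariance normalization
    degenerate, and for such pairs the documented fallback
    ``1 - mean|d - d_ref| / mean(d_ref)`` (clipped to [-1, 1]) is used.
    Returns (rpm, flags); rpm is NaN when every pair is excluded.
    """
    d = np.atleast_2d(np.asarray(d, float))
    d_ref = np.atleast_2d(np.asarray(d_ref, float))
    if d.shape[0] != d_ref.shape[0] and d.shape[1] == d_ref.shape[1]:
        pass
    if d.shape[1] == 1 and d.shape[0] > 1:
        pass
    if d_ref.shape[0] == 1 and d.shape[0] > 1:
        d_ref = np.repeat(d_ref, d.shape[0], axis=0)
    if d.shape != d_ref.shape:
        raise ValidationError("d and d_ref must have matching shapes")
    flags: list[str] = []
    vals = []
    for j in range(d.shape[1]):
        x, y = d[:, j], d_ref[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0:
            flags.append(f"pair {j}: constant observed series excluded")
            continue
        if sy == 0:
            ref_mean = y.mean()
            if ref_mean == 0:
                flags.append(f"pair {j}: zero constant reference excluded")
                continue
            flags.append(f"pair {j}: constant reference, MAE fallback used")
            vals.append(float(np.clip(1.0 - np.abs(x - y).mean() / ref_mean, -1, 1)))
            continue
        vals.append(float(np.corrcoef(x, y)[0, 1]))
    if not vals:
        flags.append("rpm undefined: all pairs excluded")
        return float("nan"), flags
    return float(np.mean(vals)), flags


# ---------------------------------------------------------------------------
# cross-recurrence quantification
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceResult:
    epsilon: float
    CR: np.ndarray
    RR: float
    DET: float
    LAM: float
    ENT_diag: float
    l_min: int = 2
    scale: int = 1


def _line_lengths(mask: np.ndarray) -> list[int]:
    """Run lengths of consecutive True values in a boolean vector."""
    out = []
    run = 0
    for v in mask:
        if v:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def crqa_from_matrix(CR: np.ndarray, l_min: int = 2, epsilon: float = 0.0,
                     scale: int = 1) -> RecurrenceResult:
    """RR / DET / LAM / diagonal-line entropy from a binary recurrence matrix."""
    CR = np.asarray(CR).astype(bool)
    n, m = CR.shape
    total = CR.sum()
    RR = total / CR.size
    diag_lengths: list[int] = []
    for off in range(-(n - 1), m):
        diag_lengths.extend(_line_lengths(np.diagonal(CR, offset=off)))
    vert_lengths: list[int] = []
    for j in range(m):
        vert_lengths.extend(_line_lengths(CR[:, j]))
    det_pts = sum(l for l in diag_lengths if l >= l_min)
    lam_pts = sum(l for l in vert_lengths if l >= l_min)
    DET = det_pts / total if total else 0.0
    LAM = lam_pts / total if total else 0.0
    kept = np.array([l for l in diag_lengths if l >= l_min])
    if kept.size:
        _, counts = np.unique(kept, return_counts=True)
        p = counts / counts.sum()
        ent = float(-(p * np.log2(p)).sum())
    else:
        ent = 0.0
    return RecurrenceResult(epsilon=epsilon, CR=CR.astype(np.uint8), RR=float(RR),
                            DET=float(DET), LAM=float(LAM), ENT_diag=ent,
                            l_min=l_min, scale=scale)


def _coarse_grain(X: np.ndarray, scale: int) -> np.ndarray:
    if scale == 1:
        return X
    n = (X.shape[0] // scale) * scale
    return X[:n].reshape(-1, scale, X.shape[1]).mean(axis=1)


def cross_recurrence(Xi: np.ndarray, Xj: np.ndarray, epsilon: float,
                     scale: int = 1, l_min: int = 2) -> RecurrenceResult:
    """Cross-recurrence plot ``CR(m,n) = [||Xi(m) - Xj(n)|| <= eps]`` plus RQA stats.

    ``scale >= 2`` applies block-mean coarse-graining to both state series
    before thresholding (the multi-scale part of MS-CRQA).
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    if scale < 1:
        raise ValidationError("scale must be >= 1")
    Xi = np.atleast_2d(np.asarray(Xi, float))
    Xj = np.atleast_2d(np.asarray(Xj, float))
    if Xi.shape[0] == 1 and Xi.shape[1] > 1:
        Xi = Xi.T
    if Xj.shape[0] == 1 and Xj.shape[1] > 1:
        Xj = Xj.T
    if Xi.shape[1] != Xj.shape[1]:
        raise ValidationError("state vectors must share dimension")
    Xi = _coarse_grain(Xi, scale)
    Xj = _coarse_grain(Xj, scale)
    D = cdist(Xi, Xj)
    return crqa_from_matrix(D <= epsilon, l_min=l_min, epsilon=epsilon, scale=scale)


def ms_crqa(Xi: np.ndarray, Xj: np.ndarray, epsilon: float,
            scales: tuple = (1, 2, 4), l_min: int = 2) -> dict[int, RecurrenceResult]:
    """Multi-scale CRQA over a set of coarse-graining factors."""
    return {s: cross_recurrence(Xi, Xj, epsilon, scale=s, l_min=l_min)
            for s in scales}


# ---------------------------------------------------------------------------
# Hilbert phase and order parameter
# ---------------------------------------------------------------------------

@dataclass
class PhaseSeries:
    t: np.ndarray
    phases: np.ndarray                # (n, n_signals), unwrapped radians
    undefined: bool = False

    def order_parameter(self) -> np.ndarray:
        return order_parameter(self.phases)


def hilbert_phase(x: np.ndarray, rate_hz: float,
                  band: tuple[float, float] | None = None) -> PhaseSeries:
    """Instantaneous unwrapped phase of each column via the analytic signal.

    Signals are mean-removed (and optionally band-passed) before the Hilbert
    transform.  An all-zero signal has no defined phase and is flagged.
    """
    x = np.asarray(x, float)
    one_d = x.ndim == 1
    X = x[:, None] if one_d else x
    n = X.shape[0]
    t = np.arange(n) / rate_hz
    if not np.any(np.abs(X) > 0):
        return PhaseSeries(t=t, phases=np.full_like(X, np.nan), undefined=True)
    Z = X - X.mean(axis=0)
    if band is not None:
        lo, hi = band
        if hi >= rate_hz / 2:
            raise ValidationError("band upper edge must be below Nyquist")
        sos = sp_signal.butter(2, (lo, hi), btype="bandpass", fs=rate_hz,
                               output="sos")
        Z = sp_signal.sosfiltfilt(sos, Z, axis=0)
    analytic = sp_signal.hilbert(Z, axis=0)
    phases = np.unwrap(np.angle(analytic), axis=0)
    return PhaseSeries(t=t, phases=phases)


def order_parameter(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter ``R = |mean_j exp(i phi_j)|`` per frame."""
    phases = np.atleast_2d(np.asarray(phases, float))
    if phases.shape[0] == 1 and phases.ndim == 2 and phases.shape[1] > 1:
        pass
    return np.abs(np.exp(1j * phases).mean(axis=-1))


def gini(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative distribution; 0 = perfectly equal."""
    x = np.sort(np.asarray(x, float))
    if (x < 0).any():
        raise ValidationError("gini: negative values")
    n = x.size
    if n == 0 or x.sum() == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * x.sum()))


# ---------------------------------------------------------------------------
# windowed indicator battery
# ---------------------------------------------------------------------------

@dataclass
class IndicatorConfig:
    window_s: float = 10.0
    overlap: float = 0.5
    accel_threshold_mps2: float = 2.0     # synchronized-burst detection level
    sync_window_s: float = 0.5            # co-occurrence window for TCR
    zone_nx: int = 6
    zone_ny: int = 4
    phase_band_hz: tuple = (0.1, 2.0)
    edge_trim: float = 0.05
    cpr_baseline_windows: int = 3
    pitch_extent: tuple = (-20.0, 20.0, -15.0, 15.0)


def _vector_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Correlation of two planar vector series: centred inner product over
    the product of centred norms.  Invariant to joint rotation and to
    translation of the underlying positions."""
    uc = u - u.mean(axis=0)
    vc = v - v.mean(axis=0)
    num = (uc * vc).sum()
    den = np.sqrt((uc ** 2).sum() * (vc ** 2).sum())
    return float(num / den) if den > 0 else float("nan")


def _pair_distances(pos: np.ndarray) -> np.ndarray:
    """(n_frames, n_pairs) distances for all unordered athlete pairs."""
    m = pos.shape[1]
    cols = []
    for i in range(m):
        for j in range(i + 1, m):
            cols.append(np.linalg.norm(pos[:, i] - pos[:, j], axis=1))
    return np.column_stack(cols)


def _accel_event_times(team: TeamTrajectory, threshold: float) -> list[np.ndarray]:
    dt = float(team.t[1] - team.t[0])
    out = []
    for k in range(team.n_athletes):
        a = np.gradient(team.velocities[:, k], dt, axis=0)
        mag = np.linalg.norm(a, axis=1)
        above = mag > threshold
        rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        out.append(team.t[rising])
    return out


def team_subset(team: TeamTrajectory, label: str) -> TeamTrajectory:
    """Restrict a trajectory to the athletes of one team."""
    idx = [k for k, aid in enumerate(team.athlete_ids)
           if team.team_of.get(aid, "A") == label]
    ids = [team.athlete_ids[k] for k in idx]
    return TeamTrajectory(t=team.t, athlete_ids=ids,
                          positions=team.positions[:, idx],
                          velocities=team.velocities[:, idx],
                          team_of={i: label for i in ids})


def movement_phases(team: TeamTrajectory, band: tuple = (0.1, 2.0)) -> PhaseSeries:
    """Per-athlete Hilbert phases of the x-oscillation about each athlete's
    own mean position (the band-pass removes slow formation drift)."""
    rate = 1.0 / float(team.t[1] - team.t[0])
    rel = team.positions[:, :, 0] - team.positions[:, :, 0].mean(axis=0)
    return hilbert_phase(rel, rate, band=band)


def perturbation_recovery(t_windows: np.ndarray, ssi: np.ndarray,
                          t_perturb: float, n_baseline: int = 3
                          ) -> float:
    """Seconds from a perturbation until SSI re-enters its pre-perturbation
    mean +- 1 SD band; NaN if it never recovers or no baseline exists."""
    before = np.flatnonzero(t_windows < t_perturb)
    if before.size < n_baseline:
        return float("nan")
    base = ssi[before[-n_baseline:]]
    mu, sd = np.nanmean(base), np.nanstd(base)
    sd = max(sd, 1e-6)
    after = np.flatnonzero(t_windows >= t_perturb)
    for k in after:
        if abs(ssi[k] - mu) <= sd:
            return float(t_windows[k] - t_perturb)
    return float("nan")


def compute_indicators(team: TeamTrajectory, events: EventTable | None = None,
                       loads: dict[str, np.ndarray] | None = None,
                       config: IndicatorConfig | None = None) -> IndicatorSeries:
    """Sliding-window indicator battery for one team's trajectory.

    ``loads`` maps athlete_id to a cumulative-load series on the team time
    grid; when absent, distance covered is used as the workload proxy.
    """
    cfg = config or IndicatorConfig()
    events = events or EventTable()
    m = team.n_athletes
    if m < 2:
        raise ValidationError("compute_indicators: need >= 2 athletes")
    t = team.t
    dt = float(t[1] - t[0])
    rate = 1.0 / dt
    step = cfg.window_s * (1 - cfg.overlap)
    starts = np.arange(t[0], t[-1] - cfg.window_s + dt / 2, step)
    if starts.size < 1:
        raise ValidationError("compute_indicators: need >= 2 windows of data")

    phases = movement_phases(team, cfg.phase_band_hz)
    trim = int(cfg.edge_trim * len(t))
    R_t = np.full(len(t), np.nan)
    R_core = order_parameter(phases.phases)
    R_t[trim:len(t) - trim] = R_core[trim:len(t) - trim]

    accel_events = _accel_event_times(team, cfg.accel_threshold_mps2)
    dists = _pair_distances(team.positions)
    d_ref = dists.mean(axis=0, keepdims=True)  # session-mean tactical template

    if loads is None:
        speed = np.linalg.norm(team.velocities, axis=2)
        loads_arr = np.cumsum(speed, axis=0) * dt
    else:
        loads_arr = np.column_stack([loads[aid] for aid in team.athlete_ids])

    aset = set(team.athlete_ids)
    passes = events.of_type("pass")
    passes = passes[passes["athlete_id"].isin(aset)]
    decisive = events.of_type("decisive_action")
    decisive = decisive[decisive["athlete_id"].isin(aset)]
    perturbations = events.of_type("perturbation")

    rows = []
    ssi_list = []
    for t0 in starts:
        sel = (t >= t0) & (t < t0 + cfg.window_s)
        V = team.velocities[sel]
        P = team.positions[sel]
        row = {"t": t0 + cfg.window_s / 2}

        pair_corr = [_vector_correlation(P[:, i], P[:, j])
                     for i in range(m) for j in range(i + 1, m)]
        row["SSI"] = float(np.nanmean(pair_corr))
        cv = V.mean(axis=1)
        row["ICC"] = float(np.nanmean(
            [_vector_correlation(V[:, k], cv) for k in range(m)]))

        ev_in = [times[(times >= t0) & (times < t0 + cfg.window_s)]
                 for times in accel_events]
        all_ev = np.sort(np.concatenate(ev_in)) if any(e.size for e in ev_in) else \
            np.empty(0)
        if all_ev.size:
            half = cfg.sync_window_s / 2
            need = int(np.ceil(m / 2))
            shared = 0
            for tau in all_ev:
                n_with = sum(1 for times in ev_in
                             if np.any(np.abs(times - tau) <= half))
                shared += n_with >= need
            row["TCR"] = shared / all_ev.size
        else:
            row["TCR"] = float("nan")

        dw = dists[sel]
        cvd = dw.std() / dw.mean() if dw.mean() > 0 else float("nan")
        row["FSQ"] = float(1.0 / (1.0 + cvd))

        pw = passes[(passes["t"] >= t0) & (passes["t"] < t0 + cfg.window_s)]
        if len(pw):
            counts = pw.groupby(["athlete_id", "target_athlete_id"]).size().to_numpy()
            p = counts / counts.sum()
            h = -(p * np.log2(p)).sum()
            row["TIE"] = float(h / np.log2(m * (m - 1)))
        else:
            row["TIE"] = float("nan")

        dv = decisive[(decisive["t"] >= t0) & (decisive["t"] < t0 + cfg.window_s)]
        if len(dv):
            r_vals = []
            for _, ev in dv.iterrows():
                k = min(int(round((ev["t"] - t[0]) * rate)), len(t) - 1)
                r_vals.append(order_parameter(phases.phases[k][None, :])[0])
            row["DMS"] = float(np.mean(r_vals))
        else:
            row["DMS"] = float("nan")

        load_w = loads_arr[sel][-1] - loads_arr[sel][0]
        row["LDH"] = float(1.0 - gini(np.clip(load_w, 0, None)))

        grid = occupancy_grid(team, cfg.zone_nx, cfg.zone_ny, cfg.pitch_extent,
                              frames=sel)
        row["S_spatial"] = spatial_entropy(grid)

        rpm_val, _ = rpm(dw, np.repeat(d_ref, dw.shape[0], axis=0))
        row["RPM"] = rpm_val
        row["R_mean"] = float(np.nanmean(R_t[sel]))

        rows.append(row)
        ssi_list.append(row["SSI"])

    table = pd.DataFrame(rows)
    t_windows = table["t"].to_numpy()
    ssi_arr = np.asarray(ssi_list)
    table["CPR"] = np.nan
    cpr_values = []
    for _, ev in perturbations.iterrows():
        rec = perturbation_recovery(t_windows, ssi_arr, float(ev["t"]),
                                    cfg.cpr_baseline_windows)
        cpr_values.append({"t_perturbation": float(ev["t"]), "recovery_s": rec})
        if np.isfinite(rec):
            k = int(np.argmin(np.abs(t_windows - float(ev["t"]))))
            table.loc[k, "CPR"] = rec
    cols = [c for c in IndicatorSeries.COLUMNS if c in table.columns]
    return IndicatorSeries(table=table[cols], window_s=cfg.window_s,
                           extras={"CPR_events": cpr_values})
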