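"""Asynchronous multi-stream alignment.

Sensor streams arrive at heterogeneous rates with independent latencies.
This module provides the machinery to bring them onto one uniform grid:

* plain dynamic time warping (baseline and test oracle),
* movement-phase event detection (stride peaks / direction changes),
* phase-matched resampling: a piecewise-linear time warp that maps a
  stream's movement-cycle anchors onto a reference stream's anchors,
  followed by B-spline interpolation onto a uniform output grid,
* a phase-coherence QC metric (mean cosine of phase deviations from the
  reference phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import BSpline, make_interp_spline

from .errors import AlignmentError, ValidationError
from .session import SensorStream

DEFAULT_DEGREE = 3
DEFAULT_OUT_RATE_HZ = 20.0


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

@dataclass
class WarpResult:
    dtw_distance: float
    path: list[tuple[int, int]]       # 0-based index pairs, boundary-anchored
    element_metric: str = "abs"


def dtw(x: np.ndarray, y: np.ndarray, metric: str = "abs") -> WarpResult:
    """Dynamic time warping with steps {(1,0),(0,1),(1,1)}, both ends anchored.

    ``DTW(i,j) = d(x_i, y_j) + min(DTW(i-1,j), DTW(i-1,j-1), DTW(i,j-1))``
    computed by an O(nm) dynamic program; the returned path is the arg-min
    monotone index pairing (0-based).
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    n, m = x.shape[0], y.shape[0]
    if n == 0 or m == 0:
        raise ValidationError("dtw: empty input series")
    if metric == "abs":
        d = np.abs(x[:, None, :] - y[None, :, :]).sum(axis=2)
    elif metric == "sqeuclidean":
        d = ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)
    elif metric == "euclidean":
        d = np.sqrt(((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ValidationError(f"dtw: unknown metric {metric!r}")
    cost = np.full((n + 1, m + 1), np.inf)
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost[i, j] = d[i - 1, j - 1] + min(cost[i - 1, j],
                                               cost[i - 1, j - 1],
                                               cost[i, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        costs = [cost[a, b] for a, b in moves]
        i, j = moves[int(np.argmin(costs))]
        path.append((i - 1, j - 1))
    path.reverse()
    return WarpResult(dtw_distance=float(cost[n, m]), path=path,
                      element_metric=metric)


# ---------------------------------------------------------------------------
# movement-phase events
# ---------------------------------------------------------------------------

@dataclass
class PhaseEvents:
    event_times: np.ndarray
    method: str = "peak"
    flat_signal: bool = False

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, float)
        if self.event_times.size > 1 and not np.all(np.diff(self.event_times) > 0):
            raise ValidationError("PhaseEvents: event_times must be strictly increasing")


def detect_phase_events(stream: SensorStream | None = None, *,
                        t: np.ndarray | None = None,
                        x: np.ndarray | None = None,
                        channel: int = 0,
                        smooth_cutoff_hz: float | None = None) -> PhaseEvents:
    """One anchor event per fundamental movement cycle (dominant-signal peaks).

    The dominant channel is mean-removed, optionally low-pass smoothed, and
    cycle anchors are taken as prominent positive peaks separated by at least
    half the dominant period.  A flat signal yields no events and a warning
    flag rather than an error.
    """
    if stream is not None:
        t = stream.t
        x = stream.values[:, channel]
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    ok = np.isfinite(x)
    t, x = t[ok], x[ok]
    if x.size < 4 or np.ptp(x) < 1e-12:
        return PhaseEvents(np.empty(0), flat_signal=True)
    fs = 1.0 / float(np.median(np.diff(t)))
    z = x - x.mean()
    if smooth_cutoff_hz is not None and smooth_cutoff_hz < fs / 2:
        sos = sp_signal.butter(4, smooth_cutoff_hz, btype="low", fs=fs, output="sos")
        z = sp_signal.sosfiltfilt(sos, z)
    # dominant period from the power spectrum fixes the minimum peak spacing
    freqs, pxx = sp_signal.periodogram(z, fs=fs)
    if pxx[1:].sum() <= 0:
        return PhaseEvents(np.empty(0), flat_signal=True)
    f0 = freqs[1:][np.argmax(pxx[1:])]
    min_dist = max(1, int(0.5 * fs / f0)) if f0 > 0 else 1
    peaks, _ = sp_signal.find_peaks(z, distance=min_dist,
                                    prominence=0.5 * np.std(z))
    return PhaseEvents(t[peaks], flat_signal=peaks.size == 0)


# ---------------------------------------------------------------------------
# phase-matched B-spline resampling
# ---------------------------------------------------------------------------

@dataclass
class SplineAlignment:
    grid: np.ndarray                  # uniform output times, seconds
    values: np.ndarray                # (n_grid, n_channels) aligned signal
    knot_vector: np.ndarray
    control_points: np.ndarray
    degree: int = DEFAULT_DEGREE
    c_phase: float | None = None
    warp_anchors: tuple = field(default_factory=tuple)  # (stream_times, ref_times)


def _pair_events(ev: PhaseEvents, ref: PhaseEvents,
                 max_count_mismatch: int = 1) -> tuple[np.ndarray, np.ndarray]:
    a, b = ev.event_times, ref.event_times
    if abs(a.size - b.size) > max_count_mismatch:
        raise AlignmentError(
            f"event count mismatch beyond tolerance: {a.size} vs {b.size}")
    m = min(a.size, b.size)
    return a[:m], b[:m]


def _warp_times(t: np.ndarray, anchors_from: np.ndarray,
                anchors_to: np.ndarray) -> np.ndarray:
    """Piecewise-linear monotone warp mapping anchors_from -> anchors_to.

    Outside the anchor span the warp continues with unit slope (constant
    offset), so endpoints stay ordered.
    """
    if anchors_from.size == 0:
        return t.copy()
    if anchors_from.size == 1:
        return t + (anchors_to[0] - anchors_from[0])
    out = np.interp(t, anchors_from, anchors_to)
    lo = t < anchors_from[0]
    hi = t > anchors_from[-1]
    out[lo] = t[lo] + (anchors_to[0] - anchors_from[0])
    out[hi] = t[hi] + (anchors_to[-1] - anchors_from[-1])
    return out


def bspline_align(stream: SensorStream, events: PhaseEvents,
                  reference_events: PhaseEvents,
                  degree: int = DEFAULT_DEGREE,
                  out_rate_hz: float = DEFAULT_OUT_RATE_HZ,
                  reference_signal: np.ndarray | None = None) -> SplineAlignment:
    """Warp a stream onto a reference clock and resample on a uniform grid.

    The stream's cycle anchors are mapped onto the reference anchors by a
    piecewise-linear warp; the warped samples become control points of an
    interpolating B-spline of the given degree (clamped ends), evaluated on
    a uniform grid at ``out_rate_hz``.  Degree 1 therefore reduces exactly to
    piecewise-linear interpolation.  If ``reference_signal`` (sampled on the
    output grid) is given, the Hilbert phase coherence between the aligned
    signal and the reference is reported as QC.
    """
    t = stream.t
    vals = stream.values
    ok = stream.valid_mask() & np.isfinite(vals).all(axis=1)
    t, vals = t[ok], vals[ok]
    if t.size < degree + 1:
        raise AlignmentError(
            f"need at least degree+1={degree + 1} samples, got {t.size}")
    a, b = _pair_events(events, reference_events)
    wt = _warp_times(t, a, b)
    if np.any(np.diff(wt) <= 0):
        raise AlignmentError("warp produced non-monotone timestamps")
    spline = make_interp_spline(wt, vals, k=degree, axis=0)
    dt_out = 1.0 / out_rate_hz
    start = np.ceil(wt[0] / dt_out) * dt_out
    n = int(np.floor((wt[-1] - start) / dt_out)) + 1
    grid = start + np.arange(n) * dt_out
    aligned = np.atleast_2d(spline(grid))
    if aligned.shape[0] != grid.size:
        aligned = aligned.T
    c_phase = None
    if reference_signal is not None:
        c_phase = alignment_phase_coherence(aligned[:, 0],
                                            np.asarray(reference_signal, float),
                                            out_rate_hz)
    return SplineAlignment(grid=grid, values=aligned,
                           knot_vector=np.asarray(spline.t),
                           control_points=np.asarray(spline.c),
                           degree=degree, c_phase=c_phase,
                           warp_anchors=(a, b))


def bspline_basis_matrix(knot_vector: np.ndarray, degree: int,
                         t: np.ndarray) -> np.ndarray:
    """Dense matrix of B-spline basis functions N_{i,d}(t); rows sum to 1."""
    return BSpline.design_matrix(t, knot_vector, degree).toarray()


# ---------------------------------------------------------------------------
# phase coherence
# ---------------------------------------------------------------------------

def phase_coherence(phases: np.ndarray, reference_phase) -> float:
    """``C_phase = mean(cos(phi_i - phi_ref))``; 1 = perfect lock, 0 = random."""
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValidationError("phase_coherence: need at least one phase")
    ref = np.asarray(reference_phase, float)
    return float(np.mean(np.cos(phases - ref)))


def alignment_phase_coherence(x: np.ndarray, reference: np.ndarray,
                              rate_hz: float) -> float:
    """Phase coherence between two equal-rate signals via their Hilbert phases.

    Both series are truncated to the common length and 5% edges are trimmed
    to avoid transform edge effects.
    """
    from .indicators import hilbert_phase  # local import: indicators owns the transform
    n = min(x.size, reference.size)
    px = hilbert_phase(x[:n], rate_hz).phases[:, 0]
    pr = hilbert_phase(reference[:n], rate_hz).phases[:, 0]
    trim = max(1, int(0.05 * n))
    return phase_coherence(px[trim:-trim], pr[trim:-trim])
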