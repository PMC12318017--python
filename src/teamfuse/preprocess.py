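"""Sensor-level fusion (SLF): filtering, signal quality, orientation.

This stage harmonizes each raw device stream before any cross-sensor
fusion: zero-lag low-pass filtering, SNR / sampling-consistency estimation
with a recalibration flag, and complementary-filter orientation estimation
from gyroscope and accelerometer channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .errors import DataError, ValidationError
from .session import SensorStream

#: default low-pass cutoffs per modality, Hz.  Chosen to keep the 15-20 Hz
#: rapid directional-change band for inertial data while suppressing
#: wide-band sensor noise; positional fixes and heart rate are far slower.
DEFAULT_CUTOFF_HZ = {"imu": 12.0, "gps": 2.0, "lps": 2.0, "physio": 0.5,
                     "insole": 12.0}

SNR_FLOOR_DB = 15.0     # below this a stream is flagged for recalibration
DEFAULT_ALPHA = 0.98    # complementary-filter gyro trust


@dataclass
class FilterSpec:
    """Zero-lag Butterworth low-pass specification."""

    cutoff_hz: float
    order: int = 4
    zero_lag: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.cutoff_hz < fs / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={fs / 2} Hz)")


@dataclass
class OrientationState:
    theta_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = DEFAULT_ALPHA
    dt: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must be in [0, 1]")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")


@dataclass
class StreamQuality:
    snr_db: float
    a_signal: float
    a_noise: float
    sampling_consistency: float
    needs_recalibration: bool
    snr_infinite: bool = False


def _sample_rate(stream: SensorStream) -> float:
    dt = np.diff(stream.t)
    if dt.size == 0:
        raise DataError(f"stream {stream.sensor_id!r}: too short")
    return 1.0 / float(np.median(dt))


def butterworth_zero_lag(stream: SensorStream, spec: FilterSpec) -> SensorStream:
    """Forward-backward fourth-order Butterworth low-pass (zero phase, DC gain 1).

    Dropout samples are bridged by linear interpolation before filtering and
    remain flagged in the returned stream's mask.
    """
    fs = _sample_rate(stream)
    spec.validate(fs)
    sos = sp_signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs,
                           output="sos")
    vals = _fill_dropouts(stream)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = sp_signal.sosfiltfilt(sos, vals[:, j])
    return replace_values(stream, out)


def _fill_dropouts(stream: SensorStream) -> np.ndarray:
    vals = stream.values.copy()
    bad = stream.dropout
    if bad.any():
        if bad.all():
            raise DataError(f"stream {stream.sensor_id!r}: all samples dropped")
        ok = ~bad
        for j in range(vals.shape[1]):
            vals[bad, j] = np.interp(stream.t[bad], stream.t[ok], vals[ok, j])
    return vals


def replace_values(stream: SensorStream, values: np.ndarray) -> SensorStream:
    return SensorStream(
        athlete_id=stream.athlete_id, sensor_id=stream.sensor_id,
        modality=stream.modality, channel_names=list(stream.channel_names),
        t=stream.t.copy(), values=values, units=list(stream.units),
        nominal_accuracy=list(stream.nominal_accuracy),
        latency_s=stream.latency_s, dropout=stream.dropout.copy())


def compute_snr(signal_rms: float, noise_rms: float) -> float:
    """SNR in dB: ``20 * log10(signal_rms / noise_rms)``.

    A zero noise amplitude returns ``+inf``; callers that need a flag use
    :func:`estimate_stream_quality`.
    """
    if signal_rms < 0 or noise_rms < 0:
        raise ValidationError("RMS amplitudes must be non-negative")
    if noise_rms == 0:
        return np.inf
    if signal_rms == 0:
        return -np.inf
    return 20.0 * np.log10(signal_rms / noise_rms)


def estimate_stream_quality(stream: SensorStream,
                            cutoff_hz: float | None = None,
                            snr_floor_db: float = SNR_FLOOR_DB) -> StreamQuality:
    """Per-stream quality: SNR, sampling consistency, recalibration flag.

    The noise amplitude is operationalized as the RMS of the out-of-band
    residual (raw minus zero-lag low-pass), and the signal amplitude as the
    RMS of the mean-removed filtered signal, so a constant offset affects
    neither band.  Streams falling below ``snr_floor_db`` are flagged for
    recalibration.
    """
    if stream.dropout.all():
        return StreamQuality(snr_db=-np.inf, a_signal=0.0, a_noise=0.0,
                             sampling_consistency=0.0, needs_recalibration=True)
    if stream.t[-1] - stream.t[0] < 2.0:
        raise DataError(f"stream {stream.sensor_id!r}: need >= 2 s of data")
    cutoff = cutoff_hz if cutoff_hz is not None else \
        DEFAULT_CUTOFF_HZ[stream.modality]
    filtered = butterworth_zero_lag(stream, FilterSpec(cutoff_hz=cutoff))
    raw = _fill_dropouts(stream)
    resid = raw - filtered.values
    ok = stream.valid_mask()
    trim = max(1, int(0.05 * stream.t.size))   # drop filtfilt edge transients
    ok = ok.copy()
    ok[:trim] = ok[-trim:] = False
    smooth = filtered.values[ok] - filtered.values[ok].mean(axis=0)
    a_signal = float(np.sqrt(np.mean(smooth ** 2)))
    a_noise = float(np.sqrt(np.mean(resid[ok] ** 2)))
    snr = compute_snr(a_signal, a_noise)
    dt = np.diff(stream.t)
    nominal = np.median(dt)
    consistency = float(np.mean(np.abs(dt - nominal) < 0.1 * nominal))
    return StreamQuality(
        snr_db=snr, a_signal=a_signal, a_noise=a_noise,
        sampling_consistency=consistency,
        needs_recalibration=bool(snr < snr_floor_db),
        snr_infinite=bool(np.isinf(snr) and snr > 0))


# ---------------------------------------------------------------------------
# complementary-filter orientation
# ---------------------------------------------------------------------------

def complementary_filter(theta_prev: float, omega: float, phi: float,
                         alpha: float, dt: float) -> float:
    """One scalar update: ``theta = alpha*(theta_prev + omega*dt) + (1-alpha)*phi``.

    ``omega`` is the gyro rate (deg/s), ``phi`` the inclination reference
    (deg) from the accelerometer (or magnetometer for yaw).
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0, 1]")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    return alpha * (theta_prev + omega * dt) + (1 - alpha) * phi


def complementary_filter_series(omega: np.ndarray, phi: np.ndarray, alpha: float,
                                dt: float, theta0: float | None = None) -> np.ndarray:
    """Run the complementary filter over full rate/reference series."""
    omega = np.asarray(omega, float)
    phi = np.asarray(phi, float)
    out = np.empty_like(phi)
    theta = phi[0] if theta0 is None else theta0
    for i in range(phi.size):
        theta = complementary_filter(theta, omega[i], phi[i], alpha, dt)
        out[i] = theta
    return out


def inclination_from_acc(acc_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Roll and pitch (deg) from the gravity component of accelerometer axes."""
    ax, ay, az = acc_g[:, 0], acc_g[:, 1], acc_g[:, 2]
    roll = np.degrees(np.arctan2(ay, az))
    pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    return roll, pitch


def estimate_orientation(imu: SensorStream, alpha: float = DEFAULT_ALPHA
                         ) -> np.ndarray:
    """Per-axis complementary-filter orientation (roll, pitch, yaw), degrees.

    Three independent scalar filters: gyro-integrated rate blended with the
    accelerometer inclination (roll, pitch) or magnetometer heading (yaw).
    """
    names = imu.channel_names
    vals = _fill_dropouts(imu)
    acc = vals[:, [names.index(c) for c in ("acc_x_g", "acc_y_g", "acc_z_g")]]
    gyro = vals[:, [names.index(c) for c in
                    ("gyro_roll_dps", "gyro_pitch_dps", "gyro_yaw_dps")]]
    yaw_ref = vals[:, names.index("mag_yaw_deg")]
    roll_ref, pitch_ref = inclination_from_acc(acc)
    dt = float(np.median(np.diff(imu.t)))
    return np.column_stack([
        complementary_filter_series(gyro[:, 0], roll_ref, alpha, dt),
        complementary_filter_series(gyro[:, 1], pitch_ref, alpha, dt),
        complementary_filter_series(gyro[:, 2], yaw_ref, alpha, dt)])
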