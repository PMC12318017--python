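"""Synthetic multi-athlete session generator.

The generator produces ground-truth team movement from a coupled-oscillator
model and then observes it through a five-modality wearable sensor network
(IMU, GPS, local positioning, heart-rate, force insoles) with
modality-specific sampling rates, noise magnitudes, transmission latency and
dropouts.

Movement model
--------------
Each athlete ``i`` oscillates about a formation slot that drifts with the
team centroid::

    pos_i(t) = centroid(t) + slot_i + a * (cos psi_i(t), sin psi_i(t))

where the movement phases ``psi_i`` follow Kuramoto dynamics within each
team::

    d psi_i = omega_i dt + (kappa / n) * sum_j sin(psi_j - psi_i) dt
              + sigma_psi dW

The coupling strength ``kappa`` is the team-coordination dial: every
downstream coordination indicator (Kuramoto order parameter R(t), spatial
synchronization, temporal coordination rate) has a known monotone relation
to it, which is what makes parameter-recovery testing possible.
Perturbation events temporarily collapse the coupling, giving the
perturbation-response indicator something real to measure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .session import (AthleteMeta, EventTable, SensorStream, SessionManifest,
                      StreamIndexEntry, TeamTrajectory)

G_MPS2 = 9.80665

#: per-modality nominal sample rates (Hz) of the emulated sensor network
MODALITY_RATES = {"imu": 200.0, "gps": 10.0, "physio": 10.0, "lps": 40.0,
                  "insole": 500.0}

IMU_CHANNELS = ["acc_x_g", "acc_y_g", "acc_z_g",
                "gyro_roll_dps", "gyro_pitch_dps", "gyro_yaw_dps", "mag_yaw_deg"]
GPS_CHANNELS = ["x_m", "y_m", "vx_mps", "vy_mps"]
LPS_CHANNELS = ["x_m", "y_m", "vx_mps", "vy_mps"]
PHYSIO_CHANNELS = ["hr_bpm"]
INSOLE_CHANNELS = ["force_left_n", "force_right_n"]


@dataclass
class SimConfig:
    """Conditions of a simulated session.

    Noise magnitudes default to the deployed sensors' stated accuracies
    (GPS +-0.5 m / +-0.1 m/s, LPS +-0.1 m / +-0.05 m/s, accelerometer
    +-0.02 g, gyroscope +-0.05 deg/s, HR +-1 bpm, insole +-1.2 N).
    """

    n_athletes_per_team: int = 4
    duration_s: float = 120.0
    frame_rate_hz: float = 200.0
    coupling_kappa: float = 2.0
    formation_spacing_m: float = 8.0
    centroid_speed_mps: float = 0.5
    osc_amplitude_m: float = 1.5
    omega_mean_hz: float = 0.25      # fundamental movement-cycle frequency
    omega_sd_hz: float = 0.03
    sigma_psi: float = 0.3           # phase diffusion, rad/sqrt(s)
    pitch_extent: tuple = (-20.0, 20.0, -15.0, 15.0)
    sport: str = "generic"
    # sensor corruption
    noise_profile: dict = field(default_factory=lambda: {
        "gps_pos": 0.5, "gps_vel": 0.1, "lps_pos": 0.1, "lps_vel": 0.05,
        "imu_acc": 0.02, "imu_gyro": 0.05, "imu_mag": 0.3,
        "hr": 1.0, "insole": 1.2})
    latency_profile: dict = field(default_factory=lambda: {
        "imu": (0.030, 0.005), "gps": (0.050, 0.010), "physio": (0.040, 0.010),
        "lps": (0.020, 0.005), "insole": (0.030, 0.005)})
    dropout_rate: float = 0.02
    # events
    passes_per_min: float = 6.0
    perturbations_per_min: float = 0.5
    decisive_per_min: float = 2.0
    perturbation_duration_s: float = 5.0
    # outcome model (shifts in per-metric SD units on TCR, CPR, SSI, ICC)
    outcome_effect: tuple = (1.0, -1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.coupling_kappa < 0:
            raise ValidationError("coupling_kappa must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        for name in ("duration_s", "frame_rate_hz", "formation_spacing_m",
                     "omega_mean_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic term switched off (deterministic truth).

        This includes the coupling-suppression perturbations: their Poisson
        timing is random and the kappa switch kinks the dynamics, so a
        noise-free reference session keeps the coupling constant.
        """
        return replace(
            self,
            noise_profile={k: 0.0 for k in self.noise_profile},
            latency_profile={k: (0.0, 0.0) for k in self.latency_profile},
            dropout_rate=0.0, sigma_psi=0.0, omega_sd_hz=0.0,
            perturbations_per_min=0.0)


@dataclass
class GroundTruth:
    """Uncorrupted session state at the simulation frame rate."""

    team: TeamTrajectory                      # all athletes, both teams
    phases: np.ndarray                        # (n_frames, n_athletes) rad, unwrapped
    orientation: dict                         # athlete_id -> (n_frames, 3) deg
    heart_rate: dict                          # athlete_id -> (n_frames,) bpm
    load_rate: dict                           # athlete_id -> (n_frames,) N (total GRF)
    events: EventTable = field(default_factory=EventTable)
    session_outcome: str = "win"


def _child_rng(root_seed: int, *tokens: str) -> np.random.Generator:
    """Stable per-stream RNG: crc32 of the token tuple spawns the child."""
    key = zlib.crc32("|".join(tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([root_seed & 0x7FFFFFFF, key]))


def _formation_slots(n: int, spacing: float, x_sign: float) -> np.ndarray:
    """Slots on a 2-column grid on one half of the pitch."""
    cols = 2
    rows = int(np.ceil(n / cols))
    slots = []
    for k in range(n):
        r, c = divmod(k, cols)
        x = x_sign * (spacing * 0.6 + c * spacing * 0.8)
        y = (r - (rows - 1) / 2.0) * spacing
        slots.append((x, y))
    return np.array(slots)


def _simulate_phases(cfg: SimConfig, n_ath: int, team_of: np.ndarray,
                     perturb_times: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of per-team Kuramoto dynamics.

    Returns (phases, dphases_dt) with the deterministic drift as the rate,
    both shaped (n_frames, n_ath).
    """
    dt = 1.0 / cfg.frame_rate_hz
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz)) + 1
    t = np.arange(n_frames) * dt
    omega = 2 * np.pi * rng.normal(cfg.omega_mean_hz, cfg.omega_sd_hz, size=n_ath)
    psi = np.empty((n_frames, n_ath))
    dpsi = np.empty((n_frames, n_ath))
    psi[0] = rng.uniform(0, 2 * np.pi, size=n_ath)
    suppressed = np.zeros(n_frames, dtype=bool)
    for pt in perturb_times:
        suppressed |= (t >= pt) & (t < pt + cfg.perturbation_duration_s)
    noise = rng.standard_normal((n_frames, n_ath)) * cfg.sigma_psi * np.sqrt(dt)
    teams = [np.where(team_of == g)[0] for g in np.unique(team_of)]
    for k in range(n_frames):
        kappa = cfg.coupling_kappa * (0.1 if suppressed[k] else 1.0)
        drift = omega.copy()
        for idx in teams:
            p = psi[k, idx]
            drift[idx] += (kappa / len(idx)) * np.sin(
                p[None, :] - p[:, None]).sum(axis=1)
        dpsi[k] = drift
        if k + 1 < n_frames:
            psi[k + 1] = psi[k] + drift * dt + noise[k]
    return psi, dpsi


def _poisson_times(rate_per_min: float, duration_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    lam = rate_per_min / 60.0 * duration_s
    n = rng.poisson(lam)
    return np.sort(rng.uniform(0, duration_s, size=n))


def _sensor_times(rate: float, duration: float, t_frames: np.ndarray,
                  frame_rate: float) -> np.ndarray:
    step = frame_rate / rate
    if abs(step - round(step)) < 1e-9 and step >= 1:
        return t_frames[:: int(round(step))]
    n = int(round(duration * rate)) + 1
    return np.arange(n) / rate


def _sample(t_frames: np.ndarray, series: np.ndarray, t_query: np.ndarray
            ) -> np.ndarray:
    return np.interp(t_query, t_frames, series)


def simulate_session(config: SimConfig
                     ) -> tuple[SessionManifest, list[SensorStream], GroundTruth]:
    """Generate one session: manifest + corrupted streams + ground truth.

    Deterministic for a given ``config.seed``.
    """
    config.validate()
    cfg = config
    rng = _child_rng(cfg.seed, "session")
    n_team = cfg.n_athletes_per_team
    n_ath = 2 * n_team
    ids = [f"{t}{k + 1}" for t in ("A", "B") for k in range(n_team)]
    team_of = np.array([0] * n_team + [1] * n_team)
    team_label = {aid: ("A" if g == 0 else "B") for aid, g in zip(ids, team_of)}

    dt = 1.0 / cfg.frame_rate_hz
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz)) + 1
    t_frames = np.arange(n_frames) * dt

    # events that feed back into the dynamics must be drawn first
    ev_rng = _child_rng(cfg.seed, "events")
    perturb_times = _poisson_times(cfg.perturbations_per_min, cfg.duration_s, ev_rng)

    psi, dpsi = _simulate_phases(cfg, n_ath, team_of, perturb_times, rng)

    # centroid path: slow planar figure inside the pitch
    omega_c = 2 * np.pi / 60.0
    amp = cfg.centroid_speed_mps / omega_c
    cx = amp * np.sin(omega_c * t_frames)
    cy = 0.5 * amp * np.sin(2 * omega_c * t_frames)
    cvx = amp * omega_c * np.cos(omega_c * t_frames)
    cvy = amp * omega_c * np.cos(2 * omega_c * t_frames)

    slots = np.vstack([_formation_slots(n_team, cfg.formation_spacing_m, -1.0),
                       _formation_slots(n_team, cfg.formation_spacing_m, +1.0)])

    a = cfg.osc_amplitude_m
    pos = np.empty((n_frames, n_ath, 2))
    vel = np.empty((n_frames, n_ath, 2))
    pos[:, :, 0] = cx[:, None] + slots[None, :, 0] + a * np.cos(psi)
    pos[:, :, 1] = cy[:, None] + slots[None, :, 1] + a * np.sin(psi)
    vel[:, :, 0] = cvx[:, None] - a * np.sin(psi) * dpsi
    vel[:, :, 1] = cvy[:, None] + a * np.cos(psi) * dpsi

    team = TeamTrajectory(t=t_frames, athlete_ids=ids, positions=pos,
                          velocities=vel, team_of=team_label)

    # orientation truth: quasi-static trunk sway locked to the movement phase
    tilt = 5.0  # deg
    heading = np.degrees(np.arctan2(vel[:, :, 1], vel[:, :, 0]))
    heading = np.degrees(np.unwrap(np.radians(heading), axis=0))
    orientation = {}
    heart_rate = {}
    load_rate = {}
    speed = np.linalg.norm(vel, axis=2)
    # first-order HR lag on speed, tau = 30 s
    alpha_hr = dt / (30.0 + dt)
    for k, aid in enumerate(ids):
        roll = tilt * np.sin(psi[:, k])
        pitchv = tilt * np.cos(psi[:, k])
        orientation[aid] = np.column_stack([roll, pitchv, heading[:, k]])
        hr = np.empty(n_frames)
        hr[0] = 60.0
        drive = 60.0 + 18.0 * speed[:, k]
        for i in range(1, n_frames):
            hr[i] = hr[i - 1] + alpha_hr * (drive[i] - hr[i - 1])
        heart_rate[aid] = hr
        left = np.clip(np.sin(psi[:, k]), 0, None) ** 2
        right = np.clip(-np.sin(psi[:, k]), 0, None) ** 2
        load_rate[aid] = 700.0 * (left + right)

    # remaining discrete events
    events = _make_events(cfg, team, perturb_times, ev_rng)
    outcome = "win" if ev_rng.random() < 0.5 else "loss"

    truth = GroundTruth(team=team, phases=psi, orientation=orientation,
                        heart_rate=heart_rate, load_rate=load_rate,
                        events=events, session_outcome=outcome)

    streams, index = _observe(cfg, truth, ids, t_frames)

    athletes = [AthleteMeta(athlete_id=aid, role="field", team=team_label[aid],
                            sensors=[e.sensor_id for e in index
                                     if e.athlete_id == aid])
                for aid in ids]
    manifest = SessionManifest(
        session_id=f"sim-{cfg.seed}", sport=cfg.sport,
        pitch_extent=tuple(cfg.pitch_extent), athletes=athletes,
        master_clock_epoch=0.0, stream_index=index)
    manifest.validate()
    return manifest, streams, truth


def _make_events(cfg: SimConfig, team: TeamTrajectory,
                 perturb_times: np.ndarray, rng: np.random.Generator) -> EventTable:
    rows = []
    for pt in perturb_times:
        rows.append({"t": pt, "event_type": "perturbation", "athlete_id": None,
                     "target_athlete_id": None, "outcome": None})
    n_ath = team.n_athletes
    by_team = {}
    for k, aid in enumerate(team.athlete_ids):
        by_team.setdefault(team.team_of[aid], []).append(k)
    for label, members in by_team.items():
        for pt in _poisson_times(cfg.passes_per_min, cfg.duration_s, rng):
            frame = min(int(round(pt * cfg.frame_rate_hz)), len(team.t) - 1)
            src = members[rng.integers(len(members))]
            d = np.linalg.norm(team.positions[frame, members]
                               - team.positions[frame, src], axis=1)
            d[members.index(src)] = np.inf
            dst = members[int(np.argmin(d))]
            rows.append({"t": pt, "event_type": "pass",
                         "athlete_id": team.athlete_ids[src],
                         "target_athlete_id": team.athlete_ids[dst],
                         "outcome": "complete"})
        for pt in _poisson_times(cfg.decisive_per_min, cfg.duration_s, rng):
            k = members[rng.integers(len(members))]
            rows.append({"t": pt, "event_type": "decisive_action",
                         "athlete_id": team.athlete_ids[k],
                         "target_athlete_id": None, "outcome": None})
    if not rows:
        return EventTable()
    df = pd.DataFrame(rows).sort_values("t").reset_index(drop=True)
    return EventTable(df)


def _observe(cfg: SimConfig, truth: GroundTruth, ids: list[str],
             t_frames: np.ndarray) -> tuple[list[SensorStream], list[StreamIndexEntry]]:
    """Resample truth at each modality's rate, delay, add noise and dropouts."""
    np_ = cfg.noise_profile
    streams: list[SensorStream] = []
    index: list[StreamIndexEntry] = []
    team = truth.team
    for k, aid in enumerate(ids):
        specs = [
            ("imu", IMU_CHANNELS,
             ["g", "g", "g", "deg/s", "deg/s", "deg/s", "deg"],
             [np_["imu_acc"]] * 3 + [np_["imu_gyro"]] * 3 + [np_["imu_mag"]]),
            ("gps", GPS_CHANNELS, ["m", "m", "m/s", "m/s"],
             [np_["gps_pos"]] * 2 + [np_["gps_vel"]] * 2),
            ("lps", LPS_CHANNELS, ["m", "m", "m/s", "m/s"],
             [np_["lps_pos"]] * 2 + [np_["lps_vel"]] * 2),
            ("physio", PHYSIO_CHANNELS, ["bpm"], [np_["hr"]]),
            ("insole", INSOLE_CHANNELS, ["N", "N"], [np_["insole"]] * 2),
        ]
        for modality, channels, units, sigmas in specs:
            rng = _child_rng(cfg.seed, aid, modality)
            rate = MODALITY_RATES[modality]
            t_s = _sensor_times(rate, cfg.duration_s, t_frames, cfg.frame_rate_hz)
            mean_lat, jit = cfg.latency_profile[modality]
            lat = np.clip(mean_lat + jit * rng.standard_normal(t_s.size), 0, None) \
                if (mean_lat or jit) else np.zeros(t_s.size)
            tq = np.clip(t_s - lat, 0, t_frames[-1])
            vals = _modality_truth(modality, truth, team, k, aid, t_frames, tq)
            for j, s in enumerate(sigmas):
                if s:
                    vals[:, j] = vals[:, j] + s * rng.standard_normal(t_s.size)
            drop = rng.random(t_s.size) < cfg.dropout_rate \
                if cfg.dropout_rate else np.zeros(t_s.size, dtype=bool)
            vals[drop] = np.nan
            sensor_id = f"{aid}-{modality}"
            streams.append(SensorStream(
                athlete_id=aid, sensor_id=sensor_id, modality=modality,
                channel_names=list(channels), t=t_s, values=vals,
                units=list(units), nominal_accuracy=[float(s) for s in sigmas],
                latency_s=float(mean_lat), dropout=drop))
            index.append(StreamIndexEntry(
                athlete_id=aid, sensor_id=sensor_id, modality=modality,
                path=f"streams/{sensor_id}.csv", sample_rate_hz=rate,
                units=list(units), nominal_accuracy=[float(s) for s in sigmas],
                latency_s=float(mean_lat)))
    return streams, index


def _modality_truth(modality: str, truth: GroundTruth, team: TeamTrajectory,
                    k: int, aid: str, t_frames: np.ndarray,
                    tq: np.ndarray) -> np.ndarray:
    if modality in ("gps", "lps"):
        return np.column_stack([
            _sample(t_frames, team.positions[:, k, 0], tq),
            _sample(t_frames, team.positions[:, k, 1], tq),
            _sample(t_frames, team.velocities[:, k, 0], tq),
            _sample(t_frames, team.velocities[:, k, 1], tq)])
    if modality == "physio":
        return _sample(t_frames, truth.heart_rate[aid], tq)[:, None]
    if modality == "insole":
        psi = _sample(t_frames, truth.phases[:, k], tq)
        left = 700.0 * np.clip(np.sin(psi), 0, None) ** 2
        right = 700.0 * np.clip(-np.sin(psi), 0, None) ** 2
        return np.column_stack([left, right])
    # imu: gravity-component accelerometer, gyro rates, magnetometer yaw
    ori = truth.orientation[aid]
    roll = np.radians(_sample(t_frames, ori[:, 0], tq))
    pitch = np.radians(_sample(t_frames, ori[:, 1], tq))
    acc_x = -np.sin(pitch)
    acc_y = np.sin(roll) * np.cos(pitch)
    acc_z = np.cos(roll) * np.cos(pitch)
    dt = t_frames[1] - t_frames[0]
    rates = np.gradient(ori, dt, axis=0)  # deg/s per axis
    gyro = np.column_stack([_sample(t_frames, rates[:, j], tq) for j in range(3)])
    yaw = _sample(t_frames, ori[:, 2], tq)
    return np.column_stack([acc_x, acc_y, acc_z, gyro, yaw])


# ---------------------------------------------------------------------------
# corruption and outcome-dataset helpers
# ---------------------------------------------------------------------------

def inject_noise(stream: SensorStream, amplitude_fraction: float,
                 seed: int) -> SensorStream:
    """Add zero-mean Gaussian noise scaled to a fraction of each channel's RMS.

    The per-channel sigma is ``amplitude_fraction`` times the RMS of the
    mean-removed channel, so a 0.3 injection on any signal lands it at
    ``20*log10(1/0.3) ~ 10.5 dB`` SNR regardless of DC offset.
    """
    if not (0 <= amplitude_fraction <= 1):
        raise ValidationError("amplitude_fraction must be in [0, 1]")
    if amplitude_fraction == 0:
        return stream
    rng = np.random.default_rng(seed)
    vals = stream.values.copy()
    ok = stream.valid_mask()
    for j in range(vals.shape[1]):
        col = vals[ok, j]
        rms = float(np.sqrt(np.mean((col - col.mean()) ** 2))) if col.size else 0.0
        vals[ok, j] = col + amplitude_fraction * rms * rng.standard_normal(col.size)
    return SensorStream(
        athlete_id=stream.athlete_id, sensor_id=stream.sensor_id,
        modality=stream.modality, channel_names=list(stream.channel_names),
        t=stream.t.copy(), values=vals, units=list(stream.units),
        nominal_accuracy=list(stream.nominal_accuracy),
        latency_s=stream.latency_s, dropout=stream.dropout.copy())


OUTCOME_METRICS = ("TCR", "CPR", "SSI", "ICC")
_METRIC_BASE = {"TCR": (0.40, 0.08), "CPR": (5.0, 1.2),
                "SSI": (0.50, 0.10), "ICC": (0.50, 0.10)}


def make_outcome_dataset(config: SimConfig, n_sessions: int, seed: int | None = None
                         ) -> list[tuple[dict, str]]:
    """Session-level indicator summaries with a win/loss label.

    Features are Gaussian around sport-plausible baselines; win sessions are
    shifted by ``config.outcome_effect`` (in per-metric SD units) on
    (TCR, CPR, SSI, ICC).  Classes are balanced.
    """
    if n_sessions < 2:
        raise ValidationError("n_sessions must be >= 2")
    shift = np.asarray(config.outcome_effect, dtype=float)
    if shift.shape != (4,):
        raise ValidationError("outcome_effect must have 4 entries (TCR, CPR, SSI, ICC)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for s in range(n_sessions):
        won = s % 2 == 0
        z = rng.standard_normal(4) + (shift if won else 0.0)
        feats = {}
        for j, name in enumerate(OUTCOME_METRICS):
            mu, sd = _METRIC_BASE[name]
            feats[name] = mu + sd * z[j]
        out.append((feats, "win" if won else "loss"))
    return out
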