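"""Session data model and on-disk formats.

A *session* is one recorded training game: a JSON manifest describing the
pitch, athletes and sensor deployment, one CSV per sensor stream, and an
optional event table (passes, perturbations, decisive actions).

Conventions
-----------
* Positions are 2-D pitch coordinates in metres, origin at pitch centre,
  x toward team A's attacking direction.
* Time is seconds (float64) on a single master clock shared by all devices;
  per-stream transmission latency is stored as metadata and never
  pre-corrected in the raw files.
* Dropouts are an explicit 0/1 ``dropout`` column; a dropped sample has NaN
  values and mask 1.  NaN anywhere else is a structural error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

SPORTS = ("basketball", "soccer", "volleyball", "handball", "generic")
MODALITIES = ("imu", "gps", "lps", "physio", "insole")
EVENT_TYPES = ("pass", "possession_change", "perturbation", "decisive_action",
               "shot", "alert")

EVENT_COLUMNS = ["t", "event_type", "athlete_id", "target_athlete_id", "outcome"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AthleteMeta:
    athlete_id: str
    role: str
    team: str  # "A" or "B"
    sensors: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.team not in ("A", "B"):
            raise ValidationError(f"athlete {self.athlete_id!r}: team must be 'A' or 'B'")
        if not self.sensors:
            raise ValidationError(f"athlete {self.athlete_id!r}: empty sensors list")


@dataclass
class StreamIndexEntry:
    athlete_id: str
    sensor_id: str
    modality: str
    path: str
    sample_rate_hz: float
    units: list[str] = field(default_factory=list)
    nominal_accuracy: list[float] = field(default_factory=list)
    latency_s: float = 0.0


@dataclass
class SessionManifest:
    session_id: str
    sport: str
    pitch_extent: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    athletes: list[AthleteMeta]
    master_clock_epoch: float
    stream_index: list[StreamIndexEntry]

    def validate(self) -> None:
        if self.sport not in SPORTS:
            raise ValidationError(f"sport: unknown value {self.sport!r}")
        x0, x1, y0, y1 = self.pitch_extent
        if not (x1 > x0 and y1 > y0):
            raise ValidationError("pitch_extent: degenerate extent")
        ids = [a.athlete_id for a in self.athletes]
        if len(set(ids)) != len(ids):
            raise ValidationError("athletes: athlete_ids not unique")
        for a in self.athletes:
            a.validate()
        known = set(ids)
        for e in self.stream_index:
            if e.athlete_id not in known:
                raise ValidationError(
                    f"stream_index: stream {e.sensor_id!r} references undeclared "
                    f"athlete {e.athlete_id!r}")
            if e.modality not in MODALITIES:
                raise ValidationError(f"stream_index: unknown modality {e.modality!r}")
            if not e.sample_rate_hz > 0:
                raise ValidationError(
                    f"stream_index: sample_rate_hz must be > 0 for {e.sensor_id!r}")


@dataclass
class SensorStream:
    """One timestamped multi-channel signal from one device on one athlete."""

    athlete_id: str
    sensor_id: str
    modality: str
    channel_names: list[str]
    t: np.ndarray                 # (n,) seconds, strictly increasing, master clock
    values: np.ndarray            # (n, n_channels)
    units: list[str] = field(default_factory=list)
    nominal_accuracy: list[float] = field(default_factory=list)
    latency_s: float = 0.0
    dropout: np.ndarray | None = None  # (n,) bool; True = sample lost

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.t.shape[0]:
            self.values = self.values.T
        if self.dropout is None:
            self.dropout = np.zeros(self.t.shape[0], dtype=bool)
        else:
            self.dropout = np.asarray(self.dropout, dtype=bool)

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"stream {self.sensor_id!r}: unknown modality")
        if self.t.ndim != 1 or self.values.shape[0] != self.t.shape[0]:
            raise DataError(f"stream {self.sensor_id!r}: values row count != len(t)")
        if self.values.shape[1] != len(self.channel_names):
            raise DataError(f"stream {self.sensor_id!r}: channel count mismatch")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError(f"stream {self.sensor_id!r}: timestamps not strictly increasing")
        bad = np.isnan(self.values).any(axis=1) & ~self.dropout
        if bad.any():
            raise DataError(
                f"stream {self.sensor_id!r}: NaN outside dropout mask at "
                f"{int(bad.sum())} samples")

    def valid_mask(self) -> np.ndarray:
        return ~self.dropout


@dataclass
class EventTable:
    """Timestamped discrete events (passes, perturbations, decisive actions)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        for c in EVENT_COLUMNS:
            if c not in self.table.columns:
                self.table[c] = pd.Series(dtype=object)
        self.table = self.table[EVENT_COLUMNS].reset_index(drop=True)

    def validate(self, span: tuple[float, float] | None = None) -> None:
        for _, row in self.table.iterrows():
            if row["event_type"] not in EVENT_TYPES:
                raise ValidationError(f"events: unknown event_type {row['event_type']!r}")
            if row["event_type"] == "pass":
                if pd.isna(row["athlete_id"]) or pd.isna(row["target_athlete_id"]):
                    raise ValidationError("events: pass row missing athlete ids")
        if span is not None and len(self.table):
            t = self.table["t"].astype(float)
            if (t < span[0] - 1e-9).any() or (t > span[1] + 1e-9).any():
                raise ValidationError("events: timestamp outside session span")

    def of_type(self, event_type: str) -> pd.DataFrame:
        return self.table[self.table["event_type"] == event_type]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AlignedAthleteRecord:
    """Per-athlete fused state on a uniform common-clock grid (ILF output)."""

    athlete_id: str
    t: np.ndarray                       # uniform grid, seconds
    position: np.ndarray                # (n, 2) metres
    velocity: np.ndarray                # (n, 2) m/s
    acceleration: np.ndarray            # (n, 2) m/s^2
    orientation: np.ndarray             # (n, 3) degrees (roll, pitch, yaw)
    heart_rate: np.ndarray              # (n,) bpm
    load: np.ndarray                    # (n,) cumulative load, a.u.
    weight_history: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class TeamTrajectory:
    """Per-frame planar state of every athlete plus the team centroid."""

    t: np.ndarray                       # (n,) seconds, uniform
    athlete_ids: list[str] = field(default_factory=list)
    positions: np.ndarray = None        # (n, n_ath, 2) metres
    velocities: np.ndarray = None       # (n, n_ath, 2) m/s
    team_of: dict[str, str] = field(default_factory=dict)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=1)

    @property
    def centroid_velocity(self) -> np.ndarray:
        return self.velocities.mean(axis=1)

    @property
    def n_athletes(self) -> int:
        return len(self.athlete_ids)


@dataclass
class IndicatorSeries:
    """Windowed collaborative-dynamics indicators.

    ``table`` holds one row per analysis window with columns ``t`` (window
    centre, seconds) and the indicator values; missing indicators are NaN,
    never silently zero.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    window_s: float = 10.0
    extras: dict = field(default_factory=dict)  # e.g. per-event CPR values

    COLUMNS = ["t", "SSI", "TCR", "FSQ", "TIE", "CPR", "ICC", "DMS", "LDH",
               "S_spatial", "RPM", "R_mean"]


@dataclass
class FusionQualityReport:
    """Per-stream quality plus information-preservation summary."""

    q_info: float | None = None
    mutual_information_bits: float | None = None
    entropy_bits: float | None = None
    snr_db: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    phase_coherence: float | None = None
    position_rmse_m: float | None = None
    temporal_jitter_ms: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


def _manifest_to_dict(m: SessionManifest) -> dict:
    return {
        "session_id": m.session_id,
        "sport": m.sport,
        "pitch_extent": list(m.pitch_extent),
        "master_clock_epoch": m.master_clock_epoch,
        "athletes": [
            {"athlete_id": a.athlete_id, "role": a.role, "team": a.team,
             "sensors": list(a.sensors)} for a in m.athletes],
        "stream_index": [
            {"athlete_id": e.athlete_id, "sensor_id": e.sensor_id,
             "modality": e.modality, "path": e.path,
             "sample_rate_hz": e.sample_rate_hz, "units": list(e.units),
             "nominal_accuracy": list(e.nominal_accuracy),
             "latency_s": e.latency_s}
            for e in m.stream_index],
    }


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise ValidationError(f"{ctx}: missing required field {key!r}")
    return d[key]


def _manifest_from_dict(d: dict) -> SessionManifest:
    athletes = [
        AthleteMeta(
            athlete_id=_require(a, "athlete_id", "athletes[]"),
            role=a.get("role", ""),
            team=_require(a, "team", "athletes[]"),
            sensors=list(_require(a, "sensors", "athletes[]")))
        for a in _require(d, "athletes", "manifest")]
    index = [
        StreamIndexEntry(
            athlete_id=_require(e, "athlete_id", "stream_index[]"),
            sensor_id=_require(e, "sensor_id", "stream_index[]"),
            modality=_require(e, "modality", "stream_index[]"),
            path=_require(e, "path", "stream_index[]"),
            sample_rate_hz=float(_require(e, "sample_rate_hz", "stream_index[]")),
            units=list(e.get("units", [])),
            nominal_accuracy=[float(x) for x in e.get("nominal_accuracy", [])],
            latency_s=float(e.get("latency_s", 0.0)))
        for e in _require(d, "stream_index", "manifest")]
    m = SessionManifest(
        session_id=_require(d, "session_id", "manifest"),
        sport=_require(d, "sport", "manifest"),
        pitch_extent=tuple(float(x) for x in _require(d, "pitch_extent", "manifest")),
        athletes=athletes,
        master_clock_epoch=float(_require(d, "master_clock_epoch", "manifest")),
        stream_index=index)
    m.validate()
    return m


def read_stream_csv(path: Path, entry: StreamIndexEntry) -> SensorStream:
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise DataError(f"stream {entry.sensor_id!r}: no 't' column in {path}")
    dropout = (df["dropout"].to_numpy(dtype=float) > 0.5) if "dropout" in df.columns \
        else None
    channels = [c for c in df.columns if c not in ("t", "dropout")]
    stream = SensorStream(
        athlete_id=entry.athlete_id,
        sensor_id=entry.sensor_id,
        modality=entry.modality,
        channel_names=channels,
        t=df["t"].to_numpy(dtype=float),
        values=df[channels].to_numpy(dtype=float),
        units=list(entry.units),
        nominal_accuracy=list(entry.nominal_accuracy),
        latency_s=entry.latency_s,
        dropout=dropout)
    stream.validate()
    return stream


def read_session(manifest_path: str | Path
                 ) -> tuple[SessionManifest, list[SensorStream], EventTable]:
    """Load a session from disk.

    A missing ``events.csv`` yields an empty :class:`EventTable`.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = _manifest_from_dict(json.load(fh))
    root = manifest_path.parent
    streams = []
    for entry in manifest.stream_index:
        p = root / entry.path
        if not p.exists():
            raise DataError(f"stream file not found: {p}")
        streams.append(read_stream_csv(p, entry))
    ev_path = root / "events.csv"
    if ev_path.exists():
        events = EventTable(pd.read_csv(ev_path))
        events.validate()
    else:
        events = EventTable()
    return manifest, streams, events


def write_session(manifest: SessionManifest, streams: list[SensorStream],
                  events: EventTable | None, out_dir: str | Path) -> Path:
    """Write a session; inverse of :func:`read_session` up to 1e-9 on floats."""
    manifest.validate()
    for s in streams:
        s.validate()
    out = Path(out_dir)
    (out / "streams").mkdir(parents=True, exist_ok=True)
    by_id = {(e.athlete_id, e.sensor_id): e for e in manifest.stream_index}
    for s in streams:
        key = (s.athlete_id, s.sensor_id)
        if key not in by_id:
            raise ValidationError(f"stream {s.sensor_id!r} not in manifest stream_index")
        entry = by_id[key]
        df = pd.DataFrame({"t": s.t})
        for j, name in enumerate(s.channel_names):
            df[name] = s.values[:, j]
        df["dropout"] = s.dropout.astype(int)
        df.to_csv(out / entry.path, index=False, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(_manifest_to_dict(manifest), fh, indent=1)
    if events is not None and len(events):
        events.table.to_csv(out / "events.csv", index=False, float_format=_FLOAT_FMT)
    return out / "manifest.json"


# --- analysis-output writers ------------------------------------------------

def _record_frame(rec: AlignedAthleteRecord) -> pd.DataFrame:
    df = pd.DataFrame({"t_s": rec.t})
    df["x_m"], df["y_m"] = rec.position[:, 0], rec.position[:, 1]
    df["vx_mps"], df["vy_mps"] = rec.velocity[:, 0], rec.velocity[:, 1]
    df["ax_mps2"], df["ay_mps2"] = rec.acceleration[:, 0], rec.acceleration[:, 1]
    df["roll_deg"], df["pitch_deg"], df["yaw_deg"] = (rec.orientation[:, k] for k in range(3))
    df["hr_bpm"] = rec.heart_rate
    df["load_au"] = rec.load
    return df


def _team_frame(team: TeamTrajectory) -> pd.DataFrame:
    df = pd.DataFrame({"t_s": team.t})
    for k, aid in enumerate(team.athlete_ids):
        df[f"{aid}_x_m"] = team.positions[:, k, 0]
        df[f"{aid}_y_m"] = team.positions[:, k, 1]
        df[f"{aid}_vx_mps"] = team.velocities[:, k, 0]
        df[f"{aid}_vy_mps"] = team.velocities[:, k, 1]
    return df


def write_outputs(obj, path: str | Path) -> Path:
    """Serialize an analysis product to CSV (JSON for quality reports)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, AlignedAthleteRecord):
        _record_frame(obj).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, TeamTrajectory):
        _team_frame(obj).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, IndicatorSeries):
        table = obj.table if len(obj.table.columns) else pd.DataFrame(
            columns=IndicatorSeries.COLUMNS)
        cols = [c for c in IndicatorSeries.COLUMNS if c in table.columns]
        cols += [c for c in table.columns if c not in cols]
        table[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif isinstance(obj, FusionQualityReport):
        payload = {
            "q_info": obj.q_info,
            "mutual_information_bits": obj.mutual_information_bits,
            "entropy_bits": obj.entropy_bits,
            "snr_db": obj.snr_db,
            "weights": obj.weights,
            "phase_coherence": obj.phase_coherence,
            "position_rmse_m": obj.position_rmse_m,
            "temporal_jitter_ms": obj.temporal_jitter_ms,
            "flags": obj.flags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)
    else:
        raise ValidationError(f"write_outputs: unsupported object {type(obj).__name__}")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(type(o))


def read_team_trajectory(path: str | Path) -> TeamTrajectory:
    """Inverse of :func:`write_outputs` for team-trajectory CSVs."""
    df = pd.read_csv(path, float_precision="round_trip")
    ids = []
    for c in df.columns:
        if c.endswith("_x_m"):
            ids.append(c[:-len("_x_m")])
    n, m = len(df), len(ids)
    pos = np.empty((n, m, 2))
    vel = np.empty((n, m, 2))
    for k, aid in enumerate(ids):
        pos[:, k, 0] = df[f"{aid}_x_m"]
        pos[:, k, 1] = df[f"{aid}_y_m"]
        vel[:, k, 0] = df[f"{aid}_vx_mps"]
        vel[:, k, 1] = df[f"{aid}_vy_mps"]
    return TeamTrajectory(t=df["t_s"].to_numpy(float), athlete_ids=ids,
                          positions=pos, velocities=vel)
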