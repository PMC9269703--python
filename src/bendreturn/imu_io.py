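"""Data model and delimited-text I/O for 3-sensor IMU recordings.

A recording of the instrumented trunk bending-and-return (b&r) test consists
of three inertial sensors — SENS1 at T12 (lower thoracic spine), SENS2 at S2
(sacrum), SENS3 on the lateral thigh — each providing a triaxial accelerometer
(``Acc X/Y/Z``, in g) and gyroscope (``Gyr X/Y/Z``, in deg/s) sampled at
100 Hz for 70 s.  Two derived channel families can be attached: angular
accelerations (``AccA``, deg/s^2) by numerical differentiation of the
gyroscope, and drift-corrected angles (``AngC``, deg) by numerical integration
of the gyroscope followed by subtraction of a least-squares straight line.

Units are carried as metadata and never converted implicitly: downstream
entropy measures use a tolerance proportional to the signal's own SD, so they
are invariant to the unit chosen.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SensorId",
    "Group",
    "SensorFrame",
    "Recording",
    "FormatError",
    "InsufficientDataError",
    "RECORDED_CHANNELS",
    "read_recording",
    "write_recording",
    "read_layout",
    "trim_warmup",
    "derive_angular_acceleration",
    "derive_corrected_angle",
    "attach_derived_channels",
]

#: The six channels every sensor records, in canonical order.
RECORDED_CHANNELS = (
    "Acc X", "Acc Y", "Acc Z", "Gyr X", "Gyr Y", "Gyr Z",
)

DERIVED_CHANNELS = (
    "AccA X", "AccA Y", "AccA Z", "AngC X", "AngC Y", "AngC Z",
)


class SensorId(str, enum.Enum):
    """Identifier of one of the three body-worn sensors."""

    SENS1 = "SENS1"  # T12, lower thoracic spine
    SENS2 = "SENS2"  # S2, sacrum
    SENS3 = "SENS3"  # lateral thigh

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Group(str, enum.Enum):
    """Clinical group label."""

    CLBP = "CLBP"  # chronic low back pain patient
    NLBP = "NLBP"  # healthy, no low back pain

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FormatError(ValueError):
    """A recording file or layout does not match the declared format."""


class InsufficientDataError(ValueError):
    """A series is too short for the requested operation."""


@dataclass
class SensorFrame:
    """All channels of one sensor, sharing one length and sampling rate.

    ``channels`` maps canonical channel names ("Acc X" ... "Gyr Z", plus
    derived "AccA *" / "AngC *") to 1-D float arrays.
    """

    sensor_id: SensorId
    channels: dict[str, np.ndarray]
    fs: float = 100.0
    placement: str = ""
    acc_units: str = "g"
    gyr_units: str = "deg/s"

    def __post_init__(self) -> None:
        self.sensor_id = SensorId(self.sensor_id)
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"{self.sensor_id}: channels have unequal lengths {sorted(lengths)}"
            )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present on {self.sensor_id} "
                f"(has {sorted(self.channels)})"
            )
        return self.channels[name]

    def flexion_gyr(self) -> np.ndarray:
        """The angular-velocity channel aligned with trunk flexion/extension.

        SENS1/SENS2 are mounted so that Gyr Y follows the movement; SENS3 is
        mounted rotated on the thigh, so its -Gyr Z plays that role.
        """
        if self.sensor_id is SensorId.SENS3:
            return -self.channel("Gyr Z")
        return self.channel("Gyr Y")


_DEFAULT_PLACEMENTS = {
    SensorId.SENS1: "T12",
    SensorId.SENS2: "S2",
    SensorId.SENS3: "thigh",
}


@dataclass
class Recording:
    """One participant's 3-sensor recording with its clinical label."""

    subject_id: str
    group: Group
    sensors: dict[SensorId, SensorFrame]
    fs: float = 100.0
    t0: float | None = None  # analysis-window bounds, seconds
    t1: float | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sensors = {SensorId(k): v for k, v in self.sensors.items()}
        missing = set(SensorId) - set(self.sensors)
        if missing:
            raise FormatError(
                f"recording {self.subject_id!r} lacks sensors "
                f"{sorted(s.value for s in missing)}"
            )
        lengths = {f.n_samples for f in self.sensors.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"recording {self.subject_id!r}: sensors have unequal lengths "
                f"{sorted(lengths)}"
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def sensor(self, sensor_id: SensorId | str) -> SensorFrame:
        return self.sensors[SensorId(sensor_id)]

    def channel(self, sensor_id: SensorId | str, name: str) -> np.ndarray:
        return self.sensor(sensor_id).channel(name)

    def iter_channels(self, include_derived: bool = False):
        """Yield (sensor_id, channel_name, series) in canonical order."""
        names = RECORDED_CHANNELS + (DERIVED_CHANNELS if include_derived else ())
        for sid in SensorId:
            frame = self.sensors[sid]
            for name in names:
                if name in frame.channels:
                    yield sid, name, frame.channels[name]


# ---------------------------------------------------------------------------
# File format: wide delimited text, one row per sample.
# Default header convention: "time", then "SENS<k> <Acc|Gyr> <X|Y|Z>".
# A layout mapping (YAML/JSON) can rename columns: {column: "SENS1 Acc X", ...}
# ---------------------------------------------------------------------------


def default_layout() -> dict[str, str]:
    """Identity column map for the canonical header convention."""
    return {
        f"{sid.value} {ch}": f"{sid.value} {ch}"
        for sid in SensorId
        for ch in RECORDED_CHANNELS
    }


def read_layout(path: str | Path) -> dict[str, str]:
    """Load a column-map config (YAML or JSON) from *path*."""
    import yaml

    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise FormatError(f"layout file {path} must contain a mapping")
    return {str(k): str(v) for k, v in layout.items()}


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_recording(
    path: str | Path,
    layout: dict[str, str] | None = None,
    *,
    subject_id: str | None = None,
    group: Group | str = Group.NLBP,
    fs: float = 100.0,
) -> Recording:
    """Read a wide delimited-text recording (one row per sample).

    Parameters
    ----------
    path
        CSV or TSV file.  A ``time`` column, if present, is ignored for data
        but used only to sanity-check ``fs``.
    layout
        Maps file column names to canonical ``"SENS<k> <Acc|Gyr> <X|Y|Z>"``
        targets.  ``None`` assumes the file already uses canonical names.
    subject_id, group, fs
        Metadata not stored in the data file; ``subject_id`` defaults to the
        file stem.

    Raises
    ------
    FormatError
        If a required sensor/channel column is missing, or rows are ragged.
    """
    import pandas as pd

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    rename = layout or {}
    df = df.rename(columns=rename)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # Reject rows with any non-numeric entry in the mapped data columns.
    wanted = [
        f"{sid.value} {ch}" for sid in SensorId for ch in RECORDED_CHANNELS
    ]
    missing = [c for c in wanted if c not in numeric.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing} "
            "(check the layout column map)"
        )
    data = numeric[wanted].dropna(axis=0, how="any")

    sensors = {}
    for sid in SensorId:
        channels = {
            ch: data[f"{sid.value} {ch}"].to_numpy(dtype=float)
            for ch in RECORDED_CHANNELS
        }
        sensors[sid] = SensorFrame(
            sensor_id=sid, channels=channels, fs=fs,
            placement=_DEFAULT_PLACEMENTS[sid],
        )
    return Recording(
        subject_id=subject_id or path.stem,
        group=Group(group),
        sensors=sensors,
        fs=fs,
    )


def write_recording(rec: Recording, path: str | Path, *, sep: str = ",") -> Path:
    """Write *rec* as wide delimited text with canonical column names.

    Full ``repr`` float precision is used so that a write/read round trip is
    bit-exact.
    """
    import pandas as pd

    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "time": np.arange(rec.n_samples) / rec.fs,
    }
    for sid, name, series in rec.iter_channels():
        cols[f"{sid.value} {name}"] = series
    frame = pd.DataFrame(cols)
    # %.17g round-trips every IEEE double exactly.
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def write_manifest(recs: list[Recording], path: str | Path) -> Path:
    """Write a cohort manifest (subject ids + labels) as JSON."""
    path = Path(path)
    payload = [
        {"subject_id": r.subject_id, "group": r.group.value, "fs": r.fs,
         "n_samples": r.n_samples}
        for r in recs
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def trim_warmup(rec: Recording, t0: float = 10.0, t1: float = 70.0) -> Recording:
    """Discard the warm-up and tail, keeping the [t0, t1) analysis window.

    The first 10 s of the test are treated as warm-up and anything after 70 s
    is dropped, leaving a 60 s window (6000 samples at 100 Hz).  A recording
    shorter than ``t1`` (a participant who stopped early) is rejected.
    """
    if t1 <= t0:
        raise ValueError(f"empty analysis window: t0={t0}, t1={t1}")
    if rec.duration < t1:
        raise InsufficientDataError(
            f"recording {rec.subject_id!r} lasts {rec.duration:.2f} s "
            f"< required {t1} s (early stop; excluded from analysis)"
        )
    i0 = int(round(t0 * rec.fs))
    i1 = int(round(t1 * rec.fs))
    sensors = {
        sid: replace(frame, channels={k: v[i0:i1] for k, v in frame.channels.items()})
        for sid, frame in rec.sensors.items()
    }
    return replace(rec, sensors=sensors, t0=t0, t1=t1)


def derive_angular_acceleration(gyr_channel: np.ndarray, fs: float) -> np.ndarray:
    """Angular acceleration (deg/s^2) by numerical differentiation.

    Central differences in the interior with one-sided differences at the
    endpoints, so the output has the same length as the input.
    """
    x = np.asarray(gyr_channel, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 samples to differentiate, got {x.size}"
        )
    return np.gradient(x, 1.0 / fs)


def derive_corrected_angle(gyr_channel: np.ndarray, fs: float) -> np.ndarray:
    """Drift-corrected angle (deg) from angular velocity (deg/s).

    Cumulative trapezoidal integration, then subtraction of the least-squares
    straight line fitted over the whole series ("linear drift subtraction").
    The output therefore has zero linear trend by construction.
    """
    x = np.asarray(gyr_channel, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples to integrate, got {x.size}"
        )
    angle = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    t = np.arange(x.size) / fs
    slope, intercept = np.polyfit(t, angle, 1)
    return angle - (slope * t + intercept)


def attach_derived_channels(rec: Recording) -> Recording:
    """Return a copy of *rec* with AccA and AngC channels on every sensor."""
    sensors = {}
    for sid, frame in rec.sensors.items():
        channels = dict(frame.channels)
        for axis in ("X", "Y", "Z"):
            gyr = frame.channel(f"Gyr {axis}")
            channels[f"AccA {axis}"] = derive_angular_acceleration(gyr, frame.fs)
            channels[f"AngC {axis}"] = derive_corrected_angle(gyr, frame.fs)
        sensors[sid] = replace(frame, channels=channels)
    return replace(rec, sensors=sensors)
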