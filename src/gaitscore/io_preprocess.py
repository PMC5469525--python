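"""Raw IMU ingestion, calibration, orientation tracking and filtering.

Three IMUs (waist over the lower lumbar spine, mid left thigh, mid right
thigh) record 3-axis acceleration and 3-axis angular velocity at 100 Hz.
Because the sensors tilt with the body, the raw acceleration is rotated into
a common body-fixed reference frame with axes

* AP — anterior–posterior, positive forward,
* SI — superior–inferior, positive upward,
* ML — medio-lateral,

using a quaternion tracked from the gyroscope.  The initial quaternion is
estimated from a >= 5 s static standing window at the start of the trial:
the mean static acceleration is gravity, and is rotated onto the global SI
axis; heading about SI is unobservable from an accelerometer and is fixed so
that the sensor's nominal forward axis (declared in the sidecar metadata)
points along global AP at t = 0.

Gravity is deliberately not subtracted: SI channels carry a +g mean and the
downstream waveform features mean-center where required.

All vector arrays use the axis order (AP, SI, ML).  Quaternions are
scalar-first ``(w, x, y, z)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin
from scipy.spatial.transform import Rotation

GRAVITY = 9.81
"""Standard gravity in m/s^2, used for unit conversion and static checks."""

PLACEMENTS = ("waist", "thigh_left", "thigh_right")

#: labelled channel order used by every multi-channel container downstream;
#: L/R are the thighs, W the waist.
NINE_CHANNELS = (
    "SI-L", "ML-L", "AP-L",
    "SI-R", "ML-R", "AP-R",
    "SI-W", "ML-W", "AP-W",
)

_PLACEMENT_SUFFIX = {"thigh_left": "L", "thigh_right": "R", "waist": "W"}
_AXIS_INDEX = {"AP": 0, "SI": 1, "ML": 2}

# per-placement raw CSV column suffixes
_RAW_COLS = ("ax", "ay", "az", "gx", "gy", "gz")


class PreprocessError(ValueError):
    """Raised for malformed recordings or failed calibration checks."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    """One IMU's raw streams: ``acc`` (N, 3) in m/s^2, ``gyro`` (N, 3) in rad/s."""

    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.shape != self.gyro.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise PreprocessError("acc and gyro must both be (N, 3) arrays")

    def __len__(self) -> int:
        return self.acc.shape[0]


@dataclass
class CalibrationOffsets:
    """Additive per-sensor, per-axis offsets: placement -> {'acc': (3,), 'gyro': (3,)}."""

    acc: dict[str, np.ndarray] = field(default_factory=dict)
    gyro: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.acc, self.gyro):
            for k, v in table.items():
                arr = np.asarray(v, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise PreprocessError(f"offset for {k} must be 3 finite values")
                table[k] = arr

    @classmethod
    def zero(cls) -> "CalibrationOffsets":
        z = {p: np.zeros(3) for p in PLACEMENTS}
        return cls(acc={k: v.copy() for k, v in z.items()}, gyro=z)


@dataclass
class IMURecording:
    """Synchronized three-sensor recording with placement metadata.

    ``axis_map`` declares, per placement, which raw sensor axis is nominally
    forward (AP) and which is up (SI), e.g. ``{"forward": "+x", "up": "+y"}``.
    ``static_window`` is the half-open sample range of the pre-walk standing
    phase.
    """

    sample_rate: float
    sensors: dict[str, SensorStream]
    static_window: tuple[int, int]
    axis_map: dict[str, dict[str, str]]
    offsets: CalibrationOffsets | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise PreprocessError("sample_rate must be positive")
        for p in PLACEMENTS:
            if p not in self.sensors:
                raise PreprocessError(f"placement {p} absent")
        lengths = {len(s) for s in self.sensors.values()}
        if len(lengths) != 1:
            raise PreprocessError("sensor streams have unequal lengths")
        s, e = self.static_window
        if e - s < 2 * self.sample_rate:
            raise PreprocessError("static window shorter than 2 s")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.sensors.values())))


@dataclass
class GlobalAcceleration:
    """Body-frame acceleration for all three sensors.

    ``data`` is (9, N) in :data:`NINE_CHANNELS` order; gravity is retained on
    the SI channels.
    """

    data: np.ndarray
    sample_rate: float

    def channel(self, label: str) -> np.ndarray:
        return self.data[NINE_CHANNELS.index(label)]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.data.shape[1]) / self.sample_rate
        df = pd.DataFrame({"t": t})
        for i, lab in enumerate(NINE_CHANNELS):
            df[lab] = self.data[i]
        return df


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_axis(spec: str) -> np.ndarray:
    """``'+x'``/``'-z'`` -> signed unit vector in raw sensor (x, y, z) axes."""
    sign = {"+": 1.0, "-": -1.0}.get(spec[0])
    idx = {"x": 0, "y": 1, "z": 2}.get(spec[-1])
    if sign is None or idx is None or len(spec) != 2:
        raise PreprocessError(f"bad axis spec {spec!r}; expected like '+x'")
    v = np.zeros(3)
    v[idx] = sign
    return v


def load_recording(path: str | Path, metadata_path: str | Path) -> IMURecording:
    """Load a raw CSV recording plus its JSON sidecar into an :class:`IMURecording`.

    The CSV has one timestamp column ``t`` and, per placement, columns
    ``<placement>_{ax,ay,az,gx,gy,gz}``.  The sidecar supplies sample rate,
    units (``"g"`` or ``"m/s2"``), the static window, per-placement axis maps
    and calibration offsets.
    """
    with open(metadata_path) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    fs = float(meta["sample_rate"])

    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        mean_dt = dts.mean()
        if mean_dt <= 0 or np.max(np.abs(dts - mean_dt)) > 0.01 * mean_dt:
            raise PreprocessError("non-uniform timestamps (jitter above 1%)")

    unit = meta.get("unit", "m/s2")
    acc_scale = GRAVITY if unit == "g" else 1.0

    sensors: dict[str, SensorStream] = {}
    for p in PLACEMENTS:
        cols = [f"{p}_{c}" for c in _RAW_COLS]
        if any(c not in df.columns for c in cols):
            raise PreprocessError(f"placement {p} absent")
        block = df[cols].to_numpy(dtype=float)
        sensors[p] = SensorStream(acc=block[:, :3] * acc_scale, gyro=block[:, 3:])

    offsets = None
    if "offsets" in meta:
        offsets = CalibrationOffsets(
            acc={p: np.asarray(meta["offsets"][p]["acc"], float) for p in PLACEMENTS},
            gyro={p: np.asarray(meta["offsets"][p]["gyro"], float) for p in PLACEMENTS},
        )

    axis_map = {p: meta["placements"][p] for p in PLACEMENTS}
    return IMURecording(
        sample_rate=fs,
        sensors=sensors,
        static_window=tuple(meta["static_window"]),
        axis_map=axis_map,
        offsets=offsets,
    )


def write_recording(rec: IMURecording, path: str | Path, metadata_path: str | Path,
                    unit: str = "m/s2") -> None:
    """Write an :class:`IMURecording` back to the CSV + JSON sidecar layout."""
    n = rec.n_samples
    scale = 1.0 / GRAVITY if unit == "g" else 1.0
    data = {"t": np.arange(n) / rec.sample_rate}
    for p in PLACEMENTS:
        s = rec.sensors[p]
        for i, c in enumerate(_RAW_COLS[:3]):
            data[f"{p}_{c}"] = s.acc[:, i] * scale
        for i, c in enumerate(_RAW_COLS[3:]):
            data[f"{p}_{c}"] = s.gyro[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")

    meta = {
        "sample_rate": rec.sample_rate,
        "unit": unit,
        "placements": rec.axis_map,
        "static_window": list(rec.static_window),
    }
    if rec.offsets is not None:
        meta["offsets"] = {
            p: {"acc": rec.offsets.acc[p].tolist(), "gyro": rec.offsets.gyro[p].tolist()}
            for p in PLACEMENTS
        }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# calibration and orientation
# ---------------------------------------------------------------------------

def apply_offsets(rec: IMURecording, off: CalibrationOffsets) -> IMURecording:
    """Subtract additive calibration offsets from every channel."""
    sensors = {}
    for p, s in rec.sensors.items():
        sensors[p] = SensorStream(
            acc=s.acc - off.acc.get(p, np.zeros(3)),
            gyro=s.gyro - off.gyro.get(p, np.zeros(3)),
        )
    return IMURecording(rec.sample_rate, sensors, rec.static_window, rec.axis_map, None)


def _quat_multiply(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _rotation_between(u: np.ndarray, v: np.ndarray) -> Rotation:
    """Minimal rotation carrying unit vector u onto unit vector v."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: rotate pi about any axis orthogonal to u
        ortho = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(ortho) < 1e-6:
            ortho = np.cross(u, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * ortho / np.linalg.norm(ortho))
    angle = np.arctan2(norm, c)
    return Rotation.from_rotvec(axis / norm * angle)


def estimate_initial_orientation(rec: IMURecording, sensor: str) -> np.ndarray:
    """Initial quaternion for one sensor from the static standing window.

    The mean static accelerometer reading (the gravity reaction, pointing up
    in the sensor frame) is rotated onto the global SI axis; the residual
    heading freedom is resolved by mapping the metadata-declared nominal
    forward axis onto global AP.  Returns a scalar-first unit quaternion.
    """
    s0, s1 = rec.static_window
    mean_acc = rec.sensors[sensor].acc[s0:s1].mean(axis=0)
    mag = np.linalg.norm(mean_acc)
    if not (0.8 * GRAVITY <= mag <= 1.2 * GRAVITY):
        raise PreprocessError(
            f"sensor not static or miscalibrated: static |acc| = {mag:.2f} m/s^2")

    e_si = np.array([0.0, 1.0, 0.0])
    e_ap = np.array([1.0, 0.0, 0.0])
    e_ml = np.array([0.0, 0.0, 1.0])
    tilt = _rotation_between(mean_acc / mag, e_si)

    forward = _parse_axis(rec.axis_map[sensor]["forward"])
    f_glob = tilt.apply(forward)
    f_h = f_glob - np.dot(f_glob, e_si) * e_si
    if np.linalg.norm(f_h) > 1e-9:
        f_h /= np.linalg.norm(f_h)
        psi = np.arctan2(np.dot(f_h, e_ml), np.dot(f_h, e_ap))
        heading = Rotation.from_rotvec(-psi * e_si)
    else:  # forward axis parallel to gravity: heading left as identity
        warnings.warn(f"{sensor}: forward axis vertical, heading undefined")
        heading = Rotation.identity()

    q = (heading * tilt).as_quat(scalar_first=True)
    return q / np.linalg.norm(q)


def update_orientation(q0: np.ndarray, gyro: np.ndarray, dt: float) -> np.ndarray:
    """Integrate body-frame angular velocity into a quaternion series.

    First-order exponential-map update per sample: each step rotates by
    ``omega * dt`` and renormalizes.  ``q[0] == q0``; output is (N, 4)
    scalar-first, with N = len(gyro).
    """
    if dt <= 0:
        raise PreprocessError("dt must be positive")
    gyro = np.asarray(gyro, dtype=float)
    n = gyro.shape[0]
    out = np.empty((n, 4))
    q = np.asarray(q0, dtype=float)
    q = q / np.linalg.norm(q)
    out[0] = q
    # precompute per-step increments (rotation over [k-1, k] uses gyro[k-1])
    rotvecs = gyro[:-1] * dt
    angles = np.linalg.norm(rotvecs, axis=1)
    for k in range(1, n):
        a = angles[k - 1]
        if a > 0:
            axis = rotvecs[k - 1] / a
            half = 0.5 * a
            dq = np.array([np.cos(half), *(np.sin(half) * axis)])
            q = _quat_multiply(q, dq)
            q = q / np.linalg.norm(q)
        out[k] = q
    return out


def to_global_frame(acc: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """Rotate per-sample sensor-frame acceleration into the global frame.

    ``acc`` is (N, 3) raw sensor axes, ``quats`` (N, 4) scalar-first; output
    is (N, 3) in (AP, SI, ML) order.  Pure rotation — gravity is retained.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.shape[0] != quats.shape[0]:
        raise PreprocessError("acc and quaternion series lengths differ")
    return Rotation.from_quat(quats, scalar_first=True).apply(acc)


def lowpass_filter(x: np.ndarray, sample_rate: float, order: int = 50,
                   cutoff: float = 20.0) -> np.ndarray:
    """Zero-phase FIR low-pass (Hamming windowed-sinc, default 50th order, 20 Hz).

    Applied forward-backward so peak timing is unbiased for segmentation.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * order:
        raise PreprocessError(f"series too short for order-{order} filter")
    taps = firwin(order + 1, cutoff, fs=sample_rate, window="hamming")
    return filtfilt(taps, [1.0], x, axis=-1)


# ---------------------------------------------------------------------------
# full preprocessing chain
# ---------------------------------------------------------------------------

def preprocess(rec: IMURecording, filter_order: int = 50,
               filter_cutoff: float = 20.0) -> GlobalAcceleration:
    """Offsets -> low-pass -> initial orientation -> gyro update -> global frame.

    Returns the nine labelled body-frame channels at the original sample rate.
    """
    if rec.offsets is not None:
        rec = apply_offsets(rec, rec.offsets)
    dt = 1.0 / rec.sample_rate

    filtered: dict[str, SensorStream] = {}
    for p, s in rec.sensors.items():
        filtered[p] = SensorStream(
            acc=lowpass_filter(s.acc.T, rec.sample_rate, filter_order, filter_cutoff).T,
            gyro=lowpass_filter(s.gyro.T, rec.sample_rate, filter_order, filter_cutoff).T,
        )
    frec = IMURecording(rec.sample_rate, filtered, rec.static_window, rec.axis_map, None)

    data = np.empty((9, rec.n_samples))
    for p in PLACEMENTS:
        q0 = estimate_initial_orientation(frec, p)
        quats = update_orientation(q0, frec.sensors[p].gyro, dt)
        glob = to_global_frame(frec.sensors[p].acc, quats)  # (N, 3) AP,SI,ML
        suffix = _PLACEMENT_SUFFIX[p]
        for axis, col in _AXIS_INDEX.items():
            data[NINE_CHANNELS.index(f"{axis}-{suffix}")] = glob[:, col]
    return GlobalAcceleration(data=data, sample_rate=rec.sample_rate)
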