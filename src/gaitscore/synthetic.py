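"""Synthetic IMU gait recordings with ground-truth events and pathology dials.

No public recordings exist for this kind of three-sensor (waist + both
thighs) walking protocol, so the pipeline is exercised on simulated data.
The generator tiles an analytic one-stride waveform template into a
continuous walk, embeds it in per-sensor frames with known constant
orientations, and prepends a static standing phase, so that every stage of
the pipeline (orientation recovery, filtering, heel-strike detection, cycle
averaging, scoring) can be validated against known ground truth.

The template is a harmonic construction honoring the landmark morphology of
healthy level walking measured at the waist and thighs:

* AP-W peaks at each heel strike (0% and ~50% of the stride), with the two
  step halves nearly identical (left/right symmetry);
* SI-W has its dominant peaks just after each contact (~6% and ~55%, foot
  flat) and slow regions around 25-40% and 75-90%;
* SI-L over 0-15% mirrors SI-R over 50-65% (stance loading of each leg);
* AP-L falls then rises over the cycle; AP-R is its half-stride shift;
* ML channels are low-amplitude and dominated by per-subject idiosyncrasy.

Pathology is injected through three orthogonal dials: ``asymmetry`` scales
left versus right step amplitudes, ``tremor_amp`` adds 6-15 Hz band-limited
ripple (below the 20 Hz preprocessing cutoff, so it survives filtering), and
``cycle_noise`` jitters stride durations and waveforms cycle to cycle.  Each
dial targets one feature family: asymmetry lowers S, tremor raises N,
cycle noise raises V; all of them lower P, H and the final score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_preprocess import (
    GRAVITY,
    NINE_CHANNELS,
    PLACEMENTS,
    CalibrationOffsets,
    IMURecording,
    SensorStream,
)

#: nominal sensor mounting pitch (rad, about ML) per placement — the constant
#: orientations the preprocessing stage must recover from the static window
SENSOR_PITCH = {"waist": np.deg2rad(8.0),
                "thigh_left": np.deg2rad(15.0),
                "thigh_right": np.deg2rad(12.0)}

_AXIS_MAP = {p: {"forward": "+x", "up": "+y"} for p in PLACEMENTS}

#: nominal per-channel amplitude scale in m/s^2, used to size perturbations
_AMPLITUDE = {
    "AP-W": 1.5, "SI-W": 2.0, "ML-W": 0.3,
    "SI-L": 1.5, "AP-L": 1.0, "ML-L": 0.3,
    "SI-R": 1.5, "AP-R": 1.0, "ML-R": 0.3,
}

SEVERITY_LEVELS = {
    "healthy":  dict(stride_frequency=(0.85, 1.00), asymmetry=(0.00, 0.05),
                     tremor_amp=(0.00, 0.02), cycle_noise=(0.01, 0.03)),
    "mild":     dict(stride_frequency=(0.80, 0.95), asymmetry=(0.10, 0.20),
                     tremor_amp=(0.05, 0.10), cycle_noise=(0.04, 0.08)),
    "moderate": dict(stride_frequency=(0.70, 0.90), asymmetry=(0.25, 0.40),
                     tremor_amp=(0.12, 0.20), cycle_noise=(0.08, 0.14)),
    "severe":   dict(stride_frequency=(0.60, 0.75), asymmetry=(0.45, 0.65),
                     tremor_amp=(0.25, 0.40), cycle_noise=(0.16, 0.25)),
}
"""Per-severity parameter ranges.  Stride frequencies follow the observed
span from healthy self-selected walking (~0.85-1.0 strides/s) down to the
slowest severely impaired walkers (~0.6 strides/s); the pathology dials are
engineering choices with ordinal, not clinical, meaning."""


@dataclass
class SyntheticGaitProfile:
    """Parameters of one simulated subject.

    ``asymmetry``: relative left/right step amplitude imbalance in [0, 1];
    ``tremor_amp``: 6-15 Hz ripple amplitude relative to each channel's RMS;
    ``cycle_noise``: relative cycle-to-cycle duration and waveform jitter.
    """

    stride_frequency: float = 0.93
    n_strides: int = 30
    asymmetry: float = 0.0
    tremor_amp: float = 0.0
    cycle_noise: float = 0.0
    seed: int = 0
    sample_rate: float = 100.0
    static_duration_s: float = 5.5

    def __post_init__(self) -> None:
        if self.stride_frequency <= 0:
            raise ValueError("stride_frequency must be positive")
        for name in ("asymmetry", "tremor_amp", "cycle_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticRecording:
    """An :class:`IMURecording` plus its ground truth."""

    recording: IMURecording
    events: np.ndarray          # heel-strike sample indices, strictly increasing
    feet: tuple[str, ...]       # 'L'/'R' label per event
    profile: SyntheticGaitProfile
    subject_id: str = ""
    global_truth: np.ndarray = field(default=None, repr=False)  # (9, N) noise-free frame


# ---------------------------------------------------------------------------
# stride template
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Smooth periodic bump centered at phase mu (von Mises shape, peak 1)."""
    return np.exp(kappa * (np.cos(2 * np.pi * (t - mu)) - 1.0))


def _skew_bump(t: np.ndarray, mu: float, w_rise: float, w_fall: float) -> np.ndarray:
    """Periodic bump at mu with a fast rise and slow decay (Gaussian flanks
    of different widths in circular phase distance); models the transient
    loading peak after a foot contact."""
    d = (np.asarray(t, dtype=float) - mu + 0.5) % 1.0 - 0.5
    width = np.where(d < 0, w_rise, w_fall)
    return np.exp(-0.5 * (d / width) ** 2)


def _template_functions() -> dict:
    """Analytic one-stride waveforms, phase t in [0, 1), left contact at 0.

    Every channel is built so its slope vanishes (or its value is in a flat
    tail) at the cycle wrap, keeping tiled cycles continuous.
    """
    two_pi = 2 * np.pi

    def ap_w(t):
        # contact peaks at 0 and 0.5; small odd content keeps the two step
        # halves similar but not identical
        return 1.5 * (np.cos(2 * two_pi * t) + 0.2 * np.cos(two_pi * t))

    def si_w(t):
        # foot-flat loading transients just after each contact; slightly
        # different left/right amplitude so the stride harmonics are not
        # purely even
        return (2.0 * _skew_bump(t, 0.06, 0.020, 0.070)
                + 1.75 * _skew_bump(t, 0.55, 0.022, 0.075) - 0.6)

    def si_l(t):
        # stance loading of the left leg, echoed softly at the contralateral
        # contact
        return 1.6 * _bump(t, 0.10, 25.0) + 0.6 * _bump(t, 0.60, 25.0) - 0.55

    def si_r(t):
        return si_l((t - 0.5) % 1.0)

    def ap_l(t):
        # left thigh decelerates through stance, swings forward late
        return np.cos(two_pi * t) + 0.25 * np.cos(2 * two_pi * t)

    def ap_r(t):
        return ap_l((t - 0.5) % 1.0)

    def ml_fixed(t):
        return 0.12 * np.cos(two_pi * t) - 0.05 * np.cos(2 * two_pi * t)

    return {"AP-W": ap_w, "SI-W": si_w, "SI-L": si_l, "SI-R": si_r,
            "AP-L": ap_l, "AP-R": ap_r,
            "ML-W": ml_fixed, "ML-L": ml_fixed, "ML-R": ml_fixed}


def healthy_template(m: int = 100) -> np.ndarray:
    """Sample the healthy stride template at m phase points -> (9, m) array
    in :data:`NINE_CHANNELS` order."""
    if m < 20:
        raise ValueError("template needs m >= 20")
    t = np.arange(m) / m
    funcs = _template_functions()
    return np.array([funcs[lab](t) for lab in NINE_CHANNELS])


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def _random_harmonics(rng: np.random.Generator, scale: float, n: int = 3):
    """A random smooth 1-periodic function: sum of low-order harmonics."""
    amps = rng.normal(0.0, scale, n)
    phases = rng.uniform(0.0, 2 * np.pi, n)

    def f(t):
        out = np.zeros_like(np.asarray(t, dtype=float))
        for k in range(n):
            out += amps[k] * np.cos(2 * np.pi * (k + 1) * t + phases[k])
        return out

    return f


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float] = (6.0, 15.0)) -> np.ndarray:
    """Unit-variance noise restricted to a frequency band via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(profile: SyntheticGaitProfile,
                       subject_id: str = "") -> SyntheticRecording:
    """Synthesize one walking trial from a profile; fully seeded.

    The gait component is tiled stride by stride with per-cycle duration and
    waveform jitter, ramped in before the first contact and tapered out after
    the last, preceded by a >= 5 s static standing phase.  Gravity rides on
    the global SI channels and the global signals are rotated into each
    sensor's (constant, pitch-only) frame, so preprocessing can recover the
    global frame exactly from the static window.
    """
    rng = np.random.default_rng(profile.seed)
    fs = profile.sample_rate
    funcs = _template_functions()
    base_d = fs / profile.stride_frequency
    ns = profile.n_strides

    # subject-level idiosyncratic ML patterns (dominate the small fixed part)
    ml_subject = {lab: _random_harmonics(rng, 0.25) for lab in ("ML-W", "ML-L", "ML-R")}

    # per-cycle durations and per-cycle, per-channel waveform perturbations;
    # stride-time variability in impaired gait is much smaller than waveform
    # variability, so the duration jitter uses a reduced share of the dial
    dur_jit = np.clip(rng.standard_normal(ns), -2, 2) * 0.4 * profile.cycle_noise
    durations = np.maximum(int(0.5 * base_d),
                           np.round(base_d * (1.0 + dur_jit)).astype(int))
    amp_jit = 1.0 + profile.cycle_noise * np.clip(rng.standard_normal((ns, 9)), -2, 2)
    perturb = [[_random_harmonics(rng, profile.cycle_noise * _AMPLITUDE[lab])
                for lab in NINE_CHANNELS] for _ in range(ns)]

    asym = profile.asymmetry
    thigh_gain = {"L": 1.0 + asym / 2.0, "R": 1.0 - asym / 2.0, "W": 1.0}

    static_len = int(round(profile.static_duration_s * fs))
    lead = int(round(0.25 * base_d))
    walk_start = static_len + lead

    # ---- gait component, cycle by cycle --------------------------------
    chunks = {lab: [] for lab in NINE_CHANNELS}
    events: list[int] = []
    feet: list[str] = []

    # lead-in: the approach into the first contact, ramped from zero
    t_lead = np.arange(-lead, 0) / durations[0] % 1.0
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, lead + 1) / lead))
    pos = walk_start
    for lab in NINE_CHANNELS:
        side = lab[-1]
        base = funcs[lab](t_lead)
        if side == "W" and lab != "ML-W":
            base = base * (1.0 + asym / 2.0 * np.cos(2 * np.pi * t_lead))
        if lab.startswith("ML"):
            base = base + ml_subject[lab](t_lead)
        chunks[lab].append(base * thigh_gain[side] * ramp)

    for c in range(ns):
        d = int(durations[c])
        t = np.arange(d) / d
        events.append(pos)
        feet.append("L")
        events.append(pos + int(round(0.5 * d)))
        feet.append("R")
        for i, lab in enumerate(NINE_CHANNELS):
            side = lab[-1]
            base = funcs[lab](t)
            if side == "W" and lab != "ML-W":
                # amplitude modulation peaking at left contact: left steps
                # scaled up, right steps down
                base = base * (1.0 + asym / 2.0 * np.cos(2 * np.pi * t))
            if lab.startswith("ML"):
                base = base + ml_subject[lab](t)
            sig = base * amp_jit[c, i] * thigh_gain[side] + perturb[c][i](t)
            chunks[lab].append(sig)
        pos += d

    # termination: keep 0.35 stride past the last right contact, tapering the
    # tail so no spurious rise toward a 61st contact remains
    d_last = int(durations[-1])
    keep = int(round(0.85 * d_last))           # cut within the last cycle
    taper_from = int(round(0.60 * d_last))
    gait = {lab: np.concatenate(ch)[: lead + sum(durations[:-1]) + keep]
            for lab, ch in chunks.items()}
    walk_len = lead + int(sum(durations[:-1])) + keep

    env = np.ones(walk_len)
    tail = walk_len - (lead + int(sum(durations[:-1])) + taper_from)
    if tail > 0:
        env[-tail:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, tail + 1) / tail))

    # tremor: band-limited ripple scaled to each channel's gait RMS
    if profile.tremor_amp > 0:
        for lab in NINE_CHANNELS:
            noise = _bandlimited_noise(rng, walk_len, fs)
            gait[lab] = gait[lab] + profile.tremor_amp * gait[lab].std() * noise
    for lab in NINE_CHANNELS:
        gait[lab] = gait[lab] * env

    # ---- assemble global-frame series -----------------------------------
    n_total = static_len + walk_len + int(round(1.0 * fs))
    global_truth = np.zeros((9, n_total))
    for i, lab in enumerate(NINE_CHANNELS):
        global_truth[i, static_len:static_len + walk_len] = gait[lab]
        if lab.startswith("SI"):
            global_truth[i] += GRAVITY

    # ---- rotate into sensor frames, add calibration offsets -------------
    e_ml = np.array([0.0, 0.0, 1.0])
    acc_off = {p: rng.uniform(-0.3, 0.3, 3) for p in PLACEMENTS}
    gyro_off = {p: rng.uniform(-0.02, 0.02, 3) for p in PLACEMENTS}

    sensors: dict[str, SensorStream] = {}
    suffix = {"waist": "W", "thigh_left": "L", "thigh_right": "R"}
    for p in PLACEMENTS:
        s = suffix[p]
        glob = np.column_stack([global_truth[NINE_CHANNELS.index(f"{ax}-{s}")]
                                for ax in ("AP", "SI", "ML")])
        rot = Rotation.from_rotvec(SENSOR_PITCH[p] * e_ml)  # sensor -> global
        acc_sensor = rot.inv().apply(glob)
        sensors[p] = SensorStream(acc=acc_sensor + acc_off[p],
                                  gyro=np.zeros_like(acc_sensor) + gyro_off[p])

    offsets = CalibrationOffsets(acc=acc_off, gyro=gyro_off)
    margin = int(round(0.25 * fs))
    rec = IMURecording(
        sample_rate=fs, sensors=sensors,
        static_window=(margin, static_len - margin),
        axis_map={p: dict(_AXIS_MAP[p]) for p in PLACEMENTS},
        offsets=offsets,
    )
    return SyntheticRecording(recording=rec, events=np.array(events, dtype=int),
                              feet=tuple(feet), profile=profile,
                              subject_id=subject_id, global_truth=global_truth)


def generate_cohort(n_subjects: int, severity: str, seed: int = 0,
                    n_strides: int = 30) -> list[SyntheticRecording]:
    """Simulate a cohort with profiles drawn from the severity's parameter ranges."""
    if severity not in SEVERITY_LEVELS:
        raise ValueError(f"unknown severity {severity!r}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ranges = SEVERITY_LEVELS[severity]
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_subjects):
        profile = SyntheticGaitProfile(
            stride_frequency=rng.uniform(*ranges["stride_frequency"]),
            asymmetry=rng.uniform(*ranges["asymmetry"]),
            tremor_amp=rng.uniform(*ranges["tremor_amp"]),
            cycle_noise=rng.uniform(*ranges["cycle_noise"]),
            n_strides=n_strides,
            seed=int(rng.integers(2 ** 31)),
        )
        out.append(generate_recording(profile, subject_id=f"{severity}_{k:02d}"))
    return out


def write_events(rec: SyntheticRecording, path: str | Path) -> None:
    """Reference foot-contact events as CSV ``sample_index,foot``."""
    pd.DataFrame({"sample_index": rec.events, "foot": list(rec.feet)}).to_csv(
        path, index=False)


def read_events(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["sample_index"].to_numpy(dtype=int)
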