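"""The five waveform features of a gait graph: P, V, N, H, S.

* **P — overall Pearson similarity.**  Per-channel Pearson correlation between
  a subject's AGG and the reference CGG, summed over the K = 6 representative
  channels; maximum K (identical shape), lower for abnormal gait.
* **V — overall variance ratio** (Hershler–Milner).  Within-phase variance of
  the three source cycles over their total variance, summed over channels;
  0 for perfectly repeatable strides, ~K for unrelated waveforms.
* **N — extreme-point count.**  Sign changes of the first difference, summed
  over channels; tremor and involuntary shaking add ripple and raise N.
* **H — overall harmonic ratio.**  A stride contains two steps, so a smooth
  symmetric gait concentrates spectral energy in the even stride harmonics;
  h = (sum of even harmonic magnitudes 2..20) / (sum of odd 1..19), computed
  on the waist channels only and summed over SI-W and AP-W.
* **S — overall step symmetry.**  Peak of the normalized unbiased
  autocorrelation of a waist channel in the step-lag band (0.3–0.7 of the
  stride); 1 per channel for perfectly regular alternating steps; summed over
  SI-W and AP-W, so S is at most ~2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gait_graph import AverageGaitGraph, CharacteristicGaitGraph, NormalizedCycle

FEATURE_ORDER = ("P", "V", "N", "H", "S")

WAIST_CHANNELS = ("SI-W", "AP-W")

H_CAP = 1e6
"""Sentinel for a vanishing odd-harmonic sum: the ratio is unbounded and a
finite cap keeps the downstream grey normalization usable."""


class FeatureError(ValueError):
    pass


@dataclass
class FeatureVector:
    P: float
    V: float
    N: int
    H: float
    S: float

    def to_array(self) -> np.ndarray:
        return np.array([self.P, self.V, float(self.N), self.H, self.S])


# ---------------------------------------------------------------------------
# P: Pearson similarity to the reference pattern
# ---------------------------------------------------------------------------

def pearson_channel(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length channels.

    A constant channel has undefined correlation; it is reported as 0 with a
    warning so the overall P stays finite for pathological flat signals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FeatureError("channel length mismatch")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = np.sqrt(xm @ xm)
    sy = np.sqrt(ym @ ym)
    if sx == 0 or sy == 0:
        warnings.warn("constant channel in Pearson; r set to 0")
        return 0.0
    return float((xm @ ym) / (sx * sy))


def pearson_total(agg: AverageGaitGraph, cgg: CharacteristicGaitGraph) -> float:
    """P: sum of per-channel correlations between AGG and CGG (max = K channels)."""
    if agg.channels != cgg.channels:
        raise FeatureError("AGG and CGG channel sets differ")
    return float(sum(pearson_channel(agg.data[c], cgg.data[c])
                     for c in range(len(agg.channels))))


# ---------------------------------------------------------------------------
# V: variance ratio across the source cycles
# ---------------------------------------------------------------------------

def variance_ratio_channel(cycles: np.ndarray) -> float:
    """Hershler–Milner variance ratio of one channel over n repeated cycles.

    ``cycles`` is (n, M): rows are time-normalized cycles.  The ratio compares
    the per-phase scatter around the phase means with the total scatter around
    the grand mean; identical cycles give 0, unrelated ones about 1.
    """
    x = np.asarray(cycles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise FeatureError("need an (n >= 2, M) cycle matrix")
    n, m = x.shape
    phase_mean = x.mean(axis=0)
    num = float(((x - phase_mean) ** 2).sum()) / (m * (n - 1))
    den = float(((x - x.mean()) ** 2).sum()) / (m * n - 1)
    if den == 0:
        return 0.0
    return num / den


def variance_ratio_total(source_cycles: list[NormalizedCycle]) -> float:
    """V: per-channel variance ratios of the AGG's source cycles, summed."""
    if not source_cycles:
        raise FeatureError("no source cycles")
    stack = np.array([c.data for c in source_cycles])  # (n, K, M)
    return float(sum(variance_ratio_channel(stack[:, c, :])
                     for c in range(stack.shape[1])))


# ---------------------------------------------------------------------------
# N: extreme points
# ---------------------------------------------------------------------------

def count_extreme_points_channel(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise FeatureError("channel too short")
    # compress runs of equal samples so a plateau counts as one extremum at most
    keep = np.concatenate(([True], np.diff(x) != 0))
    d = np.diff(x[keep])
    if len(d) < 2:
        return 0
    s = np.sign(d)
    return int(np.sum(s[1:] * s[:-1] < 0))


def count_extreme_points(agg: AverageGaitGraph) -> int:
    """N: interior extrema (first-difference sign changes), summed over channels."""
    return int(sum(count_extreme_points_channel(row) for row in agg.data))


# ---------------------------------------------------------------------------
# H: harmonic ratio of the waist channels
# ---------------------------------------------------------------------------

def harmonic_spectrum(channel: np.ndarray, n_harmonics: int = 20) -> np.ndarray:
    """Magnitudes C_n of stride harmonics n = 1..n_harmonics (DFT, one-sided)."""
    x = np.asarray(channel, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    nh = min(n_harmonics, len(spec) - 1)
    return spec[1:nh + 1]


def harmonic_ratio(channel: np.ndarray, n_harmonics: int = 20,
                   cap: float = H_CAP) -> float:
    """h = (sum of even stride harmonics) / (sum of odd stride harmonics).

    The channel must span exactly one stride so that harmonic 2 is the step
    frequency.  If the odd sum vanishes the ratio is capped at ``cap``.
    """
    c = harmonic_spectrum(channel, n_harmonics)
    n = np.arange(1, len(c) + 1)
    even = float(c[n % 2 == 0].sum())
    odd = float(c[n % 2 == 1].sum())
    if odd < 1e-12:
        warnings.warn("odd-harmonic sum vanishes; harmonic ratio capped")
        return cap
    return even / odd


def harmonic_total(agg: AverageGaitGraph, n_harmonics: int = 20) -> float:
    """H: harmonic ratios of SI-W and AP-W, summed (waist only)."""
    total = 0.0
    for lab in WAIST_CHANNELS:
        if lab not in agg.channels:
            raise FeatureError(f"waist channel {lab} missing")
        total += harmonic_ratio(agg.data[agg.channels.index(lab)], n_harmonics)
    return total


# ---------------------------------------------------------------------------
# S: step regularity from the unbiased autocorrelation
# ---------------------------------------------------------------------------

def unbiased_autocorrelation(x: np.ndarray) -> np.ndarray:
    """a(l) = sum_i x_i x_{i+l} / (M - l), for l = 0..M-1, normalized by a(0)."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    raw = np.correlate(x, x, mode="full")[m - 1:]
    a = raw / (m - np.arange(m))
    if a[0] == 0:
        warnings.warn("zero-energy channel in autocorrelation")
        return np.zeros(m)
    return a / a[0]


def symmetry_channel(channel: np.ndarray, band: tuple[float, float] = (0.3, 0.7)) -> float:
    """As: peak of the normalized unbiased autocorrelation in the step-lag band.

    The channel must be one mean-centered stride; the band brackets the
    nominal step lag at half the stride.
    """
    x = np.asarray(channel, dtype=float)
    x = x - x.mean()
    m = len(x)
    a = unbiased_autocorrelation(x)
    lo = int(np.ceil(band[0] * m))
    hi = int(np.floor(band[1] * m))
    if hi <= lo:
        raise FeatureError("empty autocorrelation search band")
    return float(a[lo:hi + 1].max())


def symmetry_total(agg: AverageGaitGraph, band: tuple[float, float] = (0.3, 0.7)) -> float:
    """S: step-regularity peaks of SI-W and AP-W, summed."""
    total = 0.0
    for lab in WAIST_CHANNELS:
        if lab not in agg.channels:
            raise FeatureError(f"waist channel {lab} missing")
        total += symmetry_channel(agg.data[agg.channels.index(lab)], band)
    return total


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def feature_vector(agg: AverageGaitGraph, source_cycles: list[NormalizedCycle],
                   cgg: CharacteristicGaitGraph, n_harmonics: int = 20,
                   symmetry_band: tuple[float, float] = (0.3, 0.7)) -> FeatureVector:
    """Assemble (P, V, N, H, S) for one AGG against the reference CGG."""
    return FeatureVector(
        P=pearson_total(agg, cgg),
        V=variance_ratio_total(source_cycles),
        N=count_extreme_points(agg),
        H=harmonic_total(agg, n_harmonics),
        S=symmetry_total(agg, symmetry_band),
    )
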