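"""Heel-strike detection and stride segmentation from waist AP acceleration.

During level walking the anterior–posterior waist acceleration (AP-W) shows
a positive peak at every heel strike — a consequence of the inverted-pendulum
trajectory of the body's center of mass.  Detecting these peaks segments the
continuous signal into steps; a stride (gait cycle) spans two consecutive
contacts of the same foot, i.e. peak i to peak i+2.

The detector is a window peak search: the expected step period is first
estimated from the autocorrelation of AP-W, then local maxima that dominate a
sliding window of 0.75 step periods and exceed an amplitude threshold
(mean + 0.2 sd) are kept, with a refractory spacing of 0.3 step periods.
Strides are cut as non-overlapping peak pairs (0->2, 2->4, ...), the first and
last strides of the walk are trimmed (gait initiation/termination), and
cycles whose duration falls outside [0.5x, 2x] of the mean of the remaining
cycles are pruned iteratively.

Detected events can be scored against reference foot-contact events (e.g.
from foot-switch sensors) by greedy one-to-one matching within a tolerance,
yielding sensitivity and positive predictive value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from .io_preprocess import GlobalAcceleration, NINE_CHANNELS

SIX_CHANNELS = ("SI-L", "AP-L", "SI-R", "AP-R", "SI-W", "AP-W")
"""Representative channels carried through gait-graph analysis."""


class SegmentationError(ValueError):
    """Raised when a signal cannot be segmented into gait cycles."""


@dataclass
class HeelStrikeEvents:
    """Detected foot-contact peaks in AP-W: sample ``indices`` plus the
    ``step_period`` estimate (samples) that parameterized the detector."""

    indices: np.ndarray
    step_period: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise SegmentationError("event indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class GaitCycle:
    """One stride: half-open sample span plus per-channel signal slices."""

    start: int
    end: int
    channels: dict[str, np.ndarray] = field(repr=False)

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationScore:
    sensitivity: float
    ppv: float
    matched: int
    missed: int
    spurious: int


def estimate_step_period(ap_w: np.ndarray, sample_rate: float,
                         min_period_s: float = 0.4, max_period_s: float = 2.0,
                         min_peak: float = 0.2) -> float:
    """Dominant step period (samples) from the biased autocorrelation of AP-W.

    The first autocorrelation peak above ``min_peak`` (normalized) in the lag
    band [0.4 s, 2.0 s] is taken as the step period.
    """
    x = np.asarray(ap_w, dtype=float)
    n = len(x)
    lo = int(round(min_period_s * sample_rate))
    hi = int(round(max_period_s * sample_rate))
    if n < hi + lo:
        raise SegmentationError("series too short to estimate a step period")
    xc = x - x.mean()
    a0 = float(np.dot(xc, xc)) / n
    if a0 <= 0:
        raise SegmentationError("no periodic gait detected")
    ac = np.correlate(xc, xc, mode="full")[n - 1:] / n / a0  # biased, normalized

    seg = ac[lo:hi + 1]
    # first local maximum above threshold
    for k in range(1, len(seg) - 1):
        if seg[k] >= min_peak and seg[k] >= seg[k - 1] and seg[k] > seg[k + 1]:
            return float(lo + k)
    raise SegmentationError("no periodic gait detected")


def detect_heel_strikes(ap_w: np.ndarray, step_period: float,
                        threshold_sd: float = 0.2,
                        refractory_frac: float = 0.3) -> HeelStrikeEvents:
    """Window peak detection of heel-strike maxima in AP-W.

    A sample is a candidate if it is the maximum of a sliding window of
    0.75 step periods and exceeds ``mean + threshold_sd * sd`` of the signal;
    of two candidates closer than ``refractory_frac`` step periods the lower
    is suppressed.
    """
    if step_period <= 0:
        raise SegmentationError("step_period must be positive")
    x = np.asarray(ap_w, dtype=float)
    win = max(3, int(round(0.75 * step_period)) | 1)  # odd window
    is_winmax = x >= maximum_filter1d(x, size=win, mode="nearest")
    thr = x.mean() + threshold_sd * x.std()
    candidates = np.flatnonzero(is_winmax & (x > thr))
    if candidates.size == 0:
        raise SegmentationError("too few steps")

    # refractory suppression: greedily keep the highest peaks
    min_dist = refractory_frac * step_period
    order = candidates[np.argsort(x[candidates])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_dist for k in kept):
            kept.append(int(idx))
    kept.sort()
    if len(kept) < 4:
        raise SegmentationError("too few steps")
    return HeelStrikeEvents(indices=np.array(kept), step_period=step_period)


def cut_strides(events: HeelStrikeEvents, channels: GlobalAcceleration) -> list[GaitCycle]:
    """Form non-overlapping strides from event i to event i+2.

    Parity is anchored at the first detected event, so strides run 0->2,
    2->4, ...; each cycle carries slices of all nine labelled channels
    (downstream stages select the six representative ones).
    """
    idx = events.indices
    if len(idx) < 4:
        raise SegmentationError("too few steps")
    cycles = []
    for i in range(0, len(idx) - 2, 2):
        s, e = int(idx[i]), int(idx[i + 2])
        sl = {lab: channels.channel(lab)[s:e].copy() for lab in NINE_CHANNELS}
        cycles.append(GaitCycle(start=s, end=e, channels=sl))
    return cycles


def prune_cycles(cycles: list[GaitCycle], end_trim: int = 2,
                 max_ratio: float = 2.0, min_ratio: float = 0.5) -> list[GaitCycle]:
    """Drop initiation/termination strides, then outlier-length strides.

    The first and last ``end_trim`` cycles are removed (gait start/stop
    transients), then any cycle whose duration exceeds ``max_ratio`` times or
    falls below ``min_ratio`` times the mean duration of the *other* remaining
    cycles is removed, iterating until stable.
    """
    if len(cycles) < 3:
        raise SegmentationError("insufficient clean cycles")
    kept = list(cycles[end_trim:len(cycles) - end_trim]) if end_trim else list(cycles)
    if len(kept) < 3:
        raise SegmentationError("insufficient clean cycles")

    changed = True
    while changed and len(kept) > 1:
        changed = False
        durations = np.array([c.duration for c in kept], dtype=float)
        total = durations.sum()
        for i in range(len(kept)):
            mean_others = (total - durations[i]) / (len(kept) - 1)
            if durations[i] > max_ratio * mean_others or durations[i] < min_ratio * mean_others:
                del kept[i]
                changed = True
                break
    if len(kept) < 3:
        raise SegmentationError("insufficient clean cycles")
    return kept


def evaluate_segmentation(detected: HeelStrikeEvents | np.ndarray,
                          reference: np.ndarray,
                          tolerance: int = 10) -> SegmentationScore:
    """Score detected events against reference foot contacts.

    Greedy one-to-one matching: each reference event claims the nearest
    unmatched detection within ``tolerance`` samples.  Sensitivity is
    matched / n_reference, PPV matched / n_detected.
    """
    det = detected.indices if isinstance(detected, HeelStrikeEvents) else np.asarray(detected)
    ref = np.asarray(reference)
    if np.any(np.diff(ref) < 0):
        raise SegmentationError("reference events must be sorted")

    used = np.zeros(len(det), dtype=bool)
    matched = 0
    for r in ref:
        if len(det) == 0:
            break
        dists = np.where(used, np.inf, np.abs(det - r))
        j = int(np.argmin(dists))
        if dists[j] <= tolerance:
            used[j] = True
            matched += 1
    n_det, n_ref = len(det), len(ref)
    return SegmentationScore(
        sensitivity=matched / n_ref if n_ref else 0.0,
        ppv=matched / n_det if n_det else 0.0,
        matched=matched,
        missed=n_ref - matched,
        spurious=n_det - matched,
    )


def infer_first_foot(channels: GlobalAcceleration, events: HeelStrikeEvents) -> str:
    """Heuristic L/R label of the first contact: the thigh whose SI channel is
    more active over the first half-stride is the newly loaded stance side."""
    s = int(events.indices[0])
    e = int(events.indices[1]) if len(events) > 1 else s + int(events.step_period)
    var_l = channels.channel("SI-L")[s:e].var()
    var_r = channels.channel("SI-R")[s:e].var()
    if var_l == var_r:
        warnings.warn("first-foot inference ambiguous; defaulting to L")
    return "L" if var_l >= var_r else "R"
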