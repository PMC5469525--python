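"""Time-normalized gait cycles, Average Gait Graphs and the reference CGG.

Every pruned stride is resampled to a fixed length M (default 100 samples,
i.e. percent of gait cycle) by linear interpolation, so waveforms are
comparable across subjects walking at different cadences.  An Average Gait
Graph (AGG) is the mean of three consecutive normalized cycles over the six
representative channels — a subject's per-trial gait signature.  The
Characteristic Gait Graph (CGG) is the mean of healthy-adult AGGs and serves
as the standard gait pattern that pathological gaits are compared against.

Channel selection: of the nine sensor channels, only those whose waveform is
reproducible across healthy adults (mean pairwise inter-subject Pearson
correlation >= 0.75) are representative of common gait; in practice the six
SI/AP channels qualify and the three ML channels do not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import NINE_CHANNELS
from .segmentation import SIX_CHANNELS, GaitCycle


class GaitGraphError(ValueError):
    pass


@dataclass
class NormalizedCycle:
    """One stride resampled to M points per channel; channels optionally
    mean-centered so the gravity offset on SI does not dominate averages."""

    data: np.ndarray  # (n_channels, M)
    channels: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.data.shape[1]


@dataclass
class AverageGaitGraph:
    """Mean waveform of three normalized cycles, (6, M)."""

    data: np.ndarray
    channels: tuple[str, ...]
    source_cycles: tuple[int, ...]
    subject_id: str = ""


@dataclass
class CharacteristicGaitGraph:
    """Reference waveform: elementwise mean of healthy-adult AGGs."""

    data: np.ndarray
    channels: tuple[str, ...]
    source_ids: tuple[str, ...] = ()


@dataclass
class ChannelStabilityReport:
    channels: tuple[str, ...]
    mean_r: np.ndarray
    sd_r: np.ndarray
    selected: tuple[str, ...]
    threshold: float = 0.75


def resample_to_m(x: np.ndarray, m: int) -> np.ndarray:
    """Linear interpolation of one channel onto m equispaced phase points.

    Both grids span [0, 1] inclusive, so a channel already of length m is
    returned unchanged and affine signals are resampled exactly.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise GaitGraphError("cycle too short to resample")
    if n == m:
        return x.copy()
    return np.interp(np.linspace(0.0, 1.0, m), np.linspace(0.0, 1.0, n), x)


def normalize_cycle(cycle: GaitCycle, m: int = 100,
                    channels: tuple[str, ...] = SIX_CHANNELS,
                    center: bool = True) -> NormalizedCycle:
    """Resample a stride's channels to fixed length M; mean-center each channel.

    Centering makes graph comparisons invariant to the +g offset carried by
    the SI channels (Pearson and the variance ratio are location-adjusted
    anyway; the harmonic and autocorrelation features require centered input).
    """
    if cycle.duration < 4:
        raise GaitGraphError("degenerate cycle duration")
    rows = []
    for lab in channels:
        row = resample_to_m(cycle.channels[lab], m)
        if center:
            row = row - row.mean()
        rows.append(row)
    return NormalizedCycle(data=np.array(rows), channels=tuple(channels))


def build_aggs(cycles: list[NormalizedCycle], n_graphs: int = 4,
               cycles_per_graph: int = 3, subject_id: str = "") -> list[AverageGaitGraph]:
    """Average consecutive non-overlapping triples of cycles into AGGs.

    If fewer than ``n_graphs * cycles_per_graph`` cycles are available the
    number of graphs is reduced (minimum 1) with a warning.
    """
    if len(cycles) < cycles_per_graph:
        raise GaitGraphError("need at least one full triple of cycles")
    available = len(cycles) // cycles_per_graph
    if available < n_graphs:
        warnings.warn(
            f"only {len(cycles)} cycles: building {available} graphs instead of {n_graphs}")
        n_graphs = available
    chans = cycles[0].channels
    aggs = []
    for g in range(n_graphs):
        idx = tuple(range(g * cycles_per_graph, (g + 1) * cycles_per_graph))
        stack = np.array([cycles[i].data for i in idx])
        aggs.append(AverageGaitGraph(
            data=stack.mean(axis=0), channels=chans,
            source_cycles=idx, subject_id=subject_id))
    return aggs


def channel_stability(mean_gaits: list[np.ndarray] | np.ndarray,
                      channels: tuple[str, ...] = NINE_CHANNELS,
                      threshold: float = 0.75) -> ChannelStabilityReport:
    """Inter-subject reproducibility of each channel's average gait waveform.

    ``mean_gaits`` holds one (n_channels, M) average gait per subject.  For
    every channel the Pearson correlation is computed over all unordered
    subject pairs; channels whose mean correlation reaches ``threshold`` are
    selected as representative.
    """
    gaits = [np.asarray(g, dtype=float) for g in mean_gaits]
    if len(gaits) < 2:
        raise GaitGraphError("channel stability needs at least 2 subjects")
    n_ch = gaits[0].shape[0]
    if n_ch != len(channels):
        raise GaitGraphError("channel count does not match channel labels")

    mean_r = np.empty(n_ch)
    sd_r = np.empty(n_ch)
    for c in range(n_ch):
        rs = []
        for i, j in combinations(range(len(gaits)), 2):
            x, y = gaits[i][c], gaits[j][c]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant channel {channels[c]}; pair r set to 0")
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(x, y)[0, 1]))
        mean_r[c] = np.mean(rs)
        sd_r[c] = np.std(rs, ddof=1) if len(rs) > 1 else 0.0

    selected = select_channels(mean_r, channels, threshold)
    return ChannelStabilityReport(channels=tuple(channels), mean_r=mean_r,
                                  sd_r=sd_r, selected=selected, threshold=threshold)


def select_channels(mean_r: np.ndarray, channels: tuple[str, ...] = NINE_CHANNELS,
                    threshold: float = 0.75) -> tuple[str, ...]:
    """Channels whose mean inter-subject correlation reaches the threshold."""
    return tuple(lab for lab, r in zip(channels, mean_r) if r >= threshold)


def build_cgg(aggs: list[AverageGaitGraph]) -> CharacteristicGaitGraph:
    """Elementwise mean of AGGs -> the Characteristic Gait Graph."""
    if not aggs:
        raise GaitGraphError("need at least one graph")
    chans = aggs[0].channels
    for a in aggs:
        if a.channels != chans or a.data.shape != aggs[0].data.shape:
            raise GaitGraphError("channel-set mismatch between graphs")
    data = np.mean([a.data for a in aggs], axis=0)
    return CharacteristicGaitGraph(data=data, channels=chans,
                                   source_ids=tuple(a.subject_id for a in aggs))


# ---------------------------------------------------------------------------
# CSV round-trip for graphs
# ---------------------------------------------------------------------------

def write_graph(graph: AverageGaitGraph | CharacteristicGaitGraph,
                path: str | Path, metadata_path: str | Path | None = None) -> None:
    df = pd.DataFrame(graph.data, index=list(graph.channels))
    df.to_csv(path, header=False, float_format="%.12g")
    if metadata_path is not None:
        meta: dict = {"channels": list(graph.channels)}
        if isinstance(graph, AverageGaitGraph):
            meta.update(subject_id=graph.subject_id,
                        source_cycles=list(graph.source_cycles))
        else:
            meta.update(source_ids=list(graph.source_ids))
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_cgg(path: str | Path) -> CharacteristicGaitGraph:
    df = pd.read_csv(path, header=None, index_col=0)
    return CharacteristicGaitGraph(data=df.to_numpy(dtype=float),
                                   channels=tuple(df.index))
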