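"""End-to-end composition: recording -> features -> model -> score.

The stages follow the assessment flow: preprocess the raw IMU streams into
the common body frame, segment strides from the waist AP channel, prune
unusable cycles, time-normalize and average cycles into AGGs, compute the
five features of each AGG against the reference CGG, then fit or apply the
grey-relational model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import features as feat
from . import gait_graph as gg
from . import grey_model as grey
from . import io_preprocess as iop
from . import segmentation as seg
from .config import PipelineConfig
from .synthetic import SyntheticRecording

logger = logging.getLogger("gaitscore")


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and subject id."""


def _as_imu(rec) -> iop.IMURecording:
    return rec.recording if isinstance(rec, SyntheticRecording) else rec


def _subject_of(rec, default: str = "") -> str:
    if isinstance(rec, SyntheticRecording) and rec.subject_id:
        return rec.subject_id
    return default


def _stage(name: str, subject: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name} failed for subject {subject!r}: {exc}") from exc


def segment_recording(rec, config: PipelineConfig | None = None,
                      subject_id: str = ""):
    """Preprocess and segment one recording.

    Returns ``(global_acc, events, pruned_cycles)``.
    """
    cfg = config or PipelineConfig()
    sid = _subject_of(rec, subject_id)
    imu = _as_imu(rec)
    ga = _stage("preprocess", sid, iop.preprocess, imu,
                cfg.filter_order, cfg.filter_cutoff)
    ap_w = ga.channel("AP-W")
    period = _stage("step-period", sid, seg.estimate_step_period, ap_w, ga.sample_rate)
    events = _stage("heel-strike-detection", sid, seg.detect_heel_strikes, ap_w, period,
                    cfg.peak_threshold_sd, cfg.refractory_frac)
    cycles = _stage("stride-cutting", sid, seg.cut_strides, events, ga)
    pruned = _stage("cycle-pruning", sid, seg.prune_cycles, cycles, cfg.end_trim)
    logger.info("%s: %d events, %d strides, %d after pruning",
                sid or "recording", len(events), len(cycles), len(pruned))
    return ga, events, pruned


def extract_gait_graphs(rec, config: PipelineConfig | None = None,
                        subject_id: str = ""):
    """Recording -> (AGGs, normalized cycles) on the six representative channels."""
    cfg = config or PipelineConfig()
    sid = _subject_of(rec, subject_id)
    _, _, pruned = segment_recording(rec, cfg, sid)
    cycles = [gg.normalize_cycle(c, cfg.m, seg.SIX_CHANNELS, cfg.center_channels)
              for c in pruned]
    aggs = _stage("agg", sid, gg.build_aggs, cycles, cfg.n_aggs,
                  cfg.cycles_per_agg, sid)
    return aggs, cycles


def subject_mean_gait(rec, config: PipelineConfig | None = None,
                      subject_id: str = "") -> np.ndarray:
    """A subject's average gait over all nine channels: the mean of the first
    three normalized cycles, used for channel-stability analysis."""
    cfg = config or PipelineConfig()
    sid = _subject_of(rec, subject_id)
    _, _, pruned = segment_recording(rec, cfg, sid)
    cycles = [gg.normalize_cycle(c, cfg.m, iop.NINE_CHANNELS, cfg.center_channels)
              for c in pruned[:cfg.cycles_per_agg]]
    return np.mean([c.data for c in cycles], axis=0)


def build_reference_cgg(recordings, config: PipelineConfig | None = None
                        ) -> gg.CharacteristicGaitGraph:
    """CGG: mean of the AGGs of the given (healthy-adult) recordings."""
    cfg = config or PipelineConfig()
    all_aggs = []
    for i, rec in enumerate(recordings):
        aggs, _ = extract_gait_graphs(rec, cfg, subject_id=_subject_of(rec, f"ref{i}"))
        all_aggs.extend(aggs)
    return gg.build_cgg(all_aggs)


def run_extract(rec, cgg: gg.CharacteristicGaitGraph,
                config: PipelineConfig | None = None,
                subject_id: str = "") -> pd.DataFrame:
    """Feature table of one recording: one row per AGG with columns
    ``subject_id, agg_index, P, V, N, H, S``."""
    cfg = config or PipelineConfig()
    sid = _subject_of(rec, subject_id)
    aggs, cycles = extract_gait_graphs(rec, cfg, sid)
    rows = []
    for k, agg in enumerate(aggs):
        src = [cycles[i] for i in agg.source_cycles]
        fv = _stage("features", sid, feat.feature_vector, agg, src, cgg,
                    cfg.n_harmonics, cfg.symmetry_band)
        rows.append({"subject_id": sid, "agg_index": k,
                     "P": fv.P, "V": fv.V, "N": fv.N, "H": fv.H, "S": fv.S})
    return pd.DataFrame(rows)


def run_fit(feature_table: pd.DataFrame,
            config: PipelineConfig | None = None) -> grey.GreyReferenceModel:
    """Fit the grey reference model from a healthy feature table."""
    cfg = config or PipelineConfig()
    x = feature_table[list(feat.FEATURE_ORDER)].to_numpy(dtype=float)
    ids = tuple(dict.fromkeys(feature_table["subject_id"].astype(str)))
    return grey.fit_model(x, gamma=cfg.gamma, weights=np.array(cfg.weights),
                          subject_ids=ids)


def run_assess(feature_table: pd.DataFrame,
               model: grey.GreyReferenceModel) -> list[grey.AssessmentResult]:
    """Score every subject in a feature table against a fitted model."""
    if list(feature_table.columns[-5:]) != list(feat.FEATURE_ORDER):
        missing = [c for c in feat.FEATURE_ORDER if c not in feature_table.columns]
        if missing:
            raise grey.GreyModelError(f"feature table missing columns {missing}")
    results = []
    for sid, group in feature_table.groupby("subject_id", sort=False):
        g = group[list(feat.FEATURE_ORDER)].to_numpy(dtype=float)
        results.append(grey.assess_subject(g, model, subject_id=str(sid)))
    return results


def score_cohorts(cohorts: dict[str, list], config: PipelineConfig | None = None,
                  n_reference: int = 4) -> dict[str, np.ndarray]:
    """Full study on simulated cohorts keyed by name; 'healthy' must be present.

    The first ``n_reference`` healthy subjects provide both the CGG and the
    grey-model training features; every subject (including the reference
    subjects) is then scored.  Returns per-cohort score arrays.
    """
    cfg = config or PipelineConfig()
    healthy = cohorts["healthy"]
    if len(healthy) < n_reference:
        raise PipelineError("not enough healthy subjects for the reference set")
    reference = healthy[:n_reference]
    cgg = build_reference_cgg(reference, cfg)
    train = pd.concat([run_extract(r, cgg, cfg) for r in reference], ignore_index=True)
    model = run_fit(train, cfg)

    scores: dict[str, np.ndarray] = {}
    for name, recs in cohorts.items():
        tables = pd.concat([run_extract(r, cgg, cfg) for r in recs], ignore_index=True)
        scores[name] = np.array([res.score for res in run_assess(tables, model)])
    return scores
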