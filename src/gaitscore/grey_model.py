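"""Grey-relational gait assessment: fit on healthy subjects, score 0-100.

Grey relational analysis (GRA) measures the similarity of a comparison
vector to a reference vector through pointwise deviations scaled by the
global minimum and maximum deviation seen in training.  Here the vectors are
the five gait features (P, V, N, H, S) of an Average Gait Graph.

Fitting (healthy subjects, 4 AGG rows each):

1. ``Xref`` — column means of the raw healthy feature matrix X.
2. Normalization to positive indicators: z = x / Xref if x <= Xref, else
   2 - x / Xref, so 1 is ideal and deviation in either direction lowers z
   (values below 0 are possible for x > 2 Xref and are kept).
3. ``R`` — column means of the normalized matrix Z.
4. ``minAbs`` / ``maxAbs`` — global min and max of |Z - R| over training.

Scoring a subject (test matrix G, one row per AGG): normalize by the model's
Xref, form the grey relational coefficients

    xi(j) = (minAbs + gamma * maxAbs) / (|z(j) - R(j)| + gamma * maxAbs)

with distinguishing coefficient gamma (default 1), take the weighted sum
C_i = sum_j w_j xi(j) per row (equal weights 0.2), and report
Score = mean(C_i) * 100.

Test rows can deviate from R by *less* than the training minAbs, which would
push the raw coefficient above 1 and the score above 100; the denominator
deviation is therefore floored at minAbs, clamping xi to [0, 1] (the raw
unclamped coefficients are retained for audit).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_ORDER


class GreyModelError(ValueError):
    pass


@dataclass
class GreyReferenceModel:
    """Fitted assessment model; serializable to JSON."""

    xref: np.ndarray
    r_set: np.ndarray
    min_abs: float
    max_abs: float
    gamma: float = 1.0
    weights: np.ndarray = field(default_factory=lambda: np.full(5, 0.2))
    feature_order: tuple[str, ...] = FEATURE_ORDER
    training_subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.xref = np.asarray(self.xref, dtype=float)
        self.r_set = np.asarray(self.r_set, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (0 < self.gamma <= 1):
            raise GreyModelError("gamma must be in (0, 1]")
        if not np.isclose(self.weights.sum(), 1.0):
            raise GreyModelError("weights must sum to 1")
        if not (0 <= self.min_abs <= self.max_abs):
            raise GreyModelError("need 0 <= minAbs <= maxAbs")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_order": list(self.feature_order),
            "Xref": self.xref.tolist(),
            "R": self.r_set.tolist(),
            "minAbs": self.min_abs,
            "maxAbs": self.max_abs,
            "gamma": self.gamma,
            "weights": self.weights.tolist(),
            "training_subject_ids": list(self.training_subject_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GreyReferenceModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            xref=np.array(d["Xref"]), r_set=np.array(d["R"]),
            min_abs=d["minAbs"], max_abs=d["maxAbs"], gamma=d["gamma"],
            weights=np.array(d["weights"]),
            feature_order=tuple(d["feature_order"]),
            training_subject_ids=tuple(d["training_subject_ids"]),
        )


@dataclass
class AssessmentResult:
    subject_id: str
    ci: np.ndarray            # per-AGG correlation degrees, in [0, 1]
    score: float              # mean(ci) * 100
    z: np.ndarray             # normalized test rows
    xi: np.ndarray            # clamped grey coefficients per row
    xi_raw: np.ndarray        # unclamped coefficients, for audit

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "Ci": self.ci.tolist(),
            "score": self.score,
            "per_feature": {
                "z": self.z.tolist(),
                "xi": self.xi.tolist(),
                "xi_raw": self.xi_raw.tolist(),
            },
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def build_reference_matrix(x: np.ndarray) -> np.ndarray:
    """Xref: column means of the raw healthy feature matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xref = x.mean(axis=0)
    if np.any(xref == 0):
        raise GreyModelError("degenerate reference column (zero mean feature)")
    return xref


def normalize_rows(x: np.ndarray, xref: np.ndarray) -> np.ndarray:
    """Map raw features onto positive indicators centered at 1.

    z = x / Xref where x <= Xref, else 2 - x / Xref; not clamped below, so
    x > 2 Xref yields negative z (a large deviation).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise GreyModelError("non-finite feature values")
    ratio = x / xref
    return np.where(ratio <= 1.0, ratio, 2.0 - ratio)


def build_reference_set(z: np.ndarray) -> np.ndarray:
    """R: column means of the normalized training matrix."""
    return np.atleast_2d(np.asarray(z, dtype=float)).mean(axis=0)


def compute_extrema(z: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Global min and max of |Z(i,j) - R(j)| over all training rows/features."""
    dev = np.abs(np.atleast_2d(z) - r)
    return float(dev.min()), float(dev.max())


def fit_model(healthy_features: np.ndarray, gamma: float = 1.0,
              weights: np.ndarray | None = None,
              subject_ids: tuple[str, ...] = ()) -> GreyReferenceModel:
    """Fit the grey reference model from the healthy feature matrix (rows = AGGs)."""
    x = np.atleast_2d(np.asarray(healthy_features, dtype=float))
    n_feat = x.shape[1]
    if weights is None:
        weights = np.full(n_feat, 1.0 / n_feat)
    xref = build_reference_matrix(x)
    z = normalize_rows(x, xref)
    r = build_reference_set(z)
    min_abs, max_abs = compute_extrema(z, r)
    return GreyReferenceModel(
        xref=xref, r_set=r, min_abs=min_abs, max_abs=max_abs,
        gamma=gamma, weights=np.asarray(weights, dtype=float),
        feature_order=FEATURE_ORDER[:n_feat] if n_feat <= 5 else tuple(map(str, range(n_feat))),
        training_subject_ids=tuple(subject_ids),
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def correlation_coefficients(z_row: np.ndarray, model: GreyReferenceModel,
                             clamp: bool = True) -> np.ndarray:
    """Grey relational coefficients xi(j) of one normalized row against R.

    With ``clamp`` the deviation is floored at the training minAbs so that
    xi <= 1; with ``clamp=False`` the textbook (unclamped) value is returned.
    Degenerate training (maxAbs = 0) yields xi = 1 at zero deviation, else 0.
    """
    dev = np.abs(np.asarray(z_row, dtype=float) - model.r_set)
    if model.max_abs == 0:
        warnings.warn("degenerate model (maxAbs = 0); xi is an exact-match indicator")
        return (dev == 0).astype(float)
    g = model.gamma * model.max_abs
    d = np.maximum(dev, model.min_abs) if clamp else dev
    return (model.min_abs + g) / (d + g)


def correlation_degree(xi: np.ndarray, weights: np.ndarray) -> float:
    """C_i: weighted sum of the grey coefficients of one row."""
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise GreyModelError("weights must sum to 1")
    return float(np.dot(np.asarray(xi, dtype=float), weights))


def assess_subject(g: np.ndarray, model: GreyReferenceModel,
                   subject_id: str = "") -> AssessmentResult:
    """Score a subject's (k, n) feature matrix (one row per AGG) on 0-100."""
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if g.shape[1] != len(model.xref):
        raise GreyModelError("feature order/length mismatch with model")
    if g.shape[0] != 4:
        warnings.warn(f"{g.shape[0]} test rows instead of 4; averaging over available rows")
    z = normalize_rows(g, model.xref)
    xi = np.array([correlation_coefficients(row, model) for row in z])
    xi_raw = np.array([correlation_coefficients(row, model, clamp=False) for row in z])
    ci = xi @ model.weights
    return AssessmentResult(
        subject_id=subject_id, ci=ci, score=float(ci.mean() * 100.0),
        z=z, xi=xi, xi_raw=xi_raw,
    )
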