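"""Projection and classification of an independent treated cohort.

Treated oocytes (one record per cell, no augmentation at inference) are
standardized with the training statistics, projected into the learned 2-D
discriminative plane, and classified by the trained linear SVM.  Cluster
proximity is quantified against the training clusters: "within-young" when
the squared Mahalanobis distance to the young centroid falls inside the 95%
chi-square (2 df) ellipse, otherwise "near-young" when strictly closer (in
Mahalanobis distance) to the young than the old centroid, otherwise
"old-like".  These thresholds quantify a verbal tripartition and are
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierModel
from .deep_features import FeatureBank
from .discriminant import DiscriminantModel
from .errors import LeakageError, StateError, ValidationError
from .swarm import DRS

PROXIMITY_CATEGORIES = ("within-young", "near-young", "old-like")


@dataclass
class ClusterStats:
    """Centroid and 2-D covariance of one training cluster in canonical space."""

    centroid: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2)

    def mahalanobis_sq(self, pts: np.ndarray) -> np.ndarray:
        cov = self.cov + 1e-9 * np.trace(self.cov) * np.eye(2)
        diff = np.atleast_2d(pts) - self.centroid
        sol = np.linalg.solve(cov, diff.T)
        return np.einsum("ij,ji->i", diff, sol)


def cluster_statistics(model: DiscriminantModel, bank: FeatureBank,
                       rows: Sequence[int]) -> dict[str, ClusterStats]:
    """Per-class centroid + covariance of projected training rows."""
    rows = np.asarray(rows, dtype=int)
    pts = model.transform(bank.values[np.ix_(rows, model.feature_indices)])
    groups = bank.sample_meta["group"].to_numpy()[rows]
    out = {}
    for cls in sorted(np.unique(groups)):
        sub = pts[groups == cls]
        if len(sub) < 3:
            raise ValidationError(f"class {cls!r} has < 3 training points")
        out[cls] = ClusterStats(centroid=sub.mean(axis=0),
                                cov=np.cov(sub.T))
    return out


@dataclass
class TreatmentReport:
    per_oocyte: pd.DataFrame
    proportions_class: dict  # predicted class -> fraction
    proportions_proximity: dict  # proximity category -> fraction
    n_treated: int
    chi2_quantile: float

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_treated": self.n_treated,
            "proportions_class": self.proportions_class,
            "proportions_proximity": self.proportions_proximity,
            "chi2_quantile": self.chi2_quantile,
            "proximity_rule": ("within-young: Mahalanobis^2 to young centroid "
                               "<= chi-square 95th percentile (2 df); "
                               "near-young: closer to young than old centroid; "
                               "old-like: otherwise (reconstructed rule)"),
            "per_oocyte": self.per_oocyte.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def assess_treated(bank_treated: FeatureBank, drs: DRS,
                   classifier: ClassifierModel,
                   young_cluster_stats: ClusterStats,
                   old_cluster_stats: ClusterStats,
                   chi2_level: float = 0.95) -> TreatmentReport:
    """Project, classify, and proximity-categorize an independent cohort.

    Requires source disjointness from the classifier's training oocytes; the
    assessment never mutates the signature, discriminant, or classifier.
    """
    if drs.model is None or classifier.weights is None:
        raise StateError("signature/classifier must be fitted before assessment")
    meta = bank_treated.sample_meta
    treated_ids = set(meta["source_id"].astype(str))
    overlap = treated_ids & set(classifier.train_source_ids)
    if overlap:
        raise LeakageError(
            f"treated sources overlap classifier training: {sorted(overlap)[:5]}")
    if (meta["transform_tag"] != "original").any():
        raise ValidationError("treated cohort must be unaugmented (one record "
                              "per oocyte)")
    if meta["source_id"].duplicated().any():
        raise ValidationError("duplicate treated source_id records")

    n = len(meta)
    q = float(stats.chi2.ppf(chi2_level, df=2))
    if n == 0:
        return TreatmentReport(per_oocyte=pd.DataFrame(), proportions_class={},
                               proportions_proximity={}, n_treated=0,
                               chi2_quantile=q)

    rows = np.arange(n)
    pts = drs.model.transform(
        bank_treated.values[np.ix_(rows, drs.model.feature_indices)])
    decisions = classifier.decision_values(bank_treated, rows)
    preds = np.where(decisions > 0, classifier.classes[1], classifier.classes[0])
    d_young = young_cluster_stats.mahalanobis_sq(pts)
    d_old = old_cluster_stats.mahalanobis_sq(pts)
    category = np.where(
        d_young <= q, "within-young",
        np.where(d_young < d_old, "near-young", "old-like"))

    per = pd.DataFrame({
        "source_id": meta["source_id"].astype(str).to_numpy(),
        "canonical_1": pts[:, 0], "canonical_2": pts[:, 1],
        "decision_value": decisions, "predicted_class": preds,
        "proximity": category,
        "mahalanobis_sq_young": d_young, "mahalanobis_sq_old": d_old,
    })
    prop_class = {c: float((preds == c).mean()) for c in classifier.classes}
    prop_prox = {c: float((category == c).mean()) for c in PROXIMITY_CATEGORIES}
    return TreatmentReport(per_oocyte=per, proportions_class=prop_class,
                           proportions_proximity=prop_prox, n_treated=n,
                           chi2_quantile=q)
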