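"""Two-class canonical discriminative analysis and the Fisher distance.

The discriminative plane is spanned by two canonical variables: axis 1 is the
ridge-regularized Fisher direction (S_W + lambda I)^-1 (m1 - m2) of the
standardized selected features; axis 2 is the leading principal axis of the
pooled within-class covariance restricted to the orthogonal complement of
axis 1.  A two-class between-scatter has rank one, so the second axis is not
defined by the classical eigenproblem; this residual-variance construction is
an explicit reconstruction that keeps all discrimination on axis 1 while
giving a faithful 2-D scatter.

The Fisher distance is the trace ratio tr(S_B)/tr(S_W) of the between- and
within-cluster scatter matrices of the projected 2-D points; it is invariant
to rotation and uniform scaling of the plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .deep_features import FeatureBank
from .errors import DegenerateClusterError, StateError, ValidationError


def fisher_distance(points_2d: np.ndarray, labels: Sequence) -> float:
    """tr(S_B) / tr(S_W) over labelled 2-D points.

    S_B weights each class centroid's offset from the grand mean by the class
    size; S_W pools squared deviations from class centroids.
    """
    pts = np.asarray(points_2d, dtype=float)
    labels = np.asarray(labels)
    if pts.ndim != 2:
        raise ValidationError(f"points must be 2-D, got shape {pts.shape}")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError(f"need >= 2 classes, got {list(classes)}")
    tr_b = 0.0
    tr_w = 0.0
    grand = pts.mean(axis=0)
    for c in classes:
        sub = pts[labels == c]
        if len(sub) < 2:
            raise ValidationError(f"class {c!r} has < 2 points")
        m = sub.mean(axis=0)
        tr_b += len(sub) * float(((m - grand) ** 2).sum())
        tr_w += float(((sub - m) ** 2).sum())
    scale = max(float((pts - grand).var(axis=0).sum()), 1.0)
    if tr_w <= 1e-12 * scale:
        raise DegenerateClusterError("within-cluster scatter is numerically zero")
    return tr_b / tr_w


@dataclass
class DiscriminantModel:
    """Fitted 2-D canonical projection over a feature subset."""

    feature_indices: np.ndarray  # (K,) column indices into the bank
    center: np.ndarray  # (K,) train means
    scale: np.ndarray  # (K,) train standard deviations (zeros -> 1)
    projection: np.ndarray  # (K, 2), unit-norm columns
    classes: tuple[str, str] = ("old", "young")
    class_centroids: dict = field(default_factory=dict)  # class -> (2,) point
    fd_train: float = float("nan")
    fd_test: float = float("nan")
    ridge_lambda: float = 0.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.center) / self.scale) @ self.projection

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_indices": np.asarray(self.feature_indices).tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "projection": self.projection.tolist(),
            "classes": list(self.classes),
            "class_centroids": {k: list(map(float, v))
                                for k, v in self.class_centroids.items()},
            "fd_train": self.fd_train,
            "fd_test": self.fd_test,
            "ridge_lambda": self.ridge_lambda,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            feature_indices=np.asarray(doc["feature_indices"], dtype=int),
            center=np.asarray(doc["center"], float),
            scale=np.asarray(doc["scale"], float),
            projection=np.asarray(doc["projection"], float),
            classes=tuple(doc["classes"]),
            class_centroids={k: np.asarray(v, float)
                             for k, v in doc["class_centroids"].items()},
            fd_train=doc["fd_train"], fd_test=doc["fd_test"],
            ridge_lambda=doc["ridge_lambda"],
        )


def _two_class_labels(groups: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    classes = tuple(sorted(np.unique(groups)))
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 classes, got {classes}")
    return groups, classes  # type: ignore[return-value]


def fit_canonical(bank: FeatureBank, feature_indices: Sequence[int],
                  train_rows: Sequence[int],
                  ridge_lambda: float | None = None) -> DiscriminantModel:
    """Fit the 2-D canonical projection on a feature subset of the bank.

    ``ridge_lambda`` defaults to 1e-3 times the mean diagonal of the pooled
    within-class scatter, which keeps the solve well-posed when the subset
    size approaches the (source-grouped) training count.
    """
    idx = np.asarray(feature_indices, dtype=int)
    if len(idx) < 2:
        raise ValidationError(f"need K >= 2 features, got {len(idx)}")
    rows = np.asarray(train_rows, dtype=int)
    X = bank.values[np.ix_(rows, idx)].astype(float)
    groups = bank.sample_meta["group"].to_numpy()[rows]
    groups, classes = _two_class_labels(groups)

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale

    means = {c: Z[groups == c].mean(axis=0) for c in classes}
    S_w = np.zeros((len(idx), len(idx)))
    for c in classes:
        D = Z[groups == c] - means[c]
        S_w += D.T @ D
    if ridge_lambda is None:
        # floor guards subsets of all-constant (hence zero-scatter) features
        ridge_lambda = max(1e-3 * float(np.mean(np.diag(S_w))), 1e-8)
    diff = means[classes[1]] - means[classes[0]]
    A = S_w + ridge_lambda * np.eye(len(idx))
    try:
        a1 = np.linalg.solve(A, diff)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "within-class scatter is singular; raise ridge_lambda"
        ) from exc
    n1 = np.linalg.norm(a1)
    if n1 <= 0:
        raise DegenerateClusterError("class means coincide; Fisher axis undefined")
    a1 = a1 / n1

    # axis 2: dominant within-class residual direction orthogonal to axis 1
    n_w = max(len(rows) - 2, 1)
    C_w = S_w / n_w
    P = np.eye(len(idx)) - np.outer(a1, a1)
    M = P @ C_w @ P
    vals, vecs = np.linalg.eigh(M)
    a2 = vecs[:, -1]
    a2 = a2 - a1 * float(a1 @ a2)
    n2 = np.linalg.norm(a2)
    if n2 <= 1e-12:
        # deterministic fallback: any unit vector orthogonal to a1
        basis = np.eye(len(idx))
        cand = basis - np.outer(basis @ a1, a1)
        j = int(np.argmax(np.linalg.norm(cand, axis=1)))
        a2 = cand[j] / np.linalg.norm(cand[j])
    else:
        a2 = a2 / n2
    if a2[np.argmax(np.abs(a2))] < 0:  # sign convention
        a2 = -a2

    proj = np.column_stack([a1, a2])
    pts = Z @ proj
    model = DiscriminantModel(feature_indices=idx, center=center, scale=scale,
                              projection=proj, classes=classes,
                              ridge_lambda=float(ridge_lambda))
    model.class_centroids = {c: pts[groups == c].mean(axis=0) for c in classes}
    model.fd_train = fisher_distance(pts, groups)
    return model


def project(model: DiscriminantModel, bank: FeatureBank,
            rows: Sequence[int], with_fd: bool = False):
    """Project bank rows into the fitted 2-D space (optionally with their FD)."""
    if model.projection is None or model.projection.size == 0:
        raise StateError("model is not fitted")
    rows = np.asarray(rows, dtype=int)
    pts = model.transform(bank.values[np.ix_(rows, model.feature_indices)])
    if not with_fd:
        return pts
    labels = bank.sample_meta["group"].to_numpy()[rows]
    return pts, fisher_distance(pts, labels)
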