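"""Linear SVM training and grouped, nested cross-validated evaluation.

Folds are grouped by source oocyte (all augmented copies of one cell stay in
one fold) and stratified by class.  The outer loop estimates generalization;
an inner grouped CV on each outer-training set selects the margin penalty C.
Optionally, the feature subset itself is re-discovered inside every outer
training set, which keeps the evaluation free of selection bias; with a bank
of thousands of candidate features, selecting first and cross-validating
afterwards is known to be strongly optimistic.

Headline metrics are per-oocyte (majority vote over augmented copies, mean
decision value for the ROC); per-copy metrics are logged alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .deep_features import FeatureBank
from .errors import ValidationError
from .swarm import DRS

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassifierModel:
    """Standardized linear maximum-margin classifier on the signature features."""

    feature_indices: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float
    C: float
    classes: tuple[str, str]  # decision > 0 predicts classes[1]
    train_source_ids: tuple[str, ...] = ()

    def decision_values(self, bank: FeatureBank, rows: Sequence[int]) -> np.ndarray:
        rows = np.asarray(rows, dtype=int)
        X = bank.values[np.ix_(rows, self.feature_indices)].astype(float)
        Z = (X - self.center) / self.scale
        return Z @ self.weights + self.bias

    def predict(self, bank: FeatureBank, rows: Sequence[int]) -> np.ndarray:
        d = self.decision_values(bank, rows)
        return np.where(d > 0, self.classes[1], self.classes[0])

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_indices": np.asarray(self.feature_indices).tolist(),
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "weights": self.weights.tolist(), "bias": self.bias, "C": self.C,
            "classes": list(self.classes),
            "train_source_ids": list(self.train_source_ids),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        doc = json.loads(Path(path).read_text())
        return cls(feature_indices=np.asarray(doc["feature_indices"], int),
                   center=np.asarray(doc["center"], float),
                   scale=np.asarray(doc["scale"], float),
                   weights=np.asarray(doc["weights"], float),
                   bias=float(doc["bias"]), C=float(doc["C"]),
                   classes=tuple(doc["classes"]),
                   train_source_ids=tuple(doc["train_source_ids"]))


def train_svm(bank: FeatureBank, drs: DRS, rows: Sequence[int],
              C: float = 1.0) -> ClassifierModel:
    """Fit a linear SVM on the standardized signature features of ``rows``."""
    rows = np.asarray(rows, dtype=int)
    idx = np.asarray(drs.feature_indices, dtype=int)
    groups = bank.sample_meta["group"].to_numpy()[rows]
    classes = tuple(sorted(np.unique(groups)))
    if len(classes) != 2:
        raise ValidationError(f"training rows must contain 2 classes, got {classes}")
    X = bank.values[np.ix_(rows, idx)].astype(float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    y = (groups == classes[1]).astype(int)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)
    return ClassifierModel(
        feature_indices=idx, center=center, scale=scale,
        weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), C=C,
        classes=classes,
        train_source_ids=tuple(sorted(set(
            bank.sample_meta["source_id"].to_numpy()[rows]))))


def roc_curve(decision_values: Sequence[float], labels: Sequence,
              positive_class=None) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC points (FPR, TPR) and trapezoidal AUC.

    Tied decision values step diagonally (simultaneously), so the AUC equals
    the concordance probability with ties counted half.
    """
    d = np.asarray(decision_values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValidationError(f"ROC needs both classes, got {classes}")
    if positive_class is None:
        positive_class = classes[-1]
    y = (labels == positive_class)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    order = np.argsort(-d, kind="stable")
    d_sorted = d[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(d_sorted):
        j = i
        while j < len(d_sorted) and d_sorted[j] == d_sorted[i]:
            tp += int(y_sorted[j])
            fp += int(~y_sorted[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.asarray(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


@dataclass
class EvalReport:
    accuracy_mean: float  # percent, per-oocyte
    accuracy_sd: float  # percent, bootstrap over oocytes
    auc: float
    roc_points: np.ndarray
    confusion_matrix: np.ndarray  # rows true, cols predicted, class order
    fold_assignments: dict  # source_id -> fold
    bootstrap_n: int
    classes: tuple[str, str]
    per_copy_accuracy: float = float("nan")  # percent
    per_copy_auc: float = float("nan")
    per_oocyte: pd.DataFrame | None = None
    chosen_C: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": list(self.classes),
            "fold_assignments": self.fold_assignments,
            "bootstrap_n": self.bootstrap_n,
            "per_copy_accuracy_pct": self.per_copy_accuracy,
            "per_copy_auc": self.per_copy_auc,
            "chosen_C": self.chosen_C,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def grouped_stratified_folds(source_ids: np.ndarray, groups: np.ndarray,
                             n_folds: int, seed: int) -> dict:
    """Assign each source oocyte to one of ``n_folds`` folds, stratified by class."""
    table = pd.DataFrame({"source_id": source_ids, "group": groups})
    per_source = table.groupby("source_id")["group"].first()
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in sorted(per_source.unique()):
        ids = np.sort(per_source.index[per_source == cls].to_numpy())
        if len(ids) < n_folds:
            raise ValidationError(
                f"class {cls!r} has {len(ids)} source oocytes < {n_folds} folds")
        perm = rng.permutation(len(ids))
        for pos, k in enumerate(perm):
            assignment[str(ids[k])] = pos % n_folds
    return assignment


def _majority_vote(preds: np.ndarray, decisions: np.ndarray,
                   classes: tuple[str, str]) -> str:
    n_pos = int((preds == classes[1]).sum())
    n_neg = len(preds) - n_pos
    if n_pos > n_neg:
        return classes[1]
    if n_neg > n_pos:
        return classes[0]
    return classes[1] if decisions.mean() > 0 else classes[0]


def nested_cv_evaluate(bank: FeatureBank, drs: DRS, folds: int = 10,
                       C_grid: Sequence[float] = DEFAULT_C_GRID,
                       bootstrap_n: int = 1000, seed: int = 0,
                       selector: Callable[[np.ndarray], np.ndarray] | None = None,
                       inner_folds: int = 3) -> EvalReport:
    """Grouped nested cross-validation with bootstrap dispersion.

    ``selector``, when given, maps an outer-training row index array to a
    feature-index subset, re-discovering the signature inside every outer
    fold; otherwise the fixed ``drs.feature_indices`` are used everywhere.
    """
    meta = bank.sample_meta
    labelled = np.flatnonzero(meta["group"].isin(["young", "old"]).to_numpy())
    src = meta["source_id"].to_numpy()
    grp = meta["group"].to_numpy()
    assignment = grouped_stratified_folds(src[labelled], grp[labelled],
                                          folds, seed)
    classes = tuple(sorted(np.unique(grp[labelled])))

    pooled_rows: list[int] = []
    pooled_dec: list[float] = []
    pooled_pred: list[str] = []
    chosen_C: list[float] = []
    for k in range(folds):
        test_rows = np.array([r for r in labelled if assignment[src[r]] == k])
        train_rows = np.array([r for r in labelled if assignment[src[r]] != k])
        feat = (np.asarray(selector(train_rows), dtype=int) if selector
                else np.asarray(drs.feature_indices, dtype=int))
        fold_drs = DRS(K=len(feat), feature_indices=feat, model=drs.model,
                       composition={}, fd_curve=[])
        best_C, best_acc = C_grid[0], -1.0
        inner = grouped_stratified_folds(src[train_rows], grp[train_rows],
                                         inner_folds, seed + 1)
        for C in C_grid:
            hits = 0
            total = 0
            for j in range(inner_folds):
                i_test = np.array([r for r in train_rows if inner[src[r]] == j])
                i_train = np.array([r for r in train_rows if inner[src[r]] != j])
                m = train_svm(bank, fold_drs, i_train, C=C)
                hits += int((m.predict(bank, i_test) == grp[i_test]).sum())
                total += len(i_test)
            acc = hits / total
            if acc > best_acc + 1e-12:
                best_acc, best_C = acc, C
        chosen_C.append(best_C)
        model = train_svm(bank, fold_drs, train_rows, C=best_C)
        pooled_rows.extend(test_rows.tolist())
        pooled_dec.extend(model.decision_values(bank, test_rows).tolist())
        pooled_pred.extend(model.predict(bank, test_rows).tolist())

    pooled_rows = np.asarray(pooled_rows)
    pooled_dec = np.asarray(pooled_dec)
    pooled_pred = np.asarray(pooled_pred)
    truth = grp[pooled_rows]
    per_copy_accuracy = 100.0 * float((pooled_pred == truth).mean())
    _, per_copy_auc = roc_curve(pooled_dec, truth, positive_class=classes[1])

    # collapse to one vote per biological oocyte
    tab = pd.DataFrame({"source_id": src[pooled_rows], "group": truth,
                        "decision": pooled_dec, "pred": pooled_pred})
    rows_out = []
    for sid, sub in tab.groupby("source_id"):
        rows_out.append({
            "source_id": sid, "group": sub["group"].iloc[0],
            "decision": float(sub["decision"].mean()),
            "pred": _majority_vote(sub["pred"].to_numpy(),
                                   sub["decision"].to_numpy(), classes),
        })
    per_oocyte = pd.DataFrame(rows_out).sort_values("source_id").reset_index(drop=True)
    correct = (per_oocyte["pred"] == per_oocyte["group"]).to_numpy()
    accuracy_mean = 100.0 * float(correct.mean())
    rng = np.random.default_rng(seed + 2)
    n = len(correct)
    boot = rng.integers(0, n, size=(bootstrap_n, n))
    accuracy_sd = 100.0 * float(correct[boot].mean(axis=1).std())
    roc_pts, auc = roc_curve(per_oocyte["decision"].to_numpy(),
                             per_oocyte["group"].to_numpy(),
                             positive_class=classes[1])
    cm = np.zeros((2, 2), dtype=int)
    for i, true_c in enumerate(classes):
        for j, pred_c in enumerate(classes):
            cm[i, j] = int(((per_oocyte["group"] == true_c)
                            & (per_oocyte["pred"] == pred_c)).sum())
    return EvalReport(accuracy_mean=accuracy_mean, accuracy_sd=accuracy_sd,
                      auc=auc, roc_points=roc_pts, confusion_matrix=cm,
                      fold_assignments=assignment, bootstrap_n=bootstrap_n,
                      classes=classes, per_copy_accuracy=per_copy_accuracy,
                      per_copy_auc=per_copy_auc, per_oocyte=per_oocyte,
                      chosen_C=chosen_C)
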