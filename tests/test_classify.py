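"""Linear SVM training, ROC construction, grouped nested cross-validation."""

import numpy as np
import pytest

from drs.classify import (nested_cv_evaluate, roc_curve, train_svm,
                          grouped_stratified_folds)
from drs.errors import ValidationError
from drs.swarm import DRS
from conftest import make_gaussian_bank


def _drs_for(bank, indices):
    return DRS(K=len(indices), feature_indices=np.asarray(indices, int),
               model=None, composition={}, fd_curve=[])


def test_separable_bank_trains_to_perfect_accuracy():
    bank = make_gaussian_bank(n_sources_per_class=20, n_features=2,
                              n_informative=2, separation=8.0, seed=1)
    drs = _drs_for(bank, [0, 1])
    rows = np.arange(bank.n_samples)
    model = train_svm(bank, drs, rows, C=10.0)
    preds = model.predict(bank, rows)
    truth = bank.sample_meta["group"].to_numpy()
    assert (preds == truth).all()


def test_single_class_training_rejected():
    bank = make_gaussian_bank(seed=2)
    young_rows = np.flatnonzero(bank.sample_meta["group"] == "young")
    with pytest.raises(ValidationError):
        train_svm(bank, _drs_for(bank, [0, 1]), young_rows)


def test_duplicating_rows_keeps_separable_boundary():
    bank = make_gaussian_bank(n_sources_per_class=15, n_features=3,
                              separation=8.0, seed=3)
    drs = _drs_for(bank, [0, 1, 2])
    rows = np.arange(bank.n_samples)
    m1 = train_svm(bank, drs, rows, C=10.0)
    m2 = train_svm(bank, drs, np.concatenate([rows, rows]), C=10.0)
    np.testing.assert_allclose(m1.weights, m2.weights, rtol=1e-4, atol=1e-6)
    assert m1.bias == pytest.approx(m2.bias, rel=1e-3, abs=1e-6)


def test_weight_norm_shrinks_as_C_decreases():
    bank = make_gaussian_bank(n_sources_per_class=30, n_features=3,
                              separation=1.0, seed=4)
    drs = _drs_for(bank, [0, 1, 2])
    rows = np.arange(bank.n_samples)
    norms = [np.linalg.norm(train_svm(bank, drs, rows, C=C).weights)
             for C in (1e-3, 1e-1, 1e1, 1e3)]
    assert norms[0] < norms[-1]
    assert all(a <= b + 1e-9 for a, b in zip(norms, norms[1:]))


def test_roc_uninformative_scores_auc_half():
    pts, auc = roc_curve([0.3] * 8, ["old"] * 4 + ["young"] * 4)
    assert auc == pytest.approx(0.5)


def test_roc_perfect_ranking_auc_one():
    pts, auc = roc_curve([0.1, 0.2, 0.8, 0.9],
                         ["old", "old", "young", "young"],
                         positive_class="young")
    assert auc == pytest.approx(1.0)


def test_roc_worked_example_auc_three_quarters():
    """Scores 1..4 with labels old,young,old,young: 3 of 4 pairs concordant."""
    pts, auc = roc_curve([1, 2, 3, 4], ["old", "young", "old", "young"],
                         positive_class="young")
    assert auc == pytest.approx(0.75)


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=40)
    labels = np.array(["old", "young"] * 20)
    pts, auc = roc_curve(scores, labels)
    assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
    assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
    assert 0.0 <= auc <= 1.0


def test_roc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(6)
    scores = rng.normal(size=60) + np.repeat([0.0, 0.7], 30)
    labels = np.repeat(["old", "young"], 30)
    _, auc = roc_curve(scores, labels, positive_class="young")
    assert auc == pytest.approx(roc_auc_score(labels == "young", scores))


def test_roc_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_curve([1, 2], ["young", "young"])


def test_grouped_folds_never_split_a_source():
    bank = make_gaussian_bank(n_sources_per_class=12, copies=4, seed=7)
    meta = bank.sample_meta
    assignment = grouped_stratified_folds(meta["source_id"].to_numpy(),
                                          meta["group"].to_numpy(), 4, seed=1)
    # every record of a source maps to one fold by construction
    for sid in meta["source_id"].unique():
        assert sid in assignment
    folds = np.array([assignment[s] for s in meta["source_id"]])
    for k in range(4):
        sub = meta[folds == k]
        assert set(sub["group"]) == {"young", "old"}


def test_too_many_folds_rejected():
    bank = make_gaussian_bank(n_sources_per_class=4, seed=8)
    meta = bank.sample_meta
    with pytest.raises(ValidationError):
        grouped_stratified_folds(meta["source_id"].to_numpy(),
                                 meta["group"].to_numpy(), 10, seed=0)


def test_nested_cv_perfectly_separated_bank():
    bank = make_gaussian_bank(n_sources_per_class=20, n_features=4,
                              n_informative=2, separation=10.0, copies=2,
                              seed=9)
    report = nested_cv_evaluate(bank, _drs_for(bank, [0, 1]), folds=5,
                                bootstrap_n=200, seed=1)
    assert report.accuracy_mean == pytest.approx(100.0)
    assert report.auc == pytest.approx(1.0)
    assert report.accuracy_sd == pytest.approx(0.0)
    assert report.confusion_matrix.sum() == 40


def test_nested_cv_shuffled_labels_null_auc():
    """Label permutation destroys signal: AUC near chance."""
    bank = make_gaussian_bank(n_sources_per_class=50, n_features=6,
                              n_informative=2, separation=3.0, seed=10)
    rng = np.random.default_rng(3)
    meta = bank.sample_meta
    per_source = meta.groupby("source_id")["group"].first()
    shuffled = per_source.sample(frac=1.0, random_state=7).to_numpy()
    relabel = dict(zip(per_source.index, shuffled))
    meta["group"] = meta["source_id"].map(relabel)
    report = nested_cv_evaluate(bank, _drs_for(bank, [0, 1, 2]), folds=5,
                                bootstrap_n=100, seed=2)
    assert 0.35 <= report.auc <= 0.65


def test_nested_cv_bootstrap_deterministic():
    bank = make_gaussian_bank(n_sources_per_class=15, n_features=4,
                              separation=1.5, seed=11)
    drs = _drs_for(bank, [0, 1])
    a = nested_cv_evaluate(bank, drs, folds=3, bootstrap_n=100, seed=5)
    b = nested_cv_evaluate(bank, drs, folds=3, bootstrap_n=100, seed=5)
    assert a.accuracy_sd == b.accuracy_sd
    assert a.auc == b.auc


def test_classifier_json_round_trip(tmp_path):
    from drs.classify import ClassifierModel

    bank = make_gaussian_bank(seed=12)
    model = train_svm(bank, _drs_for(bank, [0, 1]), np.arange(bank.n_samples))
    model.to_json(tmp_path / "clf.json")
    loaded = ClassifierModel.from_json(tmp_path / "clf.json")
    rows = np.arange(10)
    np.testing.assert_allclose(loaded.decision_values(bank, rows),
                               model.decision_values(bank, rows))
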