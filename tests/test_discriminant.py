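"""Fisher distance and the 2-D canonical projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drs.discriminant import fisher_distance, fit_canonical, project
from drs.errors import DegenerateClusterError, StateError, ValidationError
from conftest import make_gaussian_bank


def test_fisher_distance_hand_example_equals_25():
    """A={(0,0),(2,0)}, B={(10,0),(12,0)}: tr(S_B)=100, tr(S_W)=4, FD=25."""
    pts = np.array([[0, 0], [2, 0], [10, 0], [12, 0]], float)
    labels = ["a", "a", "b", "b"]
    assert fisher_distance(pts, labels) == pytest.approx(25.0)


def test_fisher_distance_zero_when_means_coincide():
    pts = np.array([[0, 0], [2, 0], [0, 0], [2, 0]], float)
    labels = ["a", "a", "b", "b"]
    assert fisher_distance(pts, labels) == pytest.approx(0.0)


@given(c=st.floats(min_value=0.1, max_value=100.0),
       angle=st.floats(min_value=0.0, max_value=2 * np.pi))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_fisher_distance_invariant_to_scaling_and_rotation(c, angle):
    rng = np.random.default_rng(17)
    pts = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(3, 1, (10, 2))])
    labels = ["a"] * 10 + ["b"] * 10
    base = fisher_distance(pts, labels)
    R = np.array([[np.cos(angle), -np.sin(angle)],
                  [np.sin(angle), np.cos(angle)]])
    assert fisher_distance(c * pts @ R.T, labels) == pytest.approx(base,
                                                                   rel=1e-9)


def test_fisher_distance_permutation_invariant():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(20, 2))
    labels = np.array(["a"] * 10 + ["b"] * 10)
    perm = rng.permutation(20)
    assert fisher_distance(pts[perm], labels[perm]) == pytest.approx(
        fisher_distance(pts, labels))


def test_fisher_distance_errors():
    pts = np.zeros((4, 2))
    with pytest.raises(ValidationError):
        fisher_distance(pts, ["a"] * 4)
    with pytest.raises(DegenerateClusterError):
        fisher_distance(np.array([[0, 0], [0, 0], [1, 1], [1, 1]], float),
                        ["a", "a", "b", "b"])


def _informative_bank(seed=0, n=200, noise=1.0):
    """Two features; classes separated only along feature 0."""
    return make_gaussian_bank(n_sources_per_class=n, n_features=2,
                              n_informative=1, separation=4.0, seed=seed)


def test_fisher_axis_recovers_informative_direction():
    bank = _informative_bank(seed=3)
    rows = np.arange(bank.n_samples)
    model = fit_canonical(bank, [0, 1], rows)
    a1 = model.projection[:, 0]
    assert abs(a1[0]) > 0.99  # axis 1 ~ (+-1, 0)
    assert np.linalg.norm(model.projection[:, 0]) == pytest.approx(1.0)
    assert np.linalg.norm(model.projection[:, 1]) == pytest.approx(1.0)
    assert abs(model.projection[:, 0] @ model.projection[:, 1]) < 1e-9


def test_large_ridge_limit_gives_mean_difference_direction():
    bank = _informative_bank(seed=4)
    rows = np.arange(bank.n_samples)
    model = fit_canonical(bank, [0, 1], rows, ridge_lambda=1e9)
    groups = bank.sample_meta["group"].to_numpy()
    Z = (bank.values[:, :2] - model.center) / model.scale
    diff = Z[groups == "young"].mean(0) - Z[groups == "old"].mean(0)
    diff /= np.linalg.norm(diff)
    assert abs(abs(model.projection[:, 0] @ diff) - 1) < 1e-6


def test_projection_reproduces_fd_train_exactly():
    bank = make_gaussian_bank(n_sources_per_class=15, n_features=5,
                              separation=2.0, seed=6)
    rows = np.arange(bank.n_samples)
    model = fit_canonical(bank, [0, 1, 2], rows)
    _, fd = project(model, bank, rows, with_fd=True)
    assert fd == pytest.approx(model.fd_train, rel=1e-12)


def test_test_fd_close_to_train_fd_at_large_n():
    bank = make_gaussian_bank(n_sources_per_class=500, n_features=4,
                              separation=3.0, seed=8)
    n = bank.n_samples
    train = np.arange(0, n, 2)
    test = np.arange(1, n, 2)
    model = fit_canonical(bank, [0, 1, 2, 3], train)
    _, fd_test = project(model, bank, test, with_fd=True)
    assert abs(fd_test - model.fd_train) < 0.25 * model.fd_train


def test_projection_shape_contract():
    bank = make_gaussian_bank(seed=9)
    model = fit_canonical(bank, [0, 1, 2], np.arange(bank.n_samples))
    pts = project(model, bank, np.arange(7))
    assert pts.shape == (7, 2)


def test_feature_reordering_permutes_projection_rows():
    bank = make_gaussian_bank(n_sources_per_class=30, n_features=6,
                              separation=2.0, seed=10)
    rows = np.arange(bank.n_samples)
    idx = [0, 2, 4]
    perm = [4, 0, 2]
    m1 = fit_canonical(bank, idx, rows, ridge_lambda=0.5)
    m2 = fit_canonical(bank, perm, rows, ridge_lambda=0.5)
    # m2's rows are m1's rows reordered by the same permutation
    mapping = [idx.index(j) for j in perm]
    np.testing.assert_allclose(np.abs(m2.projection),
                               np.abs(m1.projection[mapping]), atol=1e-8)


def test_fd_train_monotone_in_class_separation():
    fds = []
    for sep in (0.5, 1.0, 2.0, 4.0):
        bank = make_gaussian_bank(n_sources_per_class=300, n_features=2,
                                  n_informative=1, separation=sep, seed=12)
        model = fit_canonical(bank, [0, 1], np.arange(bank.n_samples))
        fds.append(model.fd_train)
    assert all(b > a for a, b in zip(fds, fds[1:]))


def test_unfitted_model_projection_raises():
    from drs.discriminant import DiscriminantModel

    model = DiscriminantModel(feature_indices=np.array([0, 1]),
                              center=np.zeros(2), scale=np.ones(2),
                              projection=np.empty((0, 0)))
    bank = make_gaussian_bank(seed=1)
    with pytest.raises(StateError):
        project(model, bank, [0, 1])


def test_model_json_round_trip(tmp_path):
    from drs.discriminant import DiscriminantModel

    bank = make_gaussian_bank(seed=2)
    model = fit_canonical(bank, [0, 1, 2], np.arange(bank.n_samples))
    model.to_json(tmp_path / "m.json")
    loaded = DiscriminantModel.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(loaded.projection, model.projection)
    assert loaded.fd_train == pytest.approx(model.fd_train)
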