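"""Convolutional feature bank: layer arithmetic, provenance, fine-tuning."""

import numpy as np
import pytest

from drs.deep_features import (ConvLayerSpec, NetSpec, convolve_layer,
                               default_nets, extract_features,
                               finetune_final_layer, make_filters)
from drs.errors import ValidationError
from drs.imaging import OocyteImage


def brute_force_correlate(image, kernel):
    """Nested-loop valid cross-correlation: the independent oracle."""
    H, W = image.shape
    kh, kw = kernel.shape
    out = np.zeros((H - kh + 1, W - kw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (image[i:i + kh, j:j + kw] * kernel).sum()
    return out


def test_single_filter_matches_brute_force_on_8x8():
    rng = np.random.default_rng(0)
    img = rng.random((8, 8)).astype(np.float32)
    kernel = rng.standard_normal((3, 3)).astype(np.float32)
    layer = ConvLayerSpec(1, apply_relu=False)
    out = convolve_layer(img, layer, kernel[None, None])
    expected = brute_force_correlate(img, kernel)
    np.testing.assert_allclose(out[0], expected, rtol=1e-5)


def test_averaging_filter_on_constant_image():
    layer = ConvLayerSpec(1, apply_relu=False)
    img = np.full((10, 10), 0.37)
    out = convolve_layer(img, layer, np.full((1, 1, 3, 3), 1.0 / 9.0))
    np.testing.assert_allclose(out, 0.37, rtol=1e-6)


def test_max_pool_of_1_to_36_grid():
    """Identity conv + 3x3/3 max-pool of the 6x6 grid 1..36 -> [[15,18],[33,36]]."""
    img = np.arange(1, 37, dtype=float).reshape(6, 6)
    ident = np.zeros((1, 1, 1, 1))
    ident[0, 0, 0, 0] = 1.0
    layer = ConvLayerSpec(1, filter_size=(1, 1), apply_relu=False, pool=(3, 3))
    out = convolve_layer(img, layer, ident)
    np.testing.assert_array_equal(out[0], [[15.0, 18.0], [33.0, 36.0]])


def test_relu_zeroes_all_negative_output():
    img = np.ones((6, 6))
    layer = ConvLayerSpec(1, apply_relu=True)
    out = convolve_layer(img, layer, -np.ones((1, 1, 3, 3)))
    assert (out == 0).all()


def test_too_small_input_raises_instructive_error():
    layer = ConvLayerSpec(1)
    with pytest.raises(ValidationError, match="larger input"):
        convolve_layer(np.ones((2, 2)), layer, np.ones((1, 1, 3, 3)))


def test_layer_spec_validation():
    with pytest.raises(ValidationError):
        ConvLayerSpec(0)
    with pytest.raises(ValidationError):
        ConvLayerSpec(4, filter_size=(2, 2))
    with pytest.raises(ValidationError):
        ConvLayerSpec(4, pool=(1, 1))


def _tiny_images(n=4, side=48, seed=0, group="young"):
    rng = np.random.default_rng(seed)
    return [OocyteImage(pixels=rng.random((side, side)),
                        mask=np.ones((side, side), bool), group=group,
                        source_id=f"s{i}") for i in range(n)]


def _tiny_net(name="tiny", channels=(4, 6), side=32):
    return NetSpec(name=name, input_side=side,
                   layers=tuple(ConvLayerSpec(c, pool=(3, 3)) for c in channels))


def test_feature_count_and_provenance_partition():
    images = _tiny_images()
    nets = [_tiny_net("a", (4, 6)), _tiny_net("b", (3,))]
    bank = extract_features(images, nets, seed=1)
    assert bank.n_features == 6 + 3
    counts = bank.feature_provenance.groupby("net").size()
    assert counts["a"] == 6 and counts["b"] == 3
    assert not np.isnan(bank.values).any()


def test_default_bank_width_near_six_thousand(small_cohort_images):
    labelled = [im for im in small_cohort_images[:2]]
    bank = extract_features(labelled, seed=0)
    assert 3000 <= bank.n_features <= 9000
    net3 = bank.feature_provenance.query("net == 'net3-moderate'")
    assert len(net3) == 96  # final layer of 96 3x3 filters
    assert (net3["layer"] == 2).all()


def test_identical_images_identical_rows():
    images = _tiny_images(2, seed=5)
    images[1] = OocyteImage(pixels=images[0].pixels.copy(),
                            mask=images[0].mask.copy(), group="old",
                            source_id="dup")
    bank = extract_features(images, [_tiny_net()], seed=2)
    np.testing.assert_array_equal(bank.values[0], bank.values[1])


def test_extraction_deterministic_in_seed():
    images = _tiny_images()
    nets = [_tiny_net()]
    a = extract_features(images, nets, seed=9).values
    b = extract_features(images, nets, seed=9).values
    c = extract_features(images, nets, seed=10).values
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_heterogeneous_sizes_rejected():
    images = _tiny_images(2)
    images.append(OocyteImage(pixels=np.zeros((24, 24)),
                              mask=np.ones((24, 24), bool), source_id="x"))
    with pytest.raises(ValidationError, match="heterogeneous"):
        extract_features(images, [_tiny_net()], seed=0)


def _symmetrize(filters):
    """Average each kernel over the dihedral group (rotations + mirrors)."""
    out = np.zeros_like(filters)
    for k in range(4):
        r = np.rot90(filters, k=k, axes=(2, 3))
        out += r + r[:, :, :, ::-1]
    return out / 8.0


def test_readout_invariant_to_rot90_and_mirror_with_symmetric_kernels():
    """Global-average readout commutes with square-symmetry transforms when the
    kernels themselves are dihedrally symmetric and pooling tiles align."""
    rng = np.random.default_rng(4)
    img = rng.random((20, 20)).astype(np.float32)
    layer = ConvLayerSpec(5, pool=(3, 3))
    w = _symmetrize(rng.standard_normal((5, 1, 3, 3))).astype(np.float32)
    base = convolve_layer(img, layer, w).mean(axis=(1, 2))
    for transform in (np.rot90, lambda a: np.rot90(a, 2),
                      lambda a: np.rot90(a, 3), np.fliplr, np.flipud):
        t = np.ascontiguousarray(transform(img))
        got = convolve_layer(t, layer, w).mean(axis=(1, 2))
        np.testing.assert_allclose(got, base, rtol=1e-4)


def _separable_images(n_per_class=6, side=40, seed=0):
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls, level in (("young", 0.8), ("old", 0.3)):
        for i in range(n_per_class):
            px = level + 0.05 * rng.standard_normal((side, side))
            images.append(OocyteImage(pixels=px, mask=np.ones((side, side), bool),
                                      group=cls, source_id=f"{cls}{i}"))
            labels.append(cls)
    return images, labels


def test_finetune_zero_learning_rate_keeps_filters():
    images, labels = _separable_images()
    net = _tiny_net(side=32)
    tuned = finetune_final_layer(net, images, labels, epochs=3,
                                 learning_rate=0.0, seed=1)
    orig = make_filters(net, 1)
    np.testing.assert_array_equal(tuned.filters[-1], orig[-1].astype(np.float32))


def test_finetune_deterministic():
    images, labels = _separable_images()
    net = _tiny_net(side=32)
    a = finetune_final_layer(net, images, labels, epochs=3, seed=7)
    b = finetune_final_layer(net, images, labels, epochs=3, seed=7)
    np.testing.assert_array_equal(a.filters[-1], b.filters[-1])


def test_finetune_reduces_loss_and_freezes_earlier_layers():
    images, labels = _separable_images(seed=3)
    net = _tiny_net(side=32)
    tuned = finetune_final_layer(net, images, labels, epochs=20,
                                 learning_rate=0.5, seed=2)
    losses = tuned.loss_history
    assert losses[-1] < losses[0]
    assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
    orig = make_filters(net, 2)
    np.testing.assert_array_equal(tuned.filters[0], orig[0])
    assert tuned.layers[-1].filter_source == "trained"


def test_finetune_single_class_rejected():
    images, labels = _separable_images()
    young = [im for im in images if im.group == "young"]
    with pytest.raises(ValidationError):
        finetune_final_layer(_tiny_net(side=32), young, ["young"] * len(young),
                             seed=0)


def test_bank_save_load_round_trip(tmp_path):
    images = _tiny_images()
    bank = extract_features(images, [_tiny_net()], seed=3)
    bank.save(tmp_path / "bank")
    loaded = type(bank).load(tmp_path / "bank")
    np.testing.assert_allclose(loaded.values, bank.values, rtol=1e-6)
    assert list(loaded.sample_meta["source_id"]) == \
        list(bank.sample_meta["source_id"])
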