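"""Multi-net convolutional feature banks.

Three fixed-architecture stacks of convolution -> ReLU -> max-pool layers,
ordered from extremely deep to moderately deep, turn each oocyte crop into a
fixed-width feature vector via a global-average readout of the final stack.
Filters are seeded, variance-scaled random banks standing in for transferred
filters; the final layer of the shallowest net can be fine-tuned on labelled
oocytes through a temporary two-class logistic head.

All convolutions are valid (unpadded) cross-correlations; max-pooling uses
non-overlapping tiles by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._utils import derive_seed
from .errors import ValidationError
from .imaging import OocyteImage


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution -> (ReLU) -> (max-pool) stage."""

    n_filters: int
    filter_size: tuple[int, int] = (3, 3)
    filter_source: str = "seeded-random"  # or "trained"
    apply_relu: bool = True
    pool: tuple[int, int] | None = None  # (window, stride)

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValidationError(f"n_filters must be >= 1, got {self.n_filters}")
        if any(d % 2 == 0 for d in self.filter_size):
            raise ValidationError(f"filter dims must be odd, got {self.filter_size}")
        if self.pool is not None and self.pool[0] < 2:
            raise ValidationError(f"pool window must be >= 2, got {self.pool}")


@dataclass(frozen=True)
class NetSpec:
    """An ordered convolutional stack with a global pooling readout.

    ``filters``, when present, pins every layer's weights (e.g. after
    fine-tuning); otherwise weights are generated deterministically from the
    extraction seed and the net name.
    """

    name: str
    layers: tuple[ConvLayerSpec, ...]
    depth_class: str = "deep"
    input_side: int = 128
    readout: str = "global-average"
    filters: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValidationError(f"net {self.name!r} needs at least one layer")

    @property
    def readout_width(self) -> int:
        return self.layers[-1].n_filters


def default_nets() -> tuple[NetSpec, NetSpec, NetSpec]:
    """The three-net bank: extremely deep / deep / moderately deep.

    Readout widths 4096 + 1792 + 96 give a bank of 5984 features, matching the
    intended order of magnitude (~6000).  Pooling is placed so the deepest
    stack still ends with a >= 2x2 map on a 128-px input.
    """
    L = ConvLayerSpec
    net1 = NetSpec(
        name="net1-verydeep",
        depth_class="extremely-deep",
        input_side=128,
        layers=(
            L(16, pool=(3, 3)), L(32), L(48, pool=(3, 3)), L(64),
            L(96), L(128), L(256), L(4096),
        ),
    )
    net2 = NetSpec(
        name="net2-deep",
        depth_class="deep",
        input_side=128,
        layers=(L(24, pool=(3, 3)), L(48, pool=(3, 3)), L(96, pool=(3, 3)),
                L(1792)),
    )
    net3 = NetSpec(
        name="net3-moderate",
        depth_class="moderately-deep",
        input_side=64,
        layers=(L(48, pool=(3, 3)), L(96, pool=(3, 3))),
    )
    return net1, net2, net3


def make_filters(net: NetSpec, seed: int) -> list[np.ndarray]:
    """He-scaled random filter banks, deterministic in (seed, net name, layer)."""
    if net.filters is not None:
        return [np.asarray(f, dtype=np.float32) for f in net.filters]
    out = []
    c_in = 1
    for i, layer in enumerate(net.layers):
        kh, kw = layer.filter_size
        rng = np.random.default_rng(derive_seed(seed, "filters", net.name, i))
        std = np.sqrt(2.0 / (c_in * kh * kw))
        out.append((std * rng.standard_normal((layer.n_filters, c_in, kh, kw)))
                   .astype(np.float32))
        c_in = layer.n_filters
    return out


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of a batch (B,C,H,W) with filters (Cout,C,kh,kw)."""
    B, C, H, W = x.shape
    c_out, c_in, kh, kw = w.shape
    if c_in != C:
        raise ValidationError(f"filter depth {c_in} != input depth {C}")
    ho, wo = H - kh + 1, W - kw + 1
    if ho < 1 or wo < 1:
        raise ValidationError(
            f"convolution output would be {ho}x{wo}; use a larger input or "
            f"fewer/smaller layers"
        )
    acc = np.zeros((B, ho, wo, c_out), dtype=np.float32)
    for dy in range(kh):
        for dx in range(kw):
            acc += np.tensordot(x[:, :, dy:dy + ho, dx:dx + wo],
                                w[:, :, dy, dx], axes=([1], [1]))
    return np.ascontiguousarray(acc.transpose(0, 3, 1, 2))


def _max_pool(x: np.ndarray, window: int, stride: int) -> np.ndarray:
    B, C, H, W = x.shape
    if H < window or W < window:
        raise ValidationError(
            f"pooling window {window} exceeds map size {H}x{W}; use a larger "
            f"input or fewer layers"
        )
    v = sliding_window_view(x, (window, window), axis=(2, 3))
    return v[:, :, ::stride, ::stride].max(axis=(-2, -1))


def convolve_layer(image_stack: np.ndarray, layer: ConvLayerSpec,
                   filters: np.ndarray) -> np.ndarray:
    """Apply one conv/ReLU/pool stage to a (C,H,W) or (H,W) stack."""
    x = np.asarray(image_stack, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    out = _conv_valid(x[None], np.asarray(filters, dtype=np.float32))[0]
    if layer.apply_relu:
        out = np.maximum(out, 0.0)
    if layer.pool is not None:
        out = _max_pool(out[None], layer.pool[0], layer.pool[1])[0]
    return out


def _forward_batch(x: np.ndarray, net: NetSpec, filters: Sequence[np.ndarray],
                   stop_before: int | None = None) -> np.ndarray:
    """Run a (B,1,H,W) batch through the stack, optionally stopping early."""
    n = len(net.layers) if stop_before is None else stop_before
    for layer, w in zip(net.layers[:n], filters[:n]):
        x = _conv_valid(x, w)
        if layer.apply_relu:
            x = np.maximum(x, 0.0)
        if layer.pool is not None:
            x = _max_pool(x, layer.pool[0], layer.pool[1])
    return x


@dataclass
class FeatureBank:
    """Samples x features matrix with per-feature net/layer provenance."""

    values: np.ndarray
    feature_provenance: pd.DataFrame  # columns: net, layer, channel
    sample_meta: pd.DataFrame  # columns: source_id, group, transform_tag, latent_age

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValidationError("feature bank contains missing values")
        if len(self.feature_provenance) != self.values.shape[1]:
            raise ValidationError("provenance length must equal feature count")
        if len(self.sample_meta) != self.values.shape[0]:
            raise ValidationError("sample metadata length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        cols = [f"{r.net}|{r.layer}|{r.channel}"
                for r in self.feature_provenance.itertuples(index=False)]
        pd.DataFrame(self.values, columns=cols).to_csv(
            prefix.with_suffix(".features.tsv"), sep="\t", index=False,
            float_format="%.7g")
        self.sample_meta.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t",
                                index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureBank":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t")
        prov = pd.DataFrame(
            [c.split("|") for c in values.columns],
            columns=["net", "layer", "channel"])
        prov["layer"] = prov["layer"].astype(int)
        prov["channel"] = prov["channel"].astype(int)
        meta = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
        return cls(values=values.to_numpy(dtype=np.float64),
                   feature_provenance=prov, sample_meta=meta)


def _resized_stack(images: Sequence[OocyteImage], side: int) -> np.ndarray:
    from skimage.transform import resize

    out = np.empty((len(images), 1, side, side), dtype=np.float32)
    for i, im in enumerate(images):
        if im.pixels.shape == (side, side):
            out[i, 0] = im.pixels
        else:
            out[i, 0] = resize(im.pixels, (side, side), order=1,
                               anti_aliasing=True, preserve_range=True)
    return out


def extract_features(images: Sequence[OocyteImage],
                     nets: Sequence[NetSpec] | None = None,
                     seed: int = 0, batch_size: int = 24) -> FeatureBank:
    """Extract the concatenated multi-net feature bank for a cohort.

    Each net resamples the common square crop to its own input side, runs the
    stack, and reduces the final maps by a global channel average.  The result
    is deterministic in (images, nets, seed).
    """
    if nets is None:
        nets = default_nets()
    if len(images) == 0:
        raise ValidationError("no images supplied")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise ValidationError(f"heterogeneous image sizes: {sorted(shapes)}")
    side0 = shapes.pop()
    if side0[0] != side0[1]:
        raise ValidationError(f"images must be square, got {side0}")

    blocks: list[np.ndarray] = []
    prov_rows: list[tuple[str, int, int]] = []
    for net in nets:
        filters = make_filters(net, seed)
        stack = _resized_stack(images, net.input_side)
        feats = np.empty((len(images), net.readout_width), dtype=np.float64)
        for lo in range(0, len(images), batch_size):
            batch = stack[lo:lo + batch_size]
            final = _forward_batch(batch, net, filters)
            feats[lo:lo + batch.shape[0]] = final.mean(axis=(2, 3))
        blocks.append(feats)
        n_layers = len(net.layers)
        prov_rows.extend((net.name, n_layers, ch)
                         for ch in range(net.readout_width))

    meta = pd.DataFrame({
        "source_id": [im.source_id for im in images],
        "group": [im.group for im in images],
        "transform_tag": [im.transform_tag for im in images],
        "latent_age": [im.latent_age for im in images],
    })
    prov = pd.DataFrame(prov_rows, columns=["net", "layer", "channel"])
    return FeatureBank(values=np.concatenate(blocks, axis=1),
                       feature_provenance=prov, sample_meta=meta)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _final_forward(xcols: np.ndarray, wmat: np.ndarray, layer: ConvLayerSpec,
                   ho: int, wo: int, v: np.ndarray, b: float):
    """Forward through the final conv layer + logistic head, keeping caches."""
    B = xcols.shape[0]
    z = (xcols @ wmat).reshape(B, ho, wo, -1).transpose(0, 3, 1, 2)
    a = np.maximum(z, 0.0) if layer.apply_relu else z
    pooled = _max_pool(a, *layer.pool) if layer.pool is not None else a
    r = pooled.mean(axis=(2, 3))
    p = _sigmoid(r @ v + b)
    return z, a, pooled, r, p


def finetune_final_layer(net: NetSpec, train_images: Sequence[OocyteImage],
                         train_labels: Sequence[str], epochs: int = 5,
                         learning_rate: float = 0.05, seed: int = 0,
                         max_samples: int | None = None) -> NetSpec:
    """Fine-tune the final layer's filters on labelled oocytes.

    A two-class logistic head is attached to the global-average readout,
    trained jointly with the final conv filters by full-batch gradient descent
    (with step halving so the loss never increases), then discarded.  Earlier
    layers are returned bit-exactly unchanged.
    """
    labels = np.asarray([str(l) for l in train_labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError(f"fine-tuning needs 2 classes, got {classes}")
    if len(labels) != len(train_images):
        raise ValidationError("train_images and train_labels length mismatch")
    y = (labels == classes[-1]).astype(np.float64)

    idx = np.arange(len(train_images))
    if max_samples is not None and len(idx) > max_samples:
        rng_sub = np.random.default_rng(derive_seed(seed, "finetune-subsample"))
        idx = np.sort(rng_sub.choice(idx, size=max_samples, replace=False))
    images = [train_images[i] for i in idx]
    y = y[idx]

    filters = make_filters(net, seed)
    stack = _resized_stack(images, net.input_side)
    x_in = _forward_batch(stack, net, filters, stop_before=len(net.layers) - 1)

    layer = net.layers[-1]
    kh, kw = layer.filter_size
    B, C, H, W = x_in.shape
    ho, wo = H - kh + 1, W - kw + 1
    if ho < 1 or wo < 1:
        raise ValidationError("final-layer input too small for its filters")
    # im2col of the cached final-layer inputs: (B, ho*wo, C*kh*kw)
    patches = sliding_window_view(x_in, (kh, kw), axis=(2, 3))
    xcols = np.ascontiguousarray(
        patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, ho * wo, C * kh * kw))

    w = filters[-1].astype(np.float64)
    c_out = w.shape[0]
    wmat = w.reshape(c_out, -1).T.copy()  # (C*kh*kw, c_out)
    rng = np.random.default_rng(derive_seed(seed, "finetune-head"))
    v = 0.01 * rng.standard_normal(c_out)
    b = 0.0

    def loss_of(wm, vv, bb) -> float:
        _, _, _, _, p = _final_forward(xcols, wm, layer, ho, wo, vv, bb)
        return _bce(p, y)

    losses = [loss_of(wmat, v, b)]
    lr = float(learning_rate)
    for _ in range(int(epochs)):
        z, a, pooled, r, p = _final_forward(xcols, wmat, layer, ho, wo, v, b)
        dlogit = (p - y) / B
        dv = r.T @ dlogit
        db = float(dlogit.sum())
        dr = dlogit[:, None] * v[None, :]  # (B, c_out)
        hp, wp = pooled.shape[2], pooled.shape[3]
        dpooled = np.broadcast_to(dr[:, :, None, None] / (hp * wp),
                                  pooled.shape)
        if layer.pool is not None:
            win, stride = layer.pool
            da = np.zeros_like(a)
            for i in range(hp):
                for j in range(wp):
                    tile = a[:, :, i * stride:i * stride + win,
                             j * stride:j * stride + win]
                    flat = tile.reshape(B, c_out, -1)
                    am = flat.argmax(axis=2)
                    g = np.zeros_like(flat)
                    np.put_along_axis(g, am[..., None],
                                      dpooled[:, :, i, j][..., None], axis=2)
                    da[:, :, i * stride:i * stride + win,
                       j * stride:j * stride + win] += g.reshape(tile.shape)
        else:
            da = np.array(dpooled)
        dz = da * (z > 0) if layer.apply_relu else da
        dz_flat = dz.transpose(0, 2, 3, 1).reshape(B, ho * wo, c_out)
        dwmat = np.tensordot(xcols, dz_flat, axes=([0, 1], [0, 1]))

        cur = losses[-1]
        step = lr
        for _try in range(30):
            w_new = wmat - step * dwmat
            v_new = v - step * dv
            b_new = b - step * db
            new_loss = loss_of(w_new, v_new, b_new)
            if new_loss <= cur + 1e-12:
                break
            step *= 0.5
        else:
            w_new, v_new, b_new, new_loss = wmat, v, b, cur
        wmat, v, b = w_new, v_new, b_new
        losses.append(new_loss)

    tuned = wmat.T.reshape(c_out, C, kh, kw).astype(np.float32)
    new_filters = tuple(f.copy() for f in filters[:-1]) + (tuned,)
    new_layers = net.layers[:-1] + (replace(layer, filter_source="trained"),)
    out = replace(net, layers=new_layers, filters=new_filters)
    object.__setattr__(out, "loss_history", losses)  # training diagnostic
    return out
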