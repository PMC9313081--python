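"""Particle-swarm search for compact discriminative feature subsets.

Each agent holds a continuous score vector over all bank features; the agent's
candidate subset is the top-K scores (ties broken by column index), so every
decoded subset has exactly K distinct features.  Fitness is the Fisher
distance of the held-out rows projected with a canonical model fitted on the
training rows restricted to that subset — held-out separation, not training
separation, drives the search.  Velocities follow the classic inertia-weighted
update with cognitive (personal-best) and social (global-best) pulls.

``sweep_K`` repeats the search over a range of subset sizes (default 2..20,
i.e. 19 runs) and picks the smallest K whose Fisher distance reaches the
plateau of the curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._utils import derive_seed
from .deep_features import FeatureBank
from .discriminant import DiscriminantModel, fit_canonical, project
from .errors import (ConfigurationError, DataQualityError, DegenerateClusterError,
                     ValidationError)


@dataclass(frozen=True)
class SwarmConfig:
    n_agents: int = 50
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    max_iter: int = 200
    convergence_tol: float = 1e-3
    patience: int = 10
    seed: int = 0

    def validate(self, n_features: int, K: int) -> None:
        if self.n_agents < 2:
            raise ConfigurationError(f"n_agents must be >= 2, got {self.n_agents}")
        if not (2 <= K <= n_features):
            raise ConfigurationError(
                f"K must be in [2, {n_features}], got {K}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be > 0")


@dataclass
class DRS:
    """A discovered deep radiomic signature."""

    K: int
    feature_indices: np.ndarray
    model: DiscriminantModel
    composition: dict  # net name -> fraction of selected features
    fd_curve: list  # [(K, best held-out FD), ...]
    history: list = field(default_factory=list)  # global-best FD per iteration

    def to_json(self, path: str | Path) -> None:
        doc = {
            "K": int(self.K),
            "feature_indices": np.asarray(self.feature_indices).tolist(),
            "composition": {k: float(v) for k, v in self.composition.items()},
            "fd_curve": [[int(k), float(f)] for k, f in self.fd_curve],
            "history": [float(h) for h in self.history],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def split_sources(source_ids: Sequence[str], groups: Sequence[str],
                  train_fraction: float, seed: int) -> set[str]:
    """Pick a class-stratified training subset of source oocytes.

    Per class, round(train_fraction * n_sources) sources go to training
    (always leaving at least one on each side).
    """
    import pandas as pd

    table = pd.DataFrame({"source_id": list(map(str, source_ids)),
                          "group": list(map(str, groups))})
    per_source = table.groupby("source_id")["group"].first()
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    for cls in sorted(per_source.unique()):
        ids = np.sort(per_source.index[per_source == cls].to_numpy())
        if len(ids) < 2:
            raise ValidationError(
                f"class {cls!r} has a single source oocyte; cannot split")
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.update(ids[perm[:n_train]])
    return train


def split_train_test(bank: FeatureBank, train_fraction: float = 0.8,
                     seed: int = 0,
                     rows: Sequence[int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Source-grouped, class-stratified row split of a labelled bank.

    All augmented descendants of one oocyte land on the same side, preventing
    leakage of near-duplicate images across the boundary.  ``rows`` restricts
    the split to a subset of the bank (e.g. an outer CV training fold).
    """
    meta = bank.sample_meta
    mask = meta["group"].isin(["young", "old"]).to_numpy()
    if rows is not None:
        sub = np.zeros(len(meta), dtype=bool)
        sub[np.asarray(rows, dtype=int)] = True
        mask &= sub
    src = meta["source_id"].astype(str).to_numpy()
    train_sources = split_sources(src[mask], meta["group"].to_numpy()[mask],
                                  train_fraction, seed)
    in_train = np.isin(src, list(train_sources)) & mask
    in_test = ~np.isin(src, list(train_sources)) & mask
    return np.flatnonzero(in_train), np.flatnonzero(in_test)


def _decode_topk(scores: np.ndarray, K: int) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:K])


def _fitness_fn(bank: FeatureBank, train_rows: np.ndarray,
                test_rows: np.ndarray, cache: dict):
    def fitness(subset: np.ndarray) -> tuple[float, DiscriminantModel | None]:
        key = tuple(int(i) for i in subset)
        if key in cache:
            return cache[key]
        try:
            model = fit_canonical(bank, subset, train_rows)
            _, fd = project(model, bank, test_rows, with_fd=True)
            model.fd_test = fd
            out = (fd, model)
        except DegenerateClusterError:
            out = (-np.inf, None)
        cache[key] = out
        return out

    return fitness


def swarm_select(bank: FeatureBank, K: int, config: SwarmConfig,
                 split: tuple[np.ndarray, np.ndarray],
                 init_subsets: Sequence[Sequence[int]] = ()) -> DRS:
    """Run one particle-swarm search at fixed subset size K.

    ``init_subsets`` warm-starts up to that many agents: their score vectors
    put the given features on top, so the K sweep can nest each run in the
    previous optimum (a subset of size K-1 plus one free slot).
    """
    n_f = bank.n_features
    config.validate(n_f, K)
    train_rows, test_rows = split
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    fitness = _fitness_fn(bank, np.asarray(train_rows), np.asarray(test_rows),
                          cache)

    pos = rng.uniform(0.0, 1.0, size=(config.n_agents, n_f))
    for a, sub in enumerate(init_subsets[:config.n_agents]):
        pos[a] *= 0.5
        pos[a, np.asarray(sub, dtype=int)] = 1.0 + rng.uniform(
            0.0, 0.1, size=len(sub))
    vel = np.zeros_like(pos)
    pbest_pos = pos.copy()
    pbest_fit = np.full(config.n_agents, -np.inf)
    pbest_sub = [None] * config.n_agents
    for i in range(config.n_agents):
        sub = _decode_topk(pos[i], K)
        f, _ = fitness(sub)
        pbest_fit[i] = f
        pbest_sub[i] = sub
    if not np.isfinite(pbest_fit).any():
        raise DataQualityError(
            "every initial agent produced a degenerate Fisher distance")
    g = int(np.argmax(pbest_fit))
    gbest_fit = float(pbest_fit[g])
    gbest_pos = pbest_pos[g].copy()
    gbest_sub = pbest_sub[g]
    history = [gbest_fit]

    still = 0
    for _ in range(config.max_iter):
        r1 = rng.uniform(size=pos.shape)
        r2 = rng.uniform(size=pos.shape)
        vel = (config.inertia * vel
               + config.c1 * r1 * (pbest_pos - pos)
               + config.c2 * r2 * (gbest_pos[None, :] - pos))
        pos = pos + vel
        prev = gbest_fit
        for i in range(config.n_agents):
            sub = _decode_topk(pos[i], K)
            f, _ = fitness(sub)
            if f > pbest_fit[i]:
                pbest_fit[i] = f
                pbest_pos[i] = pos[i]
                pbest_sub[i] = sub
                if f > gbest_fit:
                    gbest_fit = float(f)
                    gbest_pos = pos[i].copy()
                    gbest_sub = sub
        history.append(gbest_fit)
        rel = (gbest_fit - prev) / max(abs(prev), 1e-12)
        still = still + 1 if rel < config.convergence_tol else 0
        if still >= config.patience:
            break

    _, model = fitness(gbest_sub)
    return DRS(K=K, feature_indices=np.asarray(gbest_sub, dtype=int),
               model=model, composition=composition_of(bank, gbest_sub),
               fd_curve=[(K, gbest_fit)], history=history)


def composition_of(bank: FeatureBank, subset: Sequence[int]) -> dict:
    """Fraction of selected features contributed by each source net."""
    nets = bank.feature_provenance["net"].to_numpy()
    sel = nets[np.asarray(subset, dtype=int)]
    total = len(sel)
    return {net: float((sel == net).sum()) / total
            for net in pd_unique_sorted(nets)}


def pd_unique_sorted(arr: np.ndarray) -> list:
    return sorted(set(arr.tolist()))


def sweep_K(bank: FeatureBank, K_range: Sequence[int] | None = None,
            config: SwarmConfig | None = None,
            split: tuple[np.ndarray, np.ndarray] | None = None,
            plateau_delta: float = 0.05) -> DRS:
    """Sweep subset sizes, keeping the smallest K on the FD plateau.

    One swarm run per K (seeded independently from the base seed); the
    selected K* is the smallest K whose held-out FD is within
    ``plateau_delta`` (relative) of the curve maximum.
    """
    if config is None:
        config = SwarmConfig()
    if K_range is None:
        K_range = range(2, 21)
    K_list = [int(k) for k in K_range]
    if len(K_list) == 0:
        raise ConfigurationError("K_range must be non-empty")
    if split is None:
        split = split_train_test(bank, 0.8, seed=config.seed)
    runs: list[DRS] = []
    prev_best: list[Sequence[int]] = []
    for K in K_list:
        cfg = SwarmConfig(**{**config.__dict__,
                             "seed": derive_seed(config.seed, "sweep", K)})
        run = swarm_select(bank, K, cfg, split, init_subsets=prev_best)
        runs.append(run)
        prev_best = [run.feature_indices]
    curve = [(r.K, r.fd_curve[0][1]) for r in runs]
    fds = np.array([f for _, f in curve])
    best = fds.max()
    ok = np.flatnonzero(fds >= (1.0 - plateau_delta) * best)
    star = int(ok[0])
    chosen = runs[star]
    return DRS(K=chosen.K, feature_indices=chosen.feature_indices,
               model=chosen.model, composition=chosen.composition,
               fd_curve=curve, history=chosen.history)
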