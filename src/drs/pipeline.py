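"""End-to-end orchestration: simulate -> crop -> augment -> extract ->
discover -> evaluate -> assess, with full provenance.

A single global seed fans out deterministically to per-stage seeds (via CRC32
labelled derivation, see :mod:`drs._utils`), so re-running an identical config
reproduces every serialized number bit-exactly while keeping stage streams
independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import classify, deep_features, discriminant, imaging, swarm, treatment
from ._utils import derive_seed
from .errors import ConfigurationError
from .synthetic_oocytes import CohortSpec, generate_cohort, write_cohort

log = logging.getLogger("drs")

REQUIRED_SECTIONS = ("cohort", "transforms", "nets", "swarm", "classifier",
                     "treatment")


def default_config() -> dict:
    """The desk-scale default configuration (study cohort sizes, 256-px frames)."""
    return {
        "seed": 0,
        "cohort": {"n_young": 26, "n_old": 21, "n_treated": 29,
                   "p_young_in_treated": 0.6, "effect_size": 1.0,
                   "image_side": 256},
        "crop": {"pad": 4, "side": 128},
        "transforms": [[False, 0], [False, 45], [False, 90],
                       [True, 0], [True, 45], [True, 90]],
        "nets": {"finetune": True, "finetune_epochs": 4, "finetune_lr": 0.05,
                 "finetune_max_samples": 240},
        "swarm": {"n_agents": 50, "k_min": 2, "k_max": 20, "max_iter": 200,
                  "convergence_tol": 1e-3, "patience": 10,
                  "train_fraction": 0.8, "plateau_delta": 0.05},
        "classifier": {"folds": 10, "inner_folds": 3, "bootstrap_n": 1000,
                       "C_grid": [0.01, 0.1, 1.0, 10.0, 100.0],
                       "reselect": True},
        "treatment": {"chi2_level": 0.95},
        "io": {"save_bank": True, "plots": True},
    }


@dataclass
class PipelineConfig:
    """Validated nested configuration; see :func:`default_config` for keys."""

    raw: dict

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        for section in REQUIRED_SECTIONS:
            if section not in doc:
                raise ConfigurationError(f"missing config section: {section!r}")
        merged = default_config()
        for key, val in doc.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key] = {**merged[key], **val}
            else:
                merged[key] = val
        CohortSpec(**{**merged["cohort"], "seed": 0}).validate()
        return cls(raw=merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def __getitem__(self, key):
        return self.raw[key]


def make_reselector(bank, K: int, swarm_cfg: swarm.SwarmConfig,
                    train_fraction: float, seed: int):
    """Per-fold signature re-discovery for selection-clean nested CV.

    Returns a callable mapping an outer-training row set to the feature subset
    found by a swarm run confined to those rows (with its own inner 80/20
    source split), so held-out folds never influence feature selection.
    """
    def selector(train_rows: np.ndarray) -> np.ndarray:
        tag = int(np.sum(train_rows) % (2**20))
        s = derive_seed(seed, "reselect", len(train_rows), tag)
        split = swarm.split_train_test(bank, train_fraction, seed=s,
                                       rows=train_rows)
        cfg = swarm.SwarmConfig(**{**swarm_cfg.__dict__, "seed": s})
        return swarm.swarm_select(bank, K, cfg, split).feature_indices

    return selector


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: dict | PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.raw
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seed = int(cfg["seed"])

    try:
        _stage("simulate")
        spec = CohortSpec(**{**cfg["cohort"], "seed": derive_seed(seed, "simulate")})
        oocytes = generate_cohort(spec)
        manifest = write_cohort(oocytes, outdir / "data", seed=spec.seed)

        _stage("load+crop")
        crop_cfg = cfg.get("crop", {"pad": 4, "side": 128})
        images = imaging.load_cohort(manifest)
        images = [imaging.resize_to(imaging.crop_to_oocyte(im, crop_cfg["pad"]),
                                    crop_cfg["side"]) for im in images]
        labelled = [im for im in images if im.group in ("young", "old")]
        treated = [im for im in images if im.group == "treated"]

        _stage("augment")
        tset = imaging.TransformSet(tuple((bool(m), float(a))
                                          for m, a in cfg["transforms"]))
        augmented = imaging.augment(labelled, tset)

        _stage("split+finetune")
        sw = cfg["swarm"]
        split_seed = derive_seed(seed, "split")
        train_sources = swarm.split_sources(
            [im.source_id for im in labelled], [im.group for im in labelled],
            sw["train_fraction"], split_seed)
        nets = list(deep_features.default_nets())
        extract_seed = derive_seed(seed, "extract")
        nc = cfg["nets"]
        if nc.get("finetune", True):
            train_imgs = [im for im in augmented if im.source_id in train_sources]
            nets[-1] = deep_features.finetune_final_layer(
                nets[-1], train_imgs, [im.group for im in train_imgs],
                epochs=nc.get("finetune_epochs", 4),
                learning_rate=nc.get("finetune_lr", 0.05),
                seed=extract_seed,
                max_samples=nc.get("finetune_max_samples", 240))

        _stage("extract")
        bank = deep_features.extract_features(augmented, nets, seed=extract_seed)
        if cfg.get("io", {}).get("save_bank", True):
            bank.save(outdir / "bank")
        bank_treated = None
        if treated:
            bank_treated = deep_features.extract_features(treated, nets,
                                                          seed=extract_seed)
            if cfg.get("io", {}).get("save_bank", True):
                bank_treated.save(outdir / "bank_treated")

        _stage("discover")
        split = swarm.split_train_test(bank, sw["train_fraction"],
                                       seed=split_seed)
        swarm_cfg = swarm.SwarmConfig(
            n_agents=sw["n_agents"], max_iter=sw["max_iter"],
            convergence_tol=sw["convergence_tol"], patience=sw["patience"],
            seed=derive_seed(seed, "swarm"))
        drs_sig = swarm.sweep_K(bank, range(sw["k_min"], sw["k_max"] + 1),
                                swarm_cfg, split,
                                plateau_delta=sw["plateau_delta"])
        drs_sig.to_json(outdir / "drs.json")
        drs_sig.model.to_json(outdir / "discriminant.json")

        _stage("evaluate")
        cc = cfg["classifier"]
        selector = None
        if cc.get("reselect", True):
            selector = make_reselector(bank, drs_sig.K, swarm_cfg,
                                       sw["train_fraction"],
                                       derive_seed(seed, "evaluate"))
        report = classify.nested_cv_evaluate(
            bank, drs_sig, folds=cc["folds"], C_grid=tuple(cc["C_grid"]),
            bootstrap_n=cc["bootstrap_n"], seed=derive_seed(seed, "cv"),
            selector=selector, inner_folds=cc.get("inner_folds", 3))
        report.to_json(outdir / "evaluation.json")
        if report.per_oocyte is not None:
            report.per_oocyte.to_csv(outdir / "per_oocyte_predictions.tsv",
                                     sep="\t", index=False)

        _stage("assess")
        treat_report = None
        if bank_treated is not None:
            all_rows = np.concatenate(split)
            C_final = (max(set(report.chosen_C), key=report.chosen_C.count)
                       if report.chosen_C else 1.0)
            model = classify.train_svm(bank, drs_sig, all_rows, C=C_final)
            stats = treatment.cluster_statistics(drs_sig.model, bank, split[0])
            treat_report = treatment.assess_treated(
                bank_treated, drs_sig, model, stats["young"], stats["old"],
                chi2_level=cfg["treatment"]["chi2_level"])
            treat_report.to_json(outdir / "treatment.json")
            model.to_json(outdir / "classifier.json")

        if cfg.get("io", {}).get("plots", True):
            _stage("plots")
            _make_plots(outdir, bank, drs_sig, split, report, bank_treated,
                        treat_report)

        provenance = {"config": cfg, "derived_seeds": {
            name: derive_seed(seed, name) for name in
            ("simulate", "split", "extract", "swarm", "evaluate", "cv")},
            "n_features": int(bank.n_features),
            "n_samples": int(bank.n_samples)}
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        return outdir
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _make_plots(outdir: Path, bank, drs_sig, split, report, bank_treated,
                treat_report) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    ks = [k for k, _ in drs_sig.fd_curve]
    fds = [f for _, f in drs_sig.fd_curve]
    axes[0].plot(ks, fds, "o-")
    axes[0].axvline(drs_sig.K, ls="--", c="gray")
    axes[0].set_xlabel("number of signature features K")
    axes[0].set_ylabel("held-out Fisher distance")

    pts, _ = discriminant.project(drs_sig.model, bank, split[0], with_fd=True)
    groups = bank.sample_meta["group"].to_numpy()[split[0]]
    for cls, color, marker in (("young", "tab:red", "s"),
                               ("old", "tab:blue", "o")):
        sel = groups == cls
        axes[1].scatter(pts[sel, 0], pts[sel, 1], c=color, marker=marker,
                        s=18, alpha=0.7, label=cls)
    if treat_report is not None and treat_report.n_treated:
        axes[1].scatter(treat_report.per_oocyte["canonical_1"],
                        treat_report.per_oocyte["canonical_2"],
                        c="k", marker="x", s=30, label="treated")
    axes[1].legend()
    axes[1].set_xlabel("canonical variable 1")
    axes[1].set_ylabel("canonical variable 2")

    axes[2].plot(report.roc_points[:, 0], report.roc_points[:, 1], "-")
    axes[2].plot([0, 1], [0, 1], ":", c="gray")
    axes[2].set_xlabel("false positive rate")
    axes[2].set_ylabel("true positive rate")
    axes[2].set_title(f"AUC = {report.auc:.3f}")
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=120)
    plt.close(fig)
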