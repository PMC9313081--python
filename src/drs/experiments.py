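"""Reference experiments: recovery, oracle-equivalence, and sweep studies.

These drivers run the pipeline on synthetic cohorts at fixed study
conditions and return the headline numbers (cross-validated accuracy, AUC,
treated-cohort proportions, swarm-vs-exhaustive agreement).  They are used by
the test suite and the reproduction script; every internal seed derives from
the single ``seed`` argument.

Problem sizes here are desk-scale choices: 128-px crops, a 60-iteration swarm
budget (the patience rule usually converges well before), and study-sized or
moderately enlarged cohorts.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from . import classify, deep_features, imaging, swarm, treatment
from ._utils import derive_seed
from .discriminant import fit_canonical, project
from .pipeline import make_reselector
from .synthetic_oocytes import CohortSpec, generate_cohort

STRONG_EFFECT = 2.0  # separation regime where morphology axes clearly differ


def build_cohort_bank(n_young: int, n_old: int, n_treated: int,
                      effect_size: float, seed: int, p_young: float = 0.6,
                      image_side: int = 256, crop_side: int = 128,
                      finetune: bool = True):
    """Simulate, crop, augment, fine-tune, and extract feature banks.

    Returns ``(bank, bank_treated_or_None, split)`` where the split is the
    80/20 source-grouped discovery partition.
    """
    spec = CohortSpec(n_young=n_young, n_old=n_old, n_treated=n_treated,
                      p_young_in_treated=p_young, effect_size=effect_size,
                      image_side=image_side, seed=derive_seed(seed, "simulate"))
    oocytes = generate_cohort(spec)
    images = [imaging.resize_to(imaging.crop_to_oocyte(im, 4), crop_side)
              for im in imaging.from_synthetic(oocytes)]
    labelled = [im for im in images if im.group in ("young", "old")]
    treated = [im for im in images if im.group == "treated"]
    augmented = imaging.augment(labelled)

    split_seed = derive_seed(seed, "split")
    train_sources = swarm.split_sources([im.source_id for im in labelled],
                                        [im.group for im in labelled],
                                        0.8, split_seed)
    nets = list(deep_features.default_nets())
    extract_seed = derive_seed(seed, "extract")
    if finetune:
        train_imgs = [im for im in augmented if im.source_id in train_sources]
        nets[-1] = deep_features.finetune_final_layer(
            nets[-1], train_imgs, [im.group for im in train_imgs],
            epochs=4, learning_rate=0.05, seed=extract_seed, max_samples=240)
    bank = deep_features.extract_features(augmented, nets, seed=extract_seed)
    bank_treated = (deep_features.extract_features(treated, nets,
                                                   seed=extract_seed)
                    if treated else None)
    split = swarm.split_train_test(bank, 0.8, seed=split_seed)
    return bank, bank_treated, split


def age_recovery_experiment(n_per_class: int = 50, effect_size: float = STRONG_EFFECT,
                            n_treated: int = 0, p_young: float = 0.6,
                            seed: int = 1, k_range=range(2, 21),
                            max_iter: int = 60, folds: int = 10,
                            bootstrap_n: int = 1000) -> dict:
    """Full discovery + grouped nested-CV evaluation (+ optional treatment).

    Feature selection is re-run inside every outer CV fold, so the reported
    accuracy/AUC are free of selection bias — this is what makes the null
    (effect_size = 0) case honest.
    """
    bank, bank_treated, split = build_cohort_bank(
        n_per_class, n_per_class, n_treated, effect_size, seed,
        p_young=p_young)
    swarm_cfg = swarm.SwarmConfig(max_iter=max_iter,
                                  seed=derive_seed(seed, "swarm"))
    sig = swarm.sweep_K(bank, k_range, swarm_cfg, split)
    selector = make_reselector(bank, sig.K, swarm_cfg, 0.8,
                               derive_seed(seed, "evaluate"))
    report = classify.nested_cv_evaluate(
        bank, sig, folds=folds, bootstrap_n=bootstrap_n,
        seed=derive_seed(seed, "cv"), selector=selector)
    out = {
        "K": sig.K,
        "n_swarm_runs": len(sig.fd_curve),
        "fd_curve": sig.fd_curve,
        "composition": sig.composition,
        "accuracy_pct": report.accuracy_mean,
        "accuracy_sd_pct": report.accuracy_sd,
        "auc": report.auc,
        "per_copy_accuracy_pct": report.per_copy_accuracy,
    }
    if bank_treated is not None:
        rows = np.concatenate(split)
        C_final = (max(set(report.chosen_C), key=report.chosen_C.count)
                   if report.chosen_C else 1.0)
        model = classify.train_svm(bank, sig, rows, C=C_final)
        stats = treatment.cluster_statistics(sig.model, bank, split[0])
        tr = treatment.assess_treated(bank_treated, sig, model,
                                      stats["young"], stats["old"])
        out["treated_young_fraction"] = tr.proportions_class.get("young", 0.0)
        out["treated_proximity"] = tr.proportions_proximity
        out["n_treated"] = tr.n_treated
    return out


def _gaussian_bank(n_sources: int, n_features: int, n_informative: int,
                   separation: float, seed: int):
    """Direct Gaussian feature bank (no imaging), for search benchmarks."""
    import pandas as pd

    from .deep_features import FeatureBank

    rng = np.random.default_rng(seed)
    values, rows = [], []
    for cls, prefix, shift in (("young", "Y", separation / 2),
                               ("old", "O", -separation / 2)):
        for i in range(n_sources):
            x = rng.standard_normal(n_features)
            x[:n_informative] += shift
            values.append(x)
            rows.append({"source_id": f"{prefix}{i:03d}", "group": cls,
                         "transform_tag": "original",
                         "latent_age": f"{cls}-like"})
    nets = ("net1-verydeep", "net2-deep", "net3-moderate")
    prov = pd.DataFrame({"net": [nets[j % 3] for j in range(n_features)],
                         "layer": 1, "channel": np.arange(n_features)})
    return FeatureBank(values=np.asarray(values), feature_provenance=prov,
                       sample_meta=pd.DataFrame(rows))


def oracle_agreement_experiment(n_replicates: int = 20, n_features: int = 10,
                                K: int = 2, seed: int = 1) -> dict:
    """Swarm search vs exhaustive enumeration on small banks.

    For each replicate, a fresh Gaussian bank is drawn and both the swarm and
    a brute-force scan over all C(n_features, K) subsets maximize the held-out
    Fisher distance.  Returns the match rate and whether the swarm ever
    exceeded the enumerated maximum (it cannot, by construction).
    """
    matches = 0
    exceeded = False
    for rep in range(n_replicates):
        rep_seed = derive_seed(seed, "oracle", rep)
        bank = _gaussian_bank(20, n_features, 2, 2.0, rep_seed)
        split = swarm.split_train_test(bank, 0.8, seed=rep_seed)
        train, test = split
        best = -np.inf
        for sub in combinations(range(n_features), K):
            try:
                model = fit_canonical(bank, list(sub), train)
                _, fd = project(model, bank, test, with_fd=True)
            except Exception:
                continue
            best = max(best, fd)
        cfg = swarm.SwarmConfig(n_agents=50, max_iter=200, seed=rep_seed)
        got = swarm_fd = swarm.swarm_select(bank, K, cfg, split).fd_curve[0][1]
        if got > best + 1e-9:
            exceeded = True
        if abs(got - best) <= 1e-9 * max(abs(best), 1.0):
            matches += 1
    return {"match_rate": matches / n_replicates, "exceeded_oracle": exceeded,
            "n_replicates": n_replicates}


def fd_sweep_experiment(seed: int = 1, k_range=range(2, 21)) -> dict:
    """K sweep on a separable Gaussian bank: the FD-vs-K curve study.

    Every feature carries the same modest class shift, and the held-out set is
    large (240 sources), so the best achievable held-out FD grows steadily
    with K and the winner's-curse noise of maximizing over subsets stays small
    relative to that growth.
    """
    bank = _gaussian_bank(n_sources=600, n_features=22, n_informative=22,
                          separation=0.5, seed=derive_seed(seed, "sweepbank"))
    split = swarm.split_train_test(bank, 0.8, seed=derive_seed(seed, "sweepsplit"))
    cfg = swarm.SwarmConfig(max_iter=100, seed=derive_seed(seed, "sweeprun"))
    sig = swarm.sweep_K(bank, k_range, cfg, split)
    return {"fd_curve": sig.fd_curve, "n_swarm_runs": len(sig.fd_curve),
            "K_selected": sig.K}
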