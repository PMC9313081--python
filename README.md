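# drs — deep radiomic signatures for oocyte brightfield morphology

Oocyte quality declines with maternal age, but the morphological changes are
too subtle for embryologists to score reliably by eye. `drs` implements a
pipeline that quantifies those changes from plain brightfield microscopy:
it extracts a large bank of convolutional image features from segmented
oocyte images, searches for a compact *deep radiomic signature* (DRS) — a
small feature subset that best separates young from old oocytes — and uses
that signature to classify oocyte age and to assess whether a treated cohort
(e.g. oocytes from NAD⁺-precursor–treated aged animals) has shifted back
toward young-like morphology.

Because the original mouse images are not publicly deposited, the package
ships a first-class synthetic cohort generator that emulates the study
design: three cohorts (young, old, treated), class-dependent morphology
(cytoplasmic texture granularity, zona pellucida thickness, perivitelline
gap, ellipticity) with a single effect-size dial, and a latent young-like
mixture fraction in the treated group.

## Method

1. **Augmentation.** Each segmented oocyte crop is expanded by the transform
   set {identity, mirror} × {0°, 45°, 90°} (6-fold), so 21 old and 26 young
   oocytes become 126 and 156 records.
2. **Feature bank.** Three convolutional stacks of different depth
   (extremely deep / deep / moderately deep; 8, 4, and 2 layers of
   convolution → ReLU → 3×3 max-pooling with seeded variance-scaled filters,
   final layer of the shallowest net fine-tuned on labelled oocytes) are
   reduced by global average pooling to a bank of N_f = 5984 features.
3. **Signature discovery.** For a subset S of K features, a 2-D canonical
   space is fitted on training sources: axis 1 is the ridge-regularized
   Fisher direction (S_W + λI)⁻¹(m₁ − m₂); axis 2 is the dominant
   within-class residual direction orthogonal to it. Separation is measured
   by the Fisher distance FD = tr(S_B)/tr(S_W) of the projected points. A
   particle swarm (50 agents, continuous scores decoded to top-K subsets)
   maximizes FD on *held-out* sources; the subset size K is swept from 2 to
   20 (19 runs) and the smallest K on the FD plateau is kept.
4. **Classification.** A linear SVM on the standardized signature features
   is evaluated by source-grouped, stratified 10-fold nested cross-validation
   (inner folds select the margin penalty C; optionally the signature itself
   is re-discovered inside each outer fold, which keeps the estimate free of
   selection bias). Accuracy is reported per oocyte (majority vote over
   augmented copies) as mean ± bootstrap sd, with a trapezoidal ROC/AUC.
5. **Treatment assessment.** Treated oocytes (never used in discovery or
   training) are projected into the learned plane and classified; proximity
   to the young cluster is categorized by the 95% chi-square (2 df)
   Mahalanobis ellipse (within-young / near-young / old-like).

## Worked example

```python
import json
from drs.pipeline import default_config, run_pipeline

doc = default_config()
doc["seed"] = 11
doc["cohort"] = {"n_young": 8, "n_old": 8, "n_treated": 12,
                 "p_young_in_treated": 0.6, "effect_size": 2.0,
                 "image_side": 256}
doc["swarm"] = {**doc["swarm"], "k_min": 2, "k_max": 6, "max_iter": 30}
doc["classifier"] = {**doc["classifier"], "folds": 4, "bootstrap_n": 500}
out = run_pipeline(doc, "runs/example")
ev = json.loads((out / "evaluation.json").read_text())
print(ev["accuracy_mean_pct"], ev["auc"])
```

This run (about a minute on one CPU) prints, via the serialized reports:

```
selected K: 6
composition: {'net1-verydeep': 0.5, 'net2-deep': 0.5, 'net3-moderate': 0.0}
accuracy: 93.8 +/- 5.8 %
AUC: 1.0
treated class proportions: {'old': 0.583, 'young': 0.417}
treated proximity: {'within-young': 0.25, 'near-young': 0.083, 'old-like': 0.667}
```

Reading: a 6-feature signature separates the two age classes almost
perfectly (one of 16 oocytes misclassified across outer folds; AUC 1.0 on
per-oocyte decision values). Of the 12 treated oocytes, 41.7% are classified
young — consistent with the generator's latent 60% young-like fraction at
this small cohort size (7.2 ± 1.7 expected). Larger cohorts (see below)
recover the fraction tightly. The run directory also contains the FD-vs-K
curve, the 2-D canonical scatter with the treated overlay, and the ROC curve
(`summary.png`).

The same pipeline is scriptable from the shell:

```bash
drs run-all --out runs/example --seed 11
drs simulate --out runs/sim --seed 1      # images + masks + manifest only
```

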