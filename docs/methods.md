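# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohorts

Each oocyte is rendered as concentric ellipses on a bright background
(brightfield plateaus: background 0.82, cytoplasm 0.50, perivitelline
annulus 0.78, zona ring 0.62, on a [0, 1] scale): a cytoplasm disk carrying
a stationary correlated texture, a perivitelline gap, and a zona pellucida
ring whose outer boundary defines the mask. The texture is a Gaussian random
field — white noise low-pass filtered at one correlation length — and sensor
noise is additive Gaussian (cooled-camera regime). Per-oocyte variability:
radius jitter (4% of the mean), random orientation, and ±3 px center jitter.

Class differences are simultaneous shifts of four axes embryologists score,
scaled by one `effect_size` dial e (young gets `+`, old `−`, half-differences
at e = 1 in parentheses): texture correlation length (−1.5 px; young finer),
zona thickness (+1.5 px), perivitelline gap (−1.0 px; young smaller), and
ellipticity (−0.04; young rounder). At e = 0 the classes are identically
distributed by construction. The directions are choices, not biological
claims: the source study states the groups were not visually distinct and
never quantifies which axes move. `effect_size = 2` is the "strong" regime
used in the recovery experiments; defaults are e = 1, 256-px frames, cohort
sizes 26/21/29 (young/old/treated), and a latent 60% young-like fraction in
the treated group.

What the generator does **not** emulate: optics (point-spread function,
depth of field), polar bodies and fragmentation, debris, illumination
gradients, or 3-D structure. Passing tests therefore demonstrate that the
pipeline recovers *planted* morphological signal at realistic sample sizes
and noise — not that it would find age signal in real images.

## Augmentation

The reported 6-fold expansion (21→126, 26→156) pins the transform count but
not the exact inventory; the default set {identity, mirror} × {0°, 45°, 90°}
satisfies it and is configurable. Multiples of 90° are applied as lossless
array rotations; 45° uses bilinear interpolation with zero fill (inert,
since cropping already zeroes the background; masks rotate
nearest-neighbour). Coordinates are row-major, origin top-left, rotations
counter-clockwise, mirror before rotation.

## Feature bank

Three stacks stand in for transferred pretrained nets at desk scale,
preserving the extremely-deep / deep / moderately-deep ordering: 8, 4, and 2
layers of valid (unpadded) convolution → ReLU → non-overlapping 3×3
max-pooling, with He-scaled seeded random filters. Readout is global average
pooling of the final stack, giving widths 4096 + 1792 + 96 = 5984 features
(the ~6000 regime). Inputs are resampled per net (128/128/64 px). The final
96-filter 3×3 layer of the shallowest net is fine-tuned on labelled training
oocytes through a temporary two-class logistic head by full-batch gradient
descent with step halving (so the loss is non-increasing by construction);
the head is then discarded and earlier layers are bit-exactly frozen.

Global-average readouts are exactly invariant to square-symmetry transforms
of the input only when the kernels are themselves dihedrally symmetric and
pooling tiles align with the image; for generic filters, correlation does
not commute with rotation, so the invariance is approximate at best. The
property test uses symmetrized kernels; orientation robustness for the real
bank comes from augmentation, not from the readout.

## Canonical space and Fisher distance

With two classes the between-scatter has rank one, so a second canonical
axis is not defined by the classical eigenproblem. Axis 1 is the
ridge-regularized Fisher direction (S_W + λI)⁻¹(m₁ − m₂) of standardized
(train-split statistics) selected features; axis 2 is the leading principal
axis of the pooled within-class covariance restricted to axis 1's orthogonal
complement — all discrimination lives on axis 1, axis 2 provides the 2-D
scatter. λ defaults to 10⁻³ × mean diag(S_W) with a 10⁻⁸ floor (random
subsets can consist entirely of dead-ReLU constant columns, making S_W
exactly zero). The Fisher distance is tr(S_B)/tr(S_W) of the projected 2-D
points; any constant convention cancels because all comparisons share it.

## Swarm search

Agents are continuous score vectors over all N_f features, decoded to the
top-K scores (stable ties by column index), so subsets always have exactly
K members. Velocities follow the inertia-weighted rule (inertia 0.7,
cognitive = social = 1.5, 50 agents, ≤200 iterations, stop after 10
consecutive iterations with relative global-best improvement below 10⁻³).
Fitness is the Fisher distance of *held-out* rows under the model fitted on
training rows; the split is by source oocyte (all augmented copies on one
side), stratified by class, fixed once per run. Fitness values are cached by
subset, and the K sweep warm-starts each run with the previous K's optimum
(larger subsets nest smaller ones), which stabilizes the FD-vs-K curve. K*
is the smallest K whose FD reaches 95% of the curve maximum
(`plateau_delta = 0.05`).

Because fitness *is* the held-out FD, the reported curve is a maximum of
noisy estimates; its winner's-curse inflation varies with C(N_f, K). The
curve-monotonicity experiment therefore uses a bank with a large held-out
set (240 sources) and uniform per-feature signal, where the inflation is
small relative to signal growth.

## Classification and evaluation

A linear SVM (scikit-learn `SVC`, linear kernel) operates on the K
standardized raw signature features — the 2-D projection is for FD and
visualization only. Evaluation is source-grouped stratified 10-fold nested
CV: inner 3-fold grouped CV selects C from {0.01, 0.1, 1, 10, 100} (ties to
the smaller C); predictions are pooled over outer folds. Headline accuracy
is per-oocyte (majority vote over augmented copies; mean decision value for
the ROC), reported as mean ± sd over 1000 bootstrap resamples of the
per-oocyte predictions, with per-copy metrics logged alongside.

By default the pipeline re-runs the swarm selection inside every outer
training fold (`selector` argument of `nested_cv_evaluate`). Selecting ~15
of ~6000 features on all data and cross-validating afterwards is a classic
source of optimism — on pure noise it can produce apparently high accuracy —
whereas the selection-clean estimate stays at chance (AUC ≈ 0.44 at zero
effect in the acceptance run). The fixed-signature evaluation remains
available (`selector=None`) for comparison with the within-sample protocol.

## Treatment assessment

Treated oocytes are assessed one record per cell (no augmentation at
inference), must be source-disjoint from training (enforced), and never
mutate fitted objects. Cluster statistics (centroid + 2×2 covariance) come
from the discovery training split's projected points. The verbal
tripartition "exactly correlated / very close / retained old morphology" is
quantified as: within-young if squared Mahalanobis distance to the young
centroid ≤ the 95th-percentile chi-square with 2 df (≈5.99); else near-young
if strictly closer (Mahalanobis) to young than old; else old-like. The
level is configurable and the rule is recorded in the report metadata as a
reconstruction.

## Problem sizes and determinism

Experiments run at desk scale: 256-px synthetic frames cropped to 128-px
net inputs, 50 sources per class for recovery runs (600 augmented records),
a 60-iteration swarm budget in the experiment drivers (patience usually
stops earlier), and 20 replicates for the swarm-vs-exhaustive benchmark
(N_f = 10, K = 2, oracle = enumeration of all 45 subsets). One global seed
fans out to per-stage seeds via CRC32-labelled `SeedSequence` derivation, so
identical configurations reproduce every serialized number bit-exactly.

## Known limitations

- The feature bank uses seeded random filters, not genuinely pretrained
  weights; it preserves the architecture's structure, not transfer learning
  itself.
- The synthetic morphology axes and their directions are assumptions; real
  age effects may live in features the generator cannot express.
- Two-class only; the canonical construction and the SVM head do not extend
  to >2 groups as written.
- The FD-vs-K curve is only approximately monotone in regimes with small
  held-out sets; with few test sources its maximum-of-noise character
  dominates.
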