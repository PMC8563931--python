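# Methods

## The pipeline

`histossl` models a whole-slide image (WSI) as a grid of 300×300-pixel patch
positions. Patch-level classification is learned either fully supervised
(SL) or semi-supervised (SSL) with the mean-teacher scheme; patch
probabilities are then aggregated to slide decisions by a connected-cluster
rule and to patient decisions by positive sensitivity.

### Mean-teacher training

Two networks of identical architecture are kept: a *student* trained by
Adam, and a *teacher* initialised as an exact copy of the student and
updated once per epoch as an exponential moving average,
θ_t ← α·θ_t + (1−α)·θ_s. Each mini-batch preserves the labelled:unlabelled
proportion of the training pools (with at least one labelled sample). The
training loss is the sum of

- **classification cost** — softmax cross-entropy on the labelled part,
- **consistency cost** — mean squared error between the student's predicted
  probability vectors and the teacher's pseudo-label probabilities on the
  unlabelled part, averaged over samples *and* classes; no gradient flows
  through the teacher,
- an **L2 penalty** λ·Σw² over weight matrices (biases excluded).

One-tenth of the labelled patches (stratified by class) is held out as a
validation set. Early stopping fires after `early_stop_patience` epochs
without a strict validation-accuracy improvement (tolerance 1e-6), but never
during the first `pretrain_epochs` epochs; the weights with the best
validation accuracy are restored at exit. Because plain accuracy is
threshold-blind and can sit at the majority-class fraction for many epochs
while ranking quality improves, accuracy *ties* also refresh the snapshot —
so a flat plateau restores the most-trained tied weights rather than the
epoch-0 ones. The teacher (SSL) or student (SL) is both the early-stopping
monitor and the returned model.

Pseudo labels are the teacher's soft probability vectors by default;
`hard_pseudo_labels` switches to one-hot argmax. Student and teacher see the
same augmented view of each unlabelled patch by default; `dual_views` draws
independent views (the original mean-teacher recipe). Consistency applies to
unlabelled samples only. No consistency ramp-up is used. EMA cadence is per
epoch; all of these are configuration flags, not code branches.

### Defaults (the published operating point)

| parameter | default | meaning |
|---|---|---|
| `batch_size` | 128 (SSL) / 64 (SL) | mini-batch size |
| `ema_alpha` | 0.95 | per-epoch teacher smoothing |
| `learning_rate` | 1e-3 | Adam; SL adds per-epoch exponential decay 0.99 |
| `epochs` × `steps_per_epoch` | 500 × 100 | full-scale training length |
| `early_stop_patience` | 80 (SSL) / 50 (SL) | epochs without improvement |
| `pretrain_epochs` | 50 (SSL) / 0 (SL) | early stopping disabled initially |
| `l2_coefficient` | 1e-4 | weight penalty |
| `validation_fraction` | 0.1 | labelled hold-out share |

Desk-scale runs in the tests and acceptance script shrink only the sizes —
100 epochs of 8 steps — chosen so the per-epoch EMA actually converges
(0.95^100 ≈ 0.006 residual weight on the random initialisation), and they
set patience equal to the epoch count because one-tenth of ~150 labels is
too small a validation set to carry a stopping signal.

### Backbones

The trainer is backbone-agnostic; architectures are injected via
`BackboneSpec` and built in the bundled numpy network module (dense and
valid-padding conv layers, manual backprop, Adam). Shipped specs:

- `mlp` — flatten → dense(48) → ReLU → dense(n_classes), on 16×16×3 inputs;
  the default experimental backbone (~37k parameters),
- `tiny_cnn` — two stride-2 3×3 convolutions → global average pooling →
  dense; used by the learnability check,
- `logistic` — a linear readout, for convex toy analyses.

The replicate comparison uses `mlp` deliberately: the convolutional
backbone's spatial-averaging inductive bias solves the synthetic
density-texture task from ~150 labels, saturating the supervised baseline
(patch AUC ≈ 0.99) and leaving the SSL-vs-SL comparison uninformative. The
dense backbone is the model class that is genuinely label-limited at desk
scale, which is the regime the comparison is about. Full-scale ImageNet-class
backbones are outside desk scale and not bundled.

### Preprocessing

Patches are 8-bit RGB. A patch is *background* when the fraction of pixels
whose darkest channel exceeds 220 is above 0.8; background patches are
removed before training, and background-removed grid cells are holes for the
cluster rule. Intensities are normalised per channel to [−1, 1] via
x/127.5 − 1. Two resize paths exist on purpose: `resize_bilinear` is
corner-aligned bilinear interpolation (output pixel i samples source
coordinate i·(src−1)/(dst−1)) for small backbone-side adjustments, while the
large reduction from 300 px to the working resolution uses an anti-aliased
area resize — point-sampling at an ~18× reduction would alias away exactly
the texture statistics that distinguish the classes. Augmentation (random
flips, central zoom in [1.0, 1.15] with re-crop, per-channel colour scaling
in [0.98, 1.02]) is applied on the fly at the working resolution; the colour
range is deliberately mild so that augmentation emulates acquisition
variation without drowning class-level colour statistics.

## Slide and patient inference

Binarising a slide's patch probabilities at threshold t, the slide is
positive iff some 4-connected component of positive tissue cells has size
≥ 4 (both the cluster size and the connectivity are configurable; 4-neighbour
is the stricter default). The continuous *bottleneck score* is
sup{t : the slide is positive at threshold t}, computed by admitting tissue
cells in descending probability order into a union-find forest and returning
the probability of the cell whose arrival first completes a size-4
component. Thresholding the score at t reproduces the binary decision at
patch threshold t exactly, so ROC analysis of the score is consistent with
the published binary rule; with cluster size 1 the score reduces to the
maximum patch probability. A patient's score is the maximum of their slide
scores; the patient is positive iff any slide is positive. The bottleneck
construction is this package's explicit continuous extension — the binary
rule itself defines no slide score.

## Statistics

AUC is the Mann–Whitney statistic with midrank tie handling,
U/(n₁n₀). The replicate protocol repeats the subject-stratified 70/30 slide
split k times with consecutive seeds, retrains every model per replicate and
evaluates on the paired test side at patch, slide and patient level.

Paired model comparison uses the Wilcoxon signed-rank test in the variant
that reproduces the protocol's published behaviour: zero differences
dropped, midranks on |d| with tie-corrected variance, W = min(W⁺, W⁻), and
the **normal approximation without continuity correction**,
z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24), two-sided p = 2Φ(z). For uniformly
signed differences this gives p = 0.0117 (n=8), 0.0022 (n=12) and 0.00044
(n=16) — printing as 0.012 / 0.002 / 0.0004 — whereas the exact-distribution
minimum for n=8 would be 0.0078; the no-correction normal form is therefore
the reconciling choice. Means are reported with sample (n−1) standard
deviations. No multiple-testing adjustment is applied. The exact enumeration
is kept in the test suite as an independent oracle for n ≤ 10.

## The synthetic cohort

The generator emulates the statistical and spatial structure the pipeline
assumes, not H&E appearance:

- **Slides** are grids (default 12×16) of patch positions, one slide per
  subject. Round(n·positive_fraction) subjects are positive. Positive slides
  grow one contiguous tumor region by random 4-connected accretion to a
  uniform-random area fraction in [0.1, 0.5] — contiguity is the only
  property the cluster rule needs, and every positive slide hosts a
  connected region of ≥ 4 cells.
- **ROI sampling** mirrors the annotation design: 4–10 regions of interest
  per positive slide, 10–25 per negative slide (counts uniform), each a 2×3
  block of cells yielding exactly six non-overlapping 300×300 patches
  (a ~1024×768 field holds about six such tiles); requested counts beyond
  the grid capacity are clamped with a logged warning. Patch classes follow
  the per-cell tumor truth.
- **Textures**: a patch is a base-colour canvas with darker nuclei-like
  disks and Gaussian pixel noise. The two tissue classes share the base
  colour (215, 170, 190) and differ only in nuclear density (45 vs 22
  expected blobs) and radius (5.5 vs 4.5 px) — density and size of nuclei,
  not colour, are the discriminators, as in real morphology. A lognormal
  per-patch density dispersion (σ = 0.25) creates within-class heterogeneity
  so single-patch classification is genuinely imperfect. The background
  class renders near-white glass that the background filter removes
  entirely.
- **Determinism**: per-slide random streams are derived by hashing the slide
  id into the cohort seed, so cohorts are reproducible and slides are
  independent; identical (config, seed) gives byte-identical manifests.

What passing on this generator shows — and does not. The cohort exercises
every contract of the pipeline (no-leakage splits, budget arithmetic,
consistency training dynamics, cluster-rule geometry, protocol statistics)
and reproduces the qualitative headline: with a 5% label budget the mean
teacher's mean test patch AUC exceeds the supervised baseline's across
replicate splits (measured 0.934 vs 0.839 over 5 replicates at the default
seed, each replicate pair sharing labels and initialisation; the comparison
is recomputed, not asserted as a constant, by `scripts/acceptance.py`). It
cannot show anything about real H&E: there is no stain variation, no scanner
artefact, no morphological diversity, and the absolute AUCs of full-scale
systems trained on real slides are out of desk scale by construction.

## Numerical and design notes

- Per-slide label quotas use round-half-up with a floor of one labelled
  patch per non-empty training slide when the budget is positive; realised
  budgets therefore track requested ones to within one patch per slide.
- Slide splits are by subject and stratified by slide label; a class with
  fewer than two subjects cannot be stratified and is rejected.
- The bottleneck sweep breaks probability ties by admitting all tied cells
  before a threshold can be declared (the union-find check fires on the
  completing cell, whose probability equals the threshold), which is why it
  agrees exactly with the brute-force threshold scan under ties.
- Sensitivity/specificity are reported as NaN (missing), never 0, when the
  truth vector has no members of the relevant class.
- Degenerate inputs: empty labelled pools, all-zero Wilcoxon differences,
  single-class AUC labels, empty patient slide lists and sub-2×2 resize
  sources all raise `ValueError` rather than returning a default.
- Model checkpoints serialise to JSON (config, backbone spec, class order,
  parameters); training logs record per-epoch classification, consistency
  and total costs, validation accuracy and learning rate.

## Known limitations

- The numpy backbones are CPU-sized; the package does not attempt
  GPU-scale architectures, ImageNet pre-training or stain normalisation.
- The per-epoch EMA cadence makes the teacher a heavily smoothed trailing
  average; with few epochs the teacher lags the student, which is why
  desk-scale runs use many short epochs rather than few long ones.
- Patient-level AUC on small synthetic cohorts is frequently degenerate
  (few test subjects), and is reported as NaN when a test side has one
  class only.
- The collapse mode of consistency training (student and teacher agreeing
  on the majority class) is real: it appears when mini-batches contain
  fewer than a handful of labelled samples. The published batch sizes avoid
  it; very small batch sizes at very small budgets will not.
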