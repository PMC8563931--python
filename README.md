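# histossl

Semi-supervised recognition of cancer in whole-slide pathology images under a
small label budget, at desk scale.

Annotating histopathology patches is the bottleneck of slide-level cancer
recognition systems: a supervised patch classifier needs tens of thousands of
expert-labelled tiles. `histossl` implements the alternative pipeline in
which only a small fraction of patches is labelled and the rest contribute
through consistency training, then carries patch predictions up to slide and
patient decisions:

1. **Mean-teacher patch classifier.** A student network is trained on
   mini-batches mixing labelled and unlabelled patches in the pool
   proportion. The loss is

   `L = CE(y, softmax(f_s(x_lab))) + MSE(softmax(f_s(x_unl)), softmax(f_t(x_unl))) + λ‖θ‖²`

   — cross-entropy (classification cost) on the labelled part plus the mean
   squared error between student probabilities and the teacher's pseudo
   labels (consistency cost) on the unlabelled part. The teacher's
   parameters are an exponential moving average of the student's, updated
   once per epoch, `θ_t ← α θ_t + (1−α) θ_s` with α = 0.95; the teacher is
   the model used at inference.
2. **Label budgets per WSI.** A budget of n% of all patches is spent inside
   each training slide: n%/train_fraction of that slide's patches are
   labelled, the rest form the unlabelled pool. The slide-level train/test
   division (default 70/30, stratified, by subject) guarantees no patch
   leakage.
3. **Cluster-based slide inference.** A slide is positive only when ≥ 4
   spatially connected patches (4-neighbour) individually exceed the patch
   threshold — single hot patches cannot flip a slide. The binary rule
   extends to a continuous *bottleneck score*, sup{t : a 4-cluster survives
   at threshold t}, whose 0.5 slice is exactly the binary rule. A patient is
   positive iff any of their slides is.
4. **Replicate comparison protocol.** The slide split is repeated k times
   (classically 8), each model retrained per replicate, and paired metric
   vectors compared with the Wilcoxon signed-rank test (normal
   approximation, no continuity correction, midrank ties).

Everything runs on synthetic cohorts from the bundled generator — textured
patch grids with contiguous tumor regions and pathologist-style ROI sampling
— so the full pipeline is testable on one CPU in minutes, with no downloads.
Backbones are small numpy networks injected by spec (`mlp`, `tiny_cnn`); the
trainer is backbone-agnostic.

## Worked example

```python
import numpy as np
from histossl import (BackboneSpec, MeanTeacherConfig, apply_plan, auc,
                      generate_cohort, replicate_splits, supervised_defaults,
                      train_sl, train_ssl)
from histossl.preprocess import PreprocessConfig, normalize
from histossl.trainer import PatchImageCache

slides = generate_cohort(16, 0.5, seed=3)           # 8 positive, 8 negative
patches = [p for s in slides for p in s.patches]
plan = replicate_splits(slides, 1, 11, budget=0.05, train_fraction=0.7)[0]

cache = PatchImageCache(PreprocessConfig(target_size=16))
scale = dict(epochs=100, steps_per_epoch=8, pretrain_epochs=30,
             early_stop_patience=100)
ssl = train_ssl(MeanTeacherConfig(seed=5, **scale), plan, patches,
                BackboneSpec("mlp", 16), cache=cache)
sl = train_sl(supervised_defaults(seed=5, **scale), plan, patches,
              BackboneSpec("mlp", 16), cache=cache)

print(f"{len(plan.labeled_patch_ids)} labeled / "
      f"{len(plan.unlabeled_patch_ids)} unlabeled training patches")
_, _, test = apply_plan(patches, plan)
kept = cache.add(test)
x = np.stack([normalize(cache.image(p)) for p in kept])
truth = [int(p.tumor_truth) for p in kept]
for name, m in [("mean teacher (5% labels)", ssl),
                ("supervised   (5% labels)", sl)]:
    probs = m.network.predict_proba(x)[:, m.positive_class_index()]
    print(f"{name}: test patch AUC = {auc(probs, truth):.3f}")
```

prints

```
58 labeled / 752 unlabeled training patches
mean teacher (5% labels): test patch AUC = 0.905
supervised   (5% labels): test patch AUC = 0.802
```

i.e. with the same 58 labelled patches, the consistency cost over the 752
unlabelled ones lifts the teacher's test AUC by about 0.10 — the central
behaviour the pipeline exists to demonstrate. The `examples/` directory has
one narrative script per capability (cohort generation, splits and budgets,
training, slide/patient inference, replicate comparison).

A thin CLI mirrors the stages:

```bash
histossl synth --out cohort --n-subjects 20 --seed 1
histossl split --manifest cohort/manifest.csv --out splits --budget 0.1 --replicates 8 --seed 1
histossl run --config exp.yaml --out runs/exp1
```

## Layout

- `src/histossl/cohort.py` — synthetic slides, textures, ROI sampling
- `src/histossl/datasets.py` — splits, budgets, replicates, manifests
- `src/histossl/preprocess.py` — background filter, resize, augmentation
- `src/histossl/nn.py` — numpy backbones (dense / small conv) with Adam
- `src/histossl/trainer.py` — mean-teacher and supervised training loops
- `src/histossl/inference.py` — cluster rule, bottleneck score, patient rules
- `src/histossl/stats.py` — AUC, confusion metrics, Wilcoxon, protocol
- `src/histossl/workflow.py`, `cli.py` — experiment orchestration and CLI

See `docs/methods.md` for the model details, parameter defaults, and the
limits of what the synthetic cohorts can show.
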