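"""Train a mean-teacher model and its supervised baseline on one split.

The student minimises cross-entropy on the labeled batch part plus the mean
squared error between its predicted probabilities and the teacher's pseudo
labels on the unlabeled part; the teacher is a per-epoch exponential moving
average (smoothing 0.95) of the student and is the model used at inference.
"""

import logging

import numpy as np

from histossl import (BackboneSpec, MeanTeacherConfig, apply_plan, auc,
                      generate_cohort, replicate_splits, supervised_defaults,
                      train_sl, train_ssl)
from histossl.preprocess import PreprocessConfig, normalize
from histossl.trainer import PatchImageCache

logging.disable(logging.WARNING)

slides = generate_cohort(16, 0.5, seed=3)
patches = [p for s in slides for p in s.patches]
plan = replicate_splits(slides, 1, 11, budget=0.05, train_fraction=0.7)[0]
print(f"{len(plan.labeled_patch_ids)} labeled / "
      f"{len(plan.unlabeled_patch_ids)} unlabeled training patches")

cache = PatchImageCache(PreprocessConfig(target_size=16))
scale = dict(epochs=100, steps_per_epoch=8, pretrain_epochs=30,
             early_stop_patience=100)
ssl = train_ssl(MeanTeacherConfig(seed=5, **scale), plan, patches,
                BackboneSpec("mlp", 16), cache=cache)
sl = train_sl(supervised_defaults(seed=5, **scale), plan, patches,
              BackboneSpec("mlp", 16), cache=cache)

_, _, test = apply_plan(patches, plan)
kept = cache.add(test)
x = np.stack([normalize(cache.image(p)) for p in kept])
truth = [int(p.tumor_truth) for p in kept]
for name, model in [("mean teacher (5% labels)", ssl),
                    ("supervised   (5% labels)", sl)]:
    probs = model.network.predict_proba(x)[:, model.positive_class_index()]
    print(f"{name}: test patch AUC = {auc(probs, truth):.3f}")
# with the same 5% of labels, the consistency cost over the unlabeled pool
# typically lifts the teacher's AUC above the supervised baseline
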