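"""Slide-level replicate splits and per-WSI label budgets.

The train/test division is by subject (no patch of a subject leaks across
sides), repeated k times with consecutive seeds; within the training side a
label budget of n% of ALL patches is spent per slide as n%/train_fraction of
that slide's patches.
"""

from histossl import generate_cohort, label_budget_counts, replicate_splits

slides = generate_cohort(20, 0.5, seed=7)
patches = [p for s in slides for p in s.patches]

plans = replicate_splits(slides, k=3, base_seed=100, budget=0.05,
                         train_fraction=0.7)
for plan in plans:
    n_lab = len(plan.labeled_patch_ids)
    n_unl = len(plan.unlabeled_patch_ids)
    print(f"replicate {plan.replicate_id} (seed {plan.seed}): "
          f"{len(plan.train_slide_ids)} train / "
          f"{len(plan.test_slide_ids)} test slides, "
          f"{n_lab} labeled + {n_unl} unlabeled patches "
          f"(realised budget {n_lab / len(patches):.3f})")
# the realised budget tracks the requested 5% up to one patch per slide

# bookkeeping for balanced flat datasets: a two-class pool of 131,072
# training patches per class at a 1% label budget
counts = label_budget_counts({"tumor": 131072, "normal": 131072}, 0.01)
total = sum(l for l, _ in counts.values())
print(f"balanced pool at 1%: {counts} -> {total} labeled in total")
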