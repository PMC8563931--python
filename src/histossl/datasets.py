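"""Slide-level partitioning, per-WSI label budgets, replicate splits, manifests.

The labelling design mirrors weakly supervised pathology practice: the
train/test division is by subject (all slides and patches of a subject fall
on one side, so there is no patch leakage), and the label budget is spent
per slide — each training slide has budget/train_fraction of its patches
randomly labelled, the rest kept as unlabeled pool.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PatchRecord, SyntheticSlide

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["patch_id", "path", "slide_id", "subject_id", "row", "col",
                    "class", "labeled", "tumor_truth", "render_seed"]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitPlan:
    """One replicate's slide partition plus labeled-patch selection."""

    replicate_id: int
    seed: int
    train_fraction: float
    train_slide_ids: set[str] = field(default_factory=set)
    test_slide_ids: set[str] = field(default_factory=set)
    labeled_patch_ids: set[str] = field(default_factory=set)
    unlabeled_patch_ids: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.train_slide_ids & self.test_slide_ids:
            raise ValueError("train and test slide sets overlap")
        if self.labeled_patch_ids & self.unlabeled_patch_ids:
            raise ValueError("labeled and unlabeled patch sets overlap")

    def to_json(self, path) -> None:
        payload = {
            "replicate_id": self.replicate_id,
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "train_slide_ids": sorted(self.train_slide_ids),
            "test_slide_ids": sorted(self.test_slide_ids),
            "labeled_patch_ids": sorted(self.labeled_patch_ids),
            "unlabeled_patch_ids": sorted(self.unlabeled_patch_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(replicate_id=d["replicate_id"], seed=d["seed"],
                   train_fraction=d["train_fraction"],
                   train_slide_ids=set(d["train_slide_ids"]),
                   test_slide_ids=set(d["test_slide_ids"]),
                   labeled_patch_ids=set(d["labeled_patch_ids"]),
                   unlabeled_patch_ids=set(d["unlabeled_patch_ids"]))


def split_slides(slides: list[SyntheticSlide], train_fraction: float,
                 seed: int, replicate_id: int = 0) -> SplitPlan:
    """Partition slides into train/test, by subject, stratified by label.

    Exactly floor(n_slides * train_fraction) slides land in train (when each
    subject carries one slide; multi-slide subjects are kept whole, so the
    realised count can differ by at most the subject's slide count).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(slides) < 2:
        raise ValueError("need at least 2 slides to split")

    by_subject: dict[str, list[SyntheticSlide]] = {}
    for s in slides:
        by_subject.setdefault(s.subject_id, []).append(s)
    subj_label = {sid: ("positive" if any(s.label == "positive" for s in group)
                        else "negative")
                  for sid, group in by_subject.items()}
    classes: dict[str, list[str]] = {}
    for sid, lab in subj_label.items():
        classes.setdefault(lab, []).append(sid)
    for lab, members in classes.items():
        if len(members) < 2:
            raise ValueError(
                f"class {lab!r} has {len(members)} slide(s); cannot stratify")

    n_slides = len(slides)
    total_target = int(math.floor(n_slides * train_fraction))
    # per-class floor targets, remainder to the largest fractional parts
    sizes = {lab: sum(len(by_subject[s]) for s in members)
             for lab, members in classes.items()}
    targets = {lab: int(math.floor(sz * train_fraction))
               for lab, sz in sizes.items()}
    fracs = sorted(classes, key=lambda lab: sizes[lab] * train_fraction
                   - targets[lab], reverse=True)
    i = 0
    while sum(targets.values()) < total_target:
        targets[fracs[i % len(fracs)]] += 1
        i += 1

    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    for lab in sorted(classes):
        members = sorted(classes[lab])
        rng.shuffle(members)
        count = 0
        for sid in members:
            group = [s.slide_id for s in by_subject[sid]]
            if count < targets[lab]:
                train_ids.update(group)
                count += len(group)
            else:
                test_ids.update(group)
        if count == 0 or count == sizes[lab]:
            raise ValueError(
                f"class {lab!r} ended up entirely on one side of the split")

    plan = SplitPlan(replicate_id=replicate_id, seed=seed,
                     train_fraction=train_fraction,
                     train_slide_ids=train_ids, test_slide_ids=test_ids)
    plan.validate()
    return plan


def assign_label_budget(plan: SplitPlan, patches: list[PatchRecord],
                        budget_fraction_of_total: float,
                        seed: int) -> SplitPlan:
    """Spend a label budget per training slide.

    The budget is a fraction of ALL patches; each training slide labels
    round-half-up(n_slide * budget/train_fraction) of its patches (at least
    one when the quota rounds to zero and the budget is positive), the rest
    become the unlabeled pool.
    """
    if budget_fraction_of_total < 0:
        raise ValueError("budget must be >= 0")
    if budget_fraction_of_total > plan.train_fraction + 1e-12:
        raise ValueError(
            f"budget {budget_fraction_of_total} exceeds the training "
            f"fraction {plan.train_fraction}")

    per_slide_frac = budget_fraction_of_total / plan.train_fraction
    rng = np.random.default_rng(seed)
    labeled: set[str] = set()
    unlabeled: set[str] = set()
    by_slide: dict[str, list[PatchRecord]] = {}
    for p in patches:
        if p.slide_id in plan.train_slide_ids:
            by_slide.setdefault(p.slide_id, []).append(p)
    for slide_id in sorted(plan.train_slide_ids):
        group = by_slide.get(slide_id, [])
        if not group:
            logger.warning("slide %s has no patches; skipped", slide_id)
            continue
        quota = round_half_up(len(group) * per_slide_frac)
        if quota == 0 and budget_fraction_of_total > 0:
            quota = 1
        quota = min(quota, len(group))
        ids = sorted(p.patch_id for p in group)
        pick = rng.choice(len(ids), size=quota, replace=False)
        chosen = {ids[i] for i in pick}
        labeled |= chosen
        unlabeled |= set(ids) - chosen
    out = replace(plan, labeled_patch_ids=labeled, unlabeled_patch_ids=unlabeled)
    out.validate()
    return out


def replicate_splits(slides: list[SyntheticSlide], k: int, base_seed: int,
                     budget: float, train_fraction: float = 0.7,
                     patches: list[PatchRecord] | None = None,
                     ) -> list[SplitPlan]:
    """k independent replicate splits with seeds base_seed .. base_seed+k-1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if patches is None:
        patches = [p for s in slides for p in s.patches]
    plans = []
    for r in range(k):
        plan = split_slides(slides, train_fraction, seed=base_seed + r,
                            replicate_id=r)
        plan = assign_label_budget(plan, patches, budget, seed=base_seed + r)
        plans.append(plan)
    return plans


def label_budget_counts(train_pool_per_class: dict[str, int],
                        labeled_fraction_of_train: float,
                        ) -> dict[str, tuple[int, int]]:
    """Per-class (labeled, unlabeled) counts for a balanced flat dataset.

    The labeled count is round-half-up(train_pool * fraction); the remainder
    of the training pool is unlabeled.  A budget quoted as a fraction of the
    TOTAL dataset converts via fraction_of_train = budget / train_fraction.
    """
    if not 0.0 <= labeled_fraction_of_train <= 1.0:
        raise ValueError("labeled fraction must lie in [0, 1]")
    out = {}
    for cls, pool in train_pool_per_class.items():
        lab = min(pool, round_half_up(pool * labeled_fraction_of_train))
        out[cls] = (lab, pool - lab)
    return out


def apply_plan(records: list[PatchRecord], plan: SplitPlan,
               ) -> tuple[list[PatchRecord], list[PatchRecord], list[PatchRecord]]:
    """Split records into (labeled_train, unlabeled_train, test).

    Labeled flags are set on the returned training records; unlabeled
    records keep their class for evaluation but are flagged unlabeled.
    """
    labeled, unlabeled, test = [], [], []
    for p in records:
        if p.slide_id in plan.test_slide_ids:
            test.append(replace(p, labeled=False))
        elif p.patch_id in plan.labeled_patch_ids:
            labeled.append(replace(p, labeled=True))
        elif p.patch_id in plan.unlabeled_patch_ids:
            unlabeled.append(replace(p, labeled=False))
    return labeled, unlabeled, test


def write_manifest(records: list[PatchRecord], path) -> None:
    df = pd.DataFrame([{
        "patch_id": p.patch_id, "path": p.path or "", "slide_id": p.slide_id,
        "subject_id": p.subject_id, "row": p.row, "col": p.col,
        "class": p.label or "", "labeled": p.labeled,
        "tumor_truth": p.tumor_truth,
        "render_seed": -1 if p.render_seed is None else p.render_seed,
    } for p in records])
    if df.empty:
        df = pd.DataFrame(columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path) -> list[PatchRecord]:
    """Read a cohort manifest CSV; duplicate grid coordinates are rejected."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    dup = df.duplicated(subset=["slide_id", "row", "col"])
    if dup.any():
        bad = df.loc[dup, "slide_id"].iloc[0]
        raise ValueError(
            f"duplicate (slide_id,row,col) coordinate on slide {bad!r}")
    records = []
    for _, r in df.iterrows():
        seed = int(r.get("render_seed", -1))
        records.append(PatchRecord(
            patch_id=str(r["patch_id"]),
            path=(str(r["path"]) if str(r.get("path", "")) else None),
            slide_id=str(r["slide_id"]), subject_id=str(r["subject_id"]),
            row=int(r["row"]), col=int(r["col"]),
            label=(str(r["class"]) if str(r.get("class", "")) not in
                   ("", "nan") else None),
            labeled=bool(r["labeled"]),
            tumor_truth=bool(r.get("tumor_truth", False)),
            render_seed=None if seed < 0 else seed))
    return records
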