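"""Slide splits, label budgets, replicate plans, manifest round-trips."""

import numpy as np
import pytest
from scipy import stats

from histossl import (PatchRecord, assign_label_budget, label_budget_counts,
                      read_manifest, replicate_splits, split_slides,
                      write_manifest)
from histossl.cohort import SyntheticSlide


def _dummy_slides(n_pos, n_neg):
    out = []
    for i in range(n_pos + n_neg):
        lab = "positive" if i < n_pos else "negative"
        out.append(SyntheticSlide(slide_id=f"w{i:04d}", subject_id=f"s{i:04d}",
                                  label=lab, grid_shape=(2, 2),
                                  tumor_mask=np.zeros((2, 2), dtype=bool)))
    return out


class TestSplitSlides:
    def test_cohort_scale_train_count(self):
        # 842 slides at 70%: floor(842 * 0.7) = 589 on the training side
        slides = _dummy_slides(614, 228)
        plan = split_slides(slides, 0.7, seed=0)
        expected = sum(1 for k in range(842) if k < int(842 * 0.7))
        assert len(plan.train_slide_ids) == expected == 589
        assert len(plan.test_slide_ids) == 842 - 589

    def test_deterministic_and_seed_sensitivity(self):
        slides = _dummy_slides(5, 5)
        p1 = split_slides(slides, 0.5, seed=4)
        p2 = split_slides(slides, 0.5, seed=4)
        p3 = split_slides(slides, 0.5, seed=5)
        assert p1.train_slide_ids == p2.train_slide_ids
        assert len(p1.train_slide_ids) == len(p3.train_slide_ids) == 5
        assert p1.train_slide_ids != p3.train_slide_ids

    def test_stratified_both_classes_both_sides(self):
        slides = _dummy_slides(6, 6)
        plan = split_slides(slides, 0.5, seed=1)
        labels = {s.slide_id: s.label for s in slides}
        for side in (plan.train_slide_ids, plan.test_slide_ids):
            assert {labels[i] for i in side} == {"positive", "negative"}

    def test_single_slide_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            split_slides(_dummy_slides(1, 5), 0.5, seed=0)


class TestLabelBudget:
    def _slide_patches(self, slide_id, n):
        return [PatchRecord(patch_id=f"{slide_id}_p{i}", slide_id=slide_id,
                            subject_id=slide_id, row=i, col=0, label="normal")
                for i in range(n)]

    def test_budget_equal_train_fraction_labels_everything(self):
        slides = _dummy_slides(2, 2)
        patches = sum((self._slide_patches(s.slide_id, 10) for s in slides), [])
        plan = split_slides(slides, 0.5, seed=0)
        plan = assign_label_budget(plan, patches, 0.5, seed=0)
        assert not plan.unlabeled_patch_ids
        assert len(plan.labeled_patch_ids) == 20

    def test_budget_above_train_fraction_rejected(self):
        slides = _dummy_slides(2, 2)
        patches = sum((self._slide_patches(s.slide_id, 4) for s in slides), [])
        plan = split_slides(slides, 0.5, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            assign_label_budget(plan, patches, 0.6, seed=0)

    def test_budget_accounting_within_one_patch_per_slide(self, small_cohort,
                                                          small_patches):
        budget = 0.10
        plans = replicate_splits(small_cohort, 2, 7, budget,
                                 train_fraction=0.7)
        for plan in plans:
            n_train = len(plan.labeled_patch_ids) + len(plan.unlabeled_patch_ids)
            realized = len(plan.labeled_patch_ids)
            target = n_train * budget / 0.7
            assert abs(realized - target) <= len(plan.train_slide_ids)

    def test_labeled_subset_uniform_over_seeds(self):
        # one 20-patch slide with a 5-patch quota: each patch should be chosen
        # with probability 1/4 across seeds (chi-square on 400 draws)
        slides = _dummy_slides(2, 2)
        patches = sum((self._slide_patches(s.slide_id, 20) for s in slides), [])
        counts = np.zeros(20)
        n_seeds = 400
        for seed in range(n_seeds):
            plan = split_slides(slides, 0.5, seed=0)
            if "w0000" not in plan.train_slide_ids:
                plan.train_slide_ids, plan.test_slide_ids = \
                    plan.test_slide_ids, plan.train_slide_ids
            plan = assign_label_budget(plan, patches, 0.125, seed=seed)
            for pid in plan.labeled_patch_ids:
                if pid.startswith("w0000_"):
                    counts[int(pid.split("_p")[1])] += 1
        expected = n_seeds * 5 / 20
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=19) > 1e-3

    def test_no_patch_leakage(self, small_cohort, small_patches):
        plans = replicate_splits(small_cohort, 3, 11, 0.05, train_fraction=0.7)
        slide_of = {p.patch_id: p.slide_id for p in small_patches}
        for plan in plans:
            assert not plan.train_slide_ids & plan.test_slide_ids
            train_patch_slides = {slide_of[i] for i in
                                  plan.labeled_patch_ids
                                  | plan.unlabeled_patch_ids}
            assert train_patch_slides <= plan.train_slide_ids
            assert not plan.labeled_patch_ids & plan.unlabeled_patch_ids


class TestReplicateSplits:
    def test_k8_pairwise_distinct_train_sets(self, small_cohort):
        plans = replicate_splits(small_cohort, 8, 100, 0.05,
                                 train_fraction=0.7)
        trains = [frozenset(p.train_slide_ids) for p in plans]
        assert len(set(trains)) == 8
        assert [p.seed for p in plans] == list(range(100, 108))

    def test_same_base_seed_identical(self, small_cohort):
        a = replicate_splits(small_cohort, 2, 5, 0.1, train_fraction=0.7)
        b = replicate_splits(small_cohort, 2, 5, 0.1, train_fraction=0.7)
        for pa, pb in zip(a, b):
            assert pa.train_slide_ids == pb.train_slide_ids
            assert pa.labeled_patch_ids == pb.labeled_patch_ids

    def test_k1_matches_manual_composition(self, small_cohort, small_patches):
        plan = replicate_splits(small_cohort, 1, 9, 0.1,
                                train_fraction=0.7)[0]
        manual = split_slides(small_cohort, 0.7, seed=9, replicate_id=0)
        manual = assign_label_budget(manual, small_patches, 0.1, seed=9)
        assert plan.train_slide_ids == manual.train_slide_ids
        assert plan.labeled_patch_ids == manual.labeled_patch_ids


class TestBudgetBookkeeping:
    """Published per-class labeled/unlabeled counts from balanced datasets."""

    def test_three_class_budget_of_total(self):
        # 5,000 per class, 80% training pool; a 5%-of-total budget is
        # 0.05/0.8 of the training pool -> 250 labeled, 3,750 unlabeled
        counts = label_budget_counts({c: 4000 for c in "abc"}, 0.05 / 0.8)
        assert all(v == (250, 3750) for v in counts.values())
        counts80 = label_budget_counts({c: 4000 for c in "abc"}, 0.8 / 0.8)
        assert sum(l for l, _ in counts80.values()) == 12000

    def test_two_class_budget_of_train(self):
        counts1 = label_budget_counts({"t": 131072, "n": 131072}, 0.01)
        assert counts1["t"] == (1311, 129761)
        assert sum(l for l, _ in counts1.values()) == 2622
        counts5 = label_budget_counts({"t": 131072, "n": 131072}, 0.05)
        assert counts5["t"] == (6554, 124518)
        assert sum(l for l, _ in counts5.values()) == 13108
        assert sum(u for _, u in counts5.values()) == 249036


class TestManifestIO:
    def test_round_trip(self, tmp_path, small_patches):
        path = tmp_path / "m.csv"
        write_manifest(small_patches[:100], path)
        back = read_manifest(path)
        assert len(back) == 100
        for a, b in zip(small_patches[:100], back):
            assert (a.patch_id, a.slide_id, a.row, a.col, a.label,
                    a.labeled, a.tumor_truth, a.render_seed) == \
                   (b.patch_id, b.slide_id, b.row, b.col, b.label,
                    b.labeled, b.tumor_truth, b.render_seed)

    def test_duplicate_coordinate_names_slide(self, tmp_path):
        recs = [PatchRecord("a", "slideX", "s", 0, 0, "normal"),
                PatchRecord("b", "slideX", "s", 0, 0, "normal")]
        path = tmp_path / "dup.csv"
        write_manifest(recs, path)
        with pytest.raises(ValueError, match="slideX"):
            read_manifest(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_manifest(path) == []
        write_manifest([], path)
        assert read_manifest(path) == []
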