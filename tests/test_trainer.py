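"""Mean-teacher mechanics: batch composition, losses, EMA, training loop."""

import numpy as np
import pytest

from histossl import (BackboneSpec, MeanTeacherConfig, batch_counts,
                      compose_batch, ema_update, replicate_splits,
                      supervised_defaults, total_loss, train_sl, train_ssl)


class TestBatchComposition:
    def test_crc_10pct_proportions(self):
        # 6,300 labeled / 37,800 unlabeled, batch 128 -> 18 + 110
        assert batch_counts(6300, 37800, 128) == (18, 110)

    def test_no_unlabeled_degenerates_to_supervised(self):
        assert batch_counts(500, 0, 128) == (128, 0)

    def test_equal_pools_symmetric(self):
        assert batch_counts(1000, 1000, 128) == (64, 64)

    def test_labeled_count_clamped_to_one(self):
        assert batch_counts(1, 100000, 128)[0] == 1

    def test_empty_labeled_pool_rejected(self):
        with pytest.raises(ValueError, match="labeled"):
            batch_counts(0, 100, 128)

    def test_compose_batch_sizes_and_determinism(self):
        cfg = MeanTeacherConfig(batch_size=16)
        lab, unl = list(range(100)), list(range(1000))
        bl, bu = compose_batch(lab, unl, cfg, seed=3)
        nl, nu = batch_counts(100, 1000, 16)
        assert (len(bl), len(bu)) == (nl, nu)
        bl2, bu2 = compose_batch(lab, unl, cfg, seed=3)
        assert bl == bl2 and bu == bu2


class TestTotalLoss:
    def test_student_equals_teacher_leaves_ce_plus_l2(self):
        logits = np.array([[4.0, -4.0]])
        labels = np.array([0])
        probs = np.array([[0.7, 0.3], [0.2, 0.8]])
        full = total_loss(logits, labels, probs, probs, l2_term=10.0,
                          l2_coefficient=1e-3)
        ce_only = total_loss(logits, labels, np.empty((0, 2)),
                             np.empty((0, 2)), l2_term=0.0)
        assert full == pytest.approx(ce_only + 0.01)

    def test_hand_computed_consistency(self):
        # one binary unlabeled sample: ((-0.2)^2 + 0.2^2) / 2 = 0.04
        logits = np.array([[50.0, -50.0]])  # CE -> 0 for class 0
        loss = total_loss(logits, np.array([0]),
                          np.array([[0.6, 0.4]]), np.array([[0.8, 0.2]]),
                          l2_term=0.0)
        assert loss == pytest.approx(0.04, abs=1e-9)

    def test_consistency_invariant_under_class_permutation(self):
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.ones(3), size=6)
        t = rng.dirichlet(np.ones(3), size=6)
        perm = [2, 0, 1]
        a = total_loss(np.array([[9.0, -9, -9]]), np.array([0]), s, t, 0.0)
        b = total_loss(np.array([[9.0, -9, -9]]), np.array([0]),
                       s[:, perm], t[:, perm], 0.0)
        assert a == pytest.approx(b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.array([[1.0, 0.0]]), np.array([0]),
                       np.ones((2, 2)) / 2, np.ones((3, 2)) / 2, 0.0)


class TestEMA:
    def test_fixed_point_and_endpoints(self):
        c = [np.array([3.0, -1.0])]
        assert np.allclose(ema_update(c, c, 0.95)[0], c[0])
        assert ema_update([np.zeros(1)], [np.ones(1)], 0.95)[0] == \
            pytest.approx(0.05)
        assert ema_update([np.zeros(1)], [np.ones(1)], 0.0)[0] == \
            pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update([np.zeros(2)], [np.zeros(3)], 0.5)

    def test_closed_form_over_epochs(self):
        # theta_t(k) = a^k theta(0) + (1-a) sum_j a^(k-1-j) theta_s(j)
        rng = np.random.default_rng(4)
        alpha = 0.9
        theta0 = rng.normal(size=2)
        students = [rng.normal(size=2) for _ in range(6)]
        teacher = [theta0.copy()]
        t = [theta0.copy()]
        for s in students:
            t = ema_update(t, [s], alpha)
        k = len(students)
        closed = alpha ** k * theta0 + (1 - alpha) * sum(
            alpha ** (k - 1 - j) * students[j] for j in range(k))
        assert np.allclose(t[0], closed)


@pytest.fixture(scope="module")
def split_5pct(small_cohort):
    return replicate_splits(small_cohort, 1, 11, 0.05, train_fraction=0.7)[0]


SMOKE = dict(epochs=8, steps_per_epoch=6, batch_size=32, pretrain_epochs=2,
             early_stop_patience=8)


class TestTrainingLoop:
    def test_ssl_smoke_beats_chance(self, split_5pct, small_patches,
                                    shared_cache):
        cfg = MeanTeacherConfig(seed=5, epochs=30, steps_per_epoch=8,
                                pretrain_epochs=5, early_stop_patience=30)
        model = train_ssl(cfg, split_5pct, small_patches, BackboneSpec(),
                          cache=shared_cache)
        assert model.mode == "ssl"
        assert model.log[-1]["val_acc"] > 0.5
        assert len(model.log) <= cfg.epochs

    def test_deterministic_given_seed(self, split_5pct, small_patches,
                                      shared_cache):
        runs = []
        for _ in range(2):
            cfg = MeanTeacherConfig(seed=9, **SMOKE)
            m = train_ssl(cfg, split_5pct, small_patches, BackboneSpec(),
                          cache=shared_cache)
            runs.append(m)
        assert runs[0].log == runs[1].log
        for a, b in zip(runs[0].network.parameters(),
                        runs[1].network.parameters()):
            assert (a == b).all()

    def test_early_stopping_contract(self, split_5pct, small_patches,
                                     shared_cache):
        # patience 1, no pretraining: stops at the first non-improving epoch
        cfg = supervised_defaults(seed=1, epochs=40, steps_per_epoch=2,
                                  batch_size=8, pretrain_epochs=0,
                                  early_stop_patience=1, learning_rate=0.0)
        m = train_sl(cfg, split_5pct, small_patches, BackboneSpec(),
                     cache=shared_cache)
        assert len(m.log) == 2  # epoch 0 sets best, epoch 1 triggers the stop

    def test_zero_epochs_returns_initialized_model(self, split_5pct,
                                                   small_patches,
                                                   shared_cache):
        cfg = supervised_defaults(seed=1, epochs=0, pretrain_epochs=0)
        m = train_sl(cfg, split_5pct, small_patches, BackboneSpec(),
                     cache=shared_cache)
        assert m.log == []

    def test_ssl_without_unlabeled_matches_sl_losses(self, small_cohort,
                                                     small_patches,
                                                     shared_cache):
        # budget = train fraction -> empty unlabeled pool; the student update
        # sequence must then coincide with supervised training
        plan = replicate_splits(small_cohort, 1, 2, 0.7,
                                train_fraction=0.7)[0]
        kw = dict(seed=3, **SMOKE)
        ssl = train_ssl(MeanTeacherConfig(**kw), plan, small_patches,
                        BackboneSpec(), cache=shared_cache)
        sl = train_sl(MeanTeacherConfig(**kw), plan, small_patches,
                      BackboneSpec(), cache=shared_cache)
        assert [e["ce"] for e in ssl.log] == \
            pytest.approx([e["ce"] for e in sl.log])

    def test_save_load_round_trip(self, split_5pct, small_patches,
                                  shared_cache, tmp_path):
        cfg = MeanTeacherConfig(seed=2, **SMOKE)
        m = train_ssl(cfg, split_5pct, small_patches, BackboneSpec(),
                      cache=shared_cache)
        path = tmp_path / "model.json"
        m.save(path)
        from histossl import TrainedModel
        back = TrainedModel.load(path)
        assert back.classes == m.classes
        for a, b in zip(m.network.parameters(), back.network.parameters()):
            assert np.allclose(a, b)


class TestLearnability:
    def test_small_cnn_separates_classes_fully_supervised(self, shared_cache):
        """A two-convolution net trained on 500 synthetic patches per class
        reaches >= 0.95 AUC on a held-out synthetic set."""
        from histossl import auc, balanced_pool
        from histossl.datasets import SplitPlan

        train = balanced_pool({"tumor": 500, "normal": 500}, seed=31)
        test = balanced_pool({"tumor": 150, "normal": 150}, seed=77)
        for p in test:  # keep ids distinct from the training pool
            p.patch_id = "held_" + p.patch_id
        plan = SplitPlan(replicate_id=0, seed=0, train_fraction=0.5,
                         train_slide_ids={"pool_tumor", "pool_normal"},
                         labeled_patch_ids={p.patch_id for p in train})
        cfg = supervised_defaults(seed=13, epochs=30, steps_per_epoch=10,
                                  pretrain_epochs=0, early_stop_patience=30)
        model = train_sl(cfg, plan, train, BackboneSpec("tiny_cnn", 16),
                         cache=shared_cache)
        kept = shared_cache.add(test)
        probs = model.network.predict_proba(np.stack(
            [shared_cache.image(p) / 127.5 - 1.0 for p in kept]))
        score = auc(probs[:, model.positive_class_index()],
                    [int(p.label == "tumor") for p in kept])
        assert score >= 0.95
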