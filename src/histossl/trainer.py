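"""Mean-teacher semi-supervised training and the supervised baseline.

The student network is trained by Adam on the sum of a classification cost
(softmax cross-entropy on the labeled part of each mini-batch) and a
consistency cost (mean squared error between the student's predicted
probabilities and the teacher's pseudo-label probabilities on the unlabeled
part), plus an L2 weight penalty.  The teacher starts as an exact copy of the
student and is updated once per epoch as an exponential moving average of the
student parameters, theta_t <- alpha * theta_t + (1 - alpha) * theta_s; the
teacher is the model used at inference time.

Mini-batches preserve the labeled:unlabeled proportion of the training pools.
One-tenth of the labeled patches is held out (stratified) as a validation set;
early stopping triggers after ``early_stop_patience`` epochs without a
validation-accuracy improvement, but never during the first
``pretrain_epochs`` epochs, and the best-validation weights are restored at
exit.

Default hyperparameters are the published colorectal settings (batch 128,
EMA smoothing 0.95, 500 x 100 steps, patience 80, pre-training 50, L2 1e-4);
desk-scale experiments override the sizes, not the rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .cohort import DEFAULT_TEXTURES, PatchRecord, render_record
from .datasets import SplitPlan, apply_plan, round_half_up
from .preprocess import PreprocessConfig, augment, downsample_area, \
    is_background, normalize, resize_bilinear

logger = logging.getLogger(__name__)


@dataclass
class MeanTeacherConfig:
    """Training hyperparameters; defaults are the published CRC settings."""

    batch_size: int = 128
    labeled_fraction_in_batch: float | None = None  # None -> pool proportion
    ema_alpha: float = 0.95
    learning_rate: float = 1e-3
    lr_decay_rate: float | None = None  # per-epoch exponential decay
    epochs: int = 500
    steps_per_epoch: int = 100
    early_stop_patience: int = 80
    pretrain_epochs: int = 50
    l2_coefficient: float = 1e-4
    validation_fraction: float = 0.1
    n_classes: int = 2
    seed: int = 0
    augment: bool = True
    hard_pseudo_labels: bool = False
    consistency_on_labeled: bool = False
    dual_views: bool = False  # independent augmented views for student/teacher

    def __post_init__(self) -> None:
        if not 0.0 <= self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must lie in [0, 1]")
        if self.pretrain_epochs >= self.epochs and self.epochs > 0:
            raise ValueError("pretrain_epochs must be < epochs")
        if self.labeled_fraction_in_batch is not None and not (
                0.0 < self.labeled_fraction_in_batch <= 1.0):
            raise ValueError("labeled_fraction_in_batch must lie in (0, 1]")


def supervised_defaults(**overrides) -> MeanTeacherConfig:
    """The published supervised baseline settings (batch 64, patience 50,
    learning rate 1e-3 with 0.99 per-epoch exponential decay)."""
    base = dict(batch_size=64, early_stop_patience=50, pretrain_epochs=0,
                learning_rate=1e-3, lr_decay_rate=0.99)
    base.update(overrides)
    return MeanTeacherConfig(**base)


@dataclass
class TrainerState:
    epoch: int = 0
    best_val_accuracy: float = -np.inf
    epochs_since_improvement: int = 0


def batch_counts(n_labeled: int, n_unlabeled: int, batch_size: int,
                 labeled_fraction: float | None = None) -> tuple[int, int]:
    """Labeled/unlabeled counts in one mini-batch.

    The labeled share follows the pool proportion unless overridden, rounded
    to the nearest integer and clamped to at least one labeled sample.
    """
    if n_labeled < 1:
        raise ValueError("labeled pool is empty; supervised cost undefined")
    if n_unlabeled == 0:
        return batch_size, 0
    prop = (labeled_fraction if labeled_fraction is not None
            else n_labeled / (n_labeled + n_unlabeled))
    n_lab = max(1, round_half_up(batch_size * prop))
    n_lab = min(n_lab, batch_size)
    return n_lab, batch_size - n_lab


def compose_batch(labeled_pool: list, unlabeled_pool: list,
                  config: MeanTeacherConfig, seed: int) -> tuple[list, list]:
    """Draw one mini-batch preserving the pool proportion (with replacement
    across steps; each draw is a uniform sample without replacement)."""
    n_lab, n_unl = batch_counts(len(labeled_pool), len(unlabeled_pool),
                                config.batch_size,
                                config.labeled_fraction_in_batch)
    rng = np.random.default_rng(seed)
    li = rng.choice(len(labeled_pool), size=min(n_lab, len(labeled_pool)),
                    replace=n_lab > len(labeled_pool))
    part_l = [labeled_pool[i] for i in li]
    part_u = []
    if n_unl and unlabeled_pool:
        ui = rng.choice(len(unlabeled_pool), size=n_unl,
                        replace=n_unl > len(unlabeled_pool))
        part_u = [unlabeled_pool[i] for i in ui]
    return part_l, part_u


def total_loss(student_labeled_logits: np.ndarray, labels: np.ndarray,
               student_unlabeled_probs: np.ndarray,
               teacher_unlabeled_probs: np.ndarray,
               l2_term: float, l2_coefficient: float = 1e-4) -> float:
    """Classification cost + consistency cost + L2 penalty (scalar contract).

    The consistency cost averages squared probability differences over
    samples and classes; teacher probabilities are constants.
    """
    ce, _ = nn.cross_entropy(np.asarray(student_labeled_logits),
                             np.asarray(labels))
    sp = np.asarray(student_unlabeled_probs, dtype=float)
    tp = np.asarray(teacher_unlabeled_probs, dtype=float)
    if sp.shape != tp.shape:
        raise ValueError("student and teacher output shapes differ")
    consistency = float(((sp - tp) ** 2).mean()) if sp.size else 0.0
    return ce + consistency + l2_coefficient * float(l2_term)


def ema_update(teacher_params: list[np.ndarray],
               student_params: list[np.ndarray],
               ema_alpha: float) -> list[np.ndarray]:
    """theta_t <- alpha * theta_t + (1 - alpha) * theta_s (new arrays)."""
    if len(teacher_params) != len(student_params):
        raise ValueError("parameter list length mismatch")
    out = []
    for t, s in zip(teacher_params, student_params):
        if t.shape != s.shape:
            raise ValueError(f"parameter shape mismatch {t.shape} vs {s.shape}")
        out.append(ema_alpha * t + (1.0 - ema_alpha) * s)
    return out


@dataclass
class TrainedModel:
    """An inference-ready network with its provenance.

    For mean-teacher training the wrapped network is the teacher.
    """

    network: nn.Network
    backbone_spec: nn.BackboneSpec
    config: MeanTeacherConfig
    preprocess: PreprocessConfig
    classes: list[str]
    log: list[dict] = field(default_factory=list)
    mode: str = "ssl"

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        x = []
        for im in images:
            if im.shape[0] != self.backbone_spec.input_size:
                im = downsample_area(im, self.backbone_spec.input_size) \
                    if im.shape[0] > 2 * self.backbone_spec.input_size \
                    else resize_bilinear(im, self.backbone_spec.input_size)
            x.append(normalize(im))
        return self.network.predict_proba(np.stack(x))

    def positive_class_index(self) -> int:
        for name in ("tumor", "positive", "cancer"):
            if name in self.classes:
                return self.classes.index(name)
        return len(self.classes) - 1

    def save(self, path) -> None:
        payload = {
            "mode": self.mode,
            "classes": self.classes,
            "config": asdict(self.config),
            "backbone": asdict(self.backbone_spec),
            "preprocess": {k: v for k, v in vars(self.preprocess).items()},
            "params": [p.tolist() for p in self.network.get_params()],
            "log": self.log,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        spec = nn.BackboneSpec(**{**d["backbone"],
                                  "channels": tuple(d["backbone"]["channels"])})
        cfg = MeanTeacherConfig(**d["config"])
        pp = PreprocessConfig(**{**d["preprocess"],
                                 "zoom_range": tuple(d["preprocess"]["zoom_range"]),
                                 "color_jitter_range": tuple(
                                     d["preprocess"]["color_jitter_range"])})
        net = nn.build_backbone(spec, cfg.n_classes,
                                np.random.default_rng(0))
        net.set_params([np.asarray(p) for p in d["params"]])
        return cls(network=net, backbone_spec=spec, config=cfg, preprocess=pp,
                   classes=list(d["classes"]), log=list(d["log"]),
                   mode=d["mode"])


class PatchImageCache:
    """Working-resolution uint8 images for a set of patch records.

    Images come from disk when the record carries a path, otherwise they are
    rendered from the record's class and stored seed.  Background (glass)
    patches are filtered out on ingestion.
    """

    def __init__(self, preprocess: PreprocessConfig, textures=None):
        self.preprocess = preprocess
        self.textures = textures or DEFAULT_TEXTURES
        self._cache: dict[str, np.ndarray] = {}

    def _full_image(self, record: PatchRecord) -> np.ndarray:
        if record.path:
            from PIL import Image
            return np.asarray(Image.open(record.path).convert("RGB"))
        return render_record(record, self.textures)

    def add(self, records: list[PatchRecord]) -> list[PatchRecord]:
        kept = []
        for r in records:
            if r.patch_id in self._cache:
                kept.append(r)
                continue
            img = self._full_image(r)
            if is_background(img, self.preprocess):
                continue
            self._cache[r.patch_id] = downsample_area(
                img, self.preprocess.target_size)
            kept.append(r)
        return kept

    def image(self, record: PatchRecord) -> np.ndarray:
        return self._cache[record.patch_id]


def _stratified_validation(labeled: list[PatchRecord], fraction: float,
                           rng: np.random.Generator,
                           ) -> tuple[list[PatchRecord], list[PatchRecord]]:
    """Hold out ~fraction of the labeled pool, at least one patch per class."""
    by_class: dict[str, list[PatchRecord]] = {}
    for p in labeled:
        by_class.setdefault(p.label, []).append(p)
    val, train = [], []
    for cls in sorted(by_class):
        group = sorted(by_class[cls], key=lambda p: p.patch_id)
        rng.shuffle(group)
        n_val = max(1, round_half_up(len(group) * fraction)) \
            if len(group) > 1 else 0
        val.extend(group[:n_val])
        train.extend(group[n_val:])
    if len({p.label for p in val}) < len(by_class):
        logger.warning("validation set missing a class; redrawing stratified")
    return train, val


def _features(cache: PatchImageCache, records: list[PatchRecord],
              cfg: MeanTeacherConfig, rng: np.random.Generator | None,
              ) -> np.ndarray:
    imgs = []
    for r in records:
        img = cache.image(r)
        if rng is not None and cfg.augment:
            img = augment(img, cache.preprocess, int(rng.integers(2 ** 31)))
        imgs.append(normalize(img))
    return np.stack(imgs)


def _accuracy(net: nn.Network, x: np.ndarray, y: np.ndarray) -> float:
    return float((net.forward(x).argmax(axis=1) == y).mean())


def _l2_penalty_and_grads(net: nn.Network, coeff: float) -> float:
    """Adds 2*coeff*W to the stored weight gradients; returns the penalty."""
    penalty = 0.0
    for layer in net.layers:
        if layer.params:
            w = layer.params[0]
            penalty += float((w ** 2).sum())
            layer.grads[0] += 2.0 * coeff * w
    return coeff * penalty


def _train(config: MeanTeacherConfig, split_plan: SplitPlan,
           patches: list[PatchRecord], backbone_spec: nn.BackboneSpec,
           preprocess: PreprocessConfig | None, textures,
           use_teacher: bool,
           cache: PatchImageCache | None = None) -> TrainedModel:
    preprocess = (cache.preprocess if cache is not None else
                  preprocess or PreprocessConfig(
                      target_size=backbone_spec.input_size))
    labeled, unlabeled, _ = apply_plan(patches, split_plan)
    if not labeled:
        raise ValueError("split plan has no labeled training patches")
    if not use_teacher:
        unlabeled = []

    ss = np.random.SeedSequence(config.seed)
    r_init, r_split, r_batch, r_aug = [np.random.default_rng(s)
                                       for s in ss.spawn(4)]

    classes = sorted({p.label for p in labeled})
    if len(classes) > config.n_classes:
        raise ValueError(f"found {len(classes)} classes, config allows "
                         f"{config.n_classes}")
    cls_index = {c: i for i, c in enumerate(classes)}

    if cache is None:
        cache = PatchImageCache(preprocess, textures)
    labeled = cache.add(labeled)
    unlabeled = cache.add(unlabeled)

    train_lab, val = _stratified_validation(labeled,
                                            config.validation_fraction, r_split)
    x_val = _features(cache, val, config, None) if val else None
    y_val = np.array([cls_index[p.label] for p in val]) if val else None

    student = nn.build_backbone(backbone_spec, config.n_classes, r_init)
    teacher = nn.build_backbone(backbone_spec, config.n_classes, r_init) \
        if use_teacher else None
    if teacher is not None:
        teacher.set_params(student.get_params())  # exact initial copy
    opt = nn.Adam(student.parameters(), lr=config.learning_rate)

    state = TrainerState()
    eval_net = teacher if use_teacher else student
    best_params = eval_net.get_params()
    log: list[dict] = []

    n_lab_b, n_unl_b = batch_counts(len(train_lab), len(unlabeled),
                                    config.batch_size,
                                    config.labeled_fraction_in_batch)

    for epoch in range(config.epochs):
        lr = config.learning_rate * (
            config.lr_decay_rate ** epoch if config.lr_decay_rate else 1.0)
        ep_ce = ep_cons = ep_total = 0.0
        lab_order = r_batch.permutation(len(train_lab))
        unl_order = r_batch.permutation(len(unlabeled)) if unlabeled else None
        for step in range(config.steps_per_epoch):
            li = [lab_order[(step * n_lab_b + j) % len(train_lab)]
                  for j in range(n_lab_b)]
            batch_l = [train_lab[i] for i in li]
            batch_u = []
            if n_unl_b and unlabeled:
                ui = [unl_order[(step * n_unl_b + j) % len(unlabeled)]
                      for j in range(n_unl_b)]
                batch_u = [unlabeled[i] for i in ui]

            x_l = _features(cache, batch_l, config, r_aug)
            y_l = np.array([cls_index[p.label] for p in batch_l])

            if batch_u:
                if config.dual_views:
                    x_u_student = _features(cache, batch_u, config, r_aug)
                    x_u_teacher = _features(cache, batch_u, config, r_aug)
                else:
                    x_u_student = _features(cache, batch_u, config, r_aug)
                    x_u_teacher = x_u_student
                x_all = np.concatenate([x_l, x_u_student])
                logits_all = student.forward(x_all)
                ce, g_ce = nn.cross_entropy(logits_all[:len(batch_l)], y_l)
                t_probs = teacher.predict_proba(x_u_teacher)
                if config.hard_pseudo_labels:
                    hard = np.zeros_like(t_probs)
                    hard[np.arange(len(t_probs)), t_probs.argmax(axis=1)] = 1.0
                    t_probs = hard
                cons, g_cons = nn.mse_probs(logits_all[len(batch_l):], t_probs)
                g = np.concatenate([g_ce, g_cons])
            else:
                logits = student.forward(x_l)
                ce, g_ce = nn.cross_entropy(logits, y_l)
                cons, g = 0.0, g_ce
            student.backward(g)
            penalty = _l2_penalty_and_grads(student, config.l2_coefficient)
            opt.step(student.gradients(), lr=lr)
            ep_ce += ce
            ep_cons += cons
            ep_total += ce + cons + penalty

        if teacher is not None:
            teacher.set_params(ema_update(teacher.parameters(),
                                          student.parameters(),
                                          config.ema_alpha))
        val_acc = (_accuracy(eval_net, x_val, y_val)
                   if x_val is not None else np.nan)
        sp = max(1, config.steps_per_epoch)
        log.append({"epoch": epoch, "ce": ep_ce / sp,
                    "consistency": ep_cons / sp, "total": ep_total / sp,
                    "val_acc": val_acc, "lr": lr})

        state.epoch = epoch
        if np.isnan(val_acc) or val_acc > state.best_val_accuracy + 1e-6:
            state.best_val_accuracy = val_acc
            state.epochs_since_improvement = 0
            best_params = eval_net.get_params()
        else:
            if val_acc >= state.best_val_accuracy - 1e-6:
                # tie with the best: prefer the more-trained weights
                best_params = eval_net.get_params()
            state.epochs_since_improvement += 1
            if (epoch >= config.pretrain_epochs and
                    state.epochs_since_improvement >= config.early_stop_patience):
                logger.info("early stop at epoch %d (best val acc %.4f)",
                            epoch, state.best_val_accuracy)
                break

    eval_net.set_params(best_params)
    return TrainedModel(network=eval_net, backbone_spec=backbone_spec,
                        config=config, preprocess=preprocess, classes=classes,
                        log=log, mode="ssl" if use_teacher else "sl")


def train_ssl(config: MeanTeacherConfig, split_plan: SplitPlan,
              patches: list[PatchRecord], backbone_spec: nn.BackboneSpec,
              preprocess: PreprocessConfig | None = None,
              textures=None, cache: PatchImageCache | None = None,
              ) -> TrainedModel:
    """Mean-teacher training; returns the teacher model for inference."""
    return _train(config, split_plan, patches, backbone_spec, preprocess,
                  textures, use_teacher=True, cache=cache)


def train_sl(config: MeanTeacherConfig, split_plan: SplitPlan,
             patches: list[PatchRecord], backbone_spec: nn.BackboneSpec,
             preprocess: PreprocessConfig | None = None,
             textures=None, cache: PatchImageCache | None = None,
             ) -> TrainedModel:
    """Supervised training on the labeled patches only."""
    return _train(config, split_plan, patches, backbone_spec, preprocess,
                  textures, use_teacher=False, cache=cache)
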