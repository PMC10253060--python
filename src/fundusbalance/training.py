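"""Two-stage training: binary pre-training on excess majority-class data,
then balanced 4-class fine-tuning.

Stage one trains a binary Normal-vs-DR classifier on the images routed to
the pre-training subset by the threshold split, with cross-entropy
weights 1:2 favouring DR.  Stage two replaces the classification head
with a 4-output one, re-applies the feature-extractor freeze, and trains
on the balanced fine-tuning data with class weights 1 / 0.9 / 1.5 / 1.2
(Normal / Glaucoma / AMD / DR).  Both stages share the same recipe:
rectified-Adam, cosine-annealed learning rate stepped per epoch, and
early stopping on validation loss with a 5-epoch patience, restoring the
best-epoch weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from PIL import Image
from sklearn.model_selection import train_test_split

from . import nn
from .corpus import CorpusManifest, ManifestError
from .labels import CLASSES, CLASS_INDEX, DR, FINETUNE_WEIGHTS, NORMAL, PRETRAIN_WEIGHTS
from .preprocess import AugmentationConfig, PreprocessConfig, augment, resize_normalize
from .synthetic import load_pixels

__all__ = [
    "BackboneSpec",
    "CosineSchedule",
    "TrainConfig",
    "StageResult",
    "EarlyStopper",
    "build_model",
    "register_backbone",
    "cosine_lr",
    "weighted_cross_entropy",
    "pretrain",
    "finetune",
    "predict_probs",
]


class BackboneError(ValueError):
    """Raised for unknown or invalid backbone specifications."""


@dataclass
class BackboneSpec:
    """Which feature extractor to build and how much of it to freeze."""

    family: str = "tiny-cnn"
    pretrained: bool = False
    n_outputs: int = 2
    freeze_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.freeze_fraction <= 1.0:
            raise BackboneError("freeze_fraction must be in [0, 1]")
        if self.n_outputs not in (2, 4):
            raise BackboneError("n_outputs must be 2 or 4")


@dataclass
class CosineSchedule:
    t_max: int = 20
    eta_min: float = 1e-5
    eta_max: float = 3e-4

    def __post_init__(self) -> None:
        if not self.eta_min < self.eta_max:
            raise ValueError("eta_min must be < eta_max")


@dataclass
class TrainConfig:
    """Hyperparameters of one training stage."""

    learning_rate: float = 3e-4
    batch_size: int = 32
    weight_decay: float = 1e-5
    schedule: CosineSchedule = field(default_factory=CosineSchedule)
    patience: int = 5
    class_weights: tuple[float, ...] | None = None
    max_epochs: int = 10
    val_fraction: float = 0.1
    optimizer: str = "radam"
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")


@dataclass
class StageResult:
    model: nn.Model
    history: list[dict]
    best_epoch: int
    stopped_early: bool


# ---------------------------------------------------------------------------
# backbone registry

def _build_tiny_cnn(spec: BackboneSpec, input_size: int, rng: np.random.Generator) -> nn.Model:
    # 4 conv blocks (conv-relu-pool), channels 8/16/32/64; ~25k parameters.
    channels = (8, 16, 32, 64)
    if input_size % 16 != 0:
        raise BackboneError("tiny-cnn needs the input size divisible by 16")
    blocks: list[list[nn.Layer]] = []
    cin = 3
    for i, cout in enumerate(channels):
        blocks.append([nn.Conv2D(cin, cout, rng, name=f"conv{i}"),
                       nn.BatchNorm2D(cout, name=f"bn{i}"), nn.ReLU(), nn.MaxPool2()])
        cin = cout
    blocks[-1].append(nn.Flatten())
    head_in = channels[-1] * (input_size // 16) ** 2
    head = nn.Linear(head_in, spec.n_outputs, rng, name="fc")
    return nn.Model(blocks, head, head_in, freeze_fraction=spec.freeze_fraction)


_BACKBONES: dict[str, Callable[[BackboneSpec, int, np.random.Generator], nn.Model]] = {
    "tiny-cnn": _build_tiny_cnn,
}


def register_backbone(family: str, builder) -> None:
    """Register a builder for an additional backbone family.

    Large ImageNet-pretrained families (resnet50, convnext-tiny,
    regnet-y-3.2gf) plug in through this hook when a deep-learning
    framework providing them is available.
    """
    _BACKBONES[family] = builder


def build_model(spec: BackboneSpec, input_size: int = 32,
                rng: np.random.Generator | int | None = 0) -> nn.Model:
    """Build a backbone + randomly initialized head per the spec.

    The first ceil(freeze_fraction * n_blocks) feature-extractor blocks
    are marked non-trainable; the head is always trainable.
    """
    if spec.family not in _BACKBONES:
        raise BackboneError(
            f"unknown backbone family {spec.family!r}; registered: {sorted(_BACKBONES)}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _BACKBONES[spec.family](spec, input_size, rng)


# ---------------------------------------------------------------------------
# loss and schedule

def cosine_lr(t: int, sched: CosineSchedule) -> float:
    """Cosine-annealed learning rate at integer epoch t.

    eta(t) = eta_min + (eta_max - eta_min) (1 + cos(pi t / T_max)) / 2,
    evaluated at every epoch: eta(0) = eta_max, eta(T_max) = eta_min,
    monotone nonincreasing over one annealing cycle.  Beyond T_max the
    expression is simply continued, so training longer than one cycle
    re-warms the rate, in the spirit of the warm-restart schedules this
    annealing rule comes from.
    """
    if t < 0:
        raise ValueError("epoch must be >= 0")
    return sched.eta_min + 0.5 * (sched.eta_max - sched.eta_min) * (
        1.0 + math.cos(math.pi * t / sched.t_max)
    )


def weighted_cross_entropy(
    probs: np.ndarray,
    y: np.ndarray | int,
    weights: Sequence[float],
    reduction: str = "mean",
) -> np.ndarray | float:
    """Class-weighted cross-entropy on predicted probabilities.

    Per-sample loss is -w_y log p_y; the "mean" reduction divides the sum
    by the total weight of the batch (weighted mean), so with all weights
    equal it reduces to the standard mean cross-entropy.  Probabilities
    are floored at 1e-12 instead of raising on log(0).
    """
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    w = np.asarray(weights, dtype=float)
    if p.shape[1] != w.shape[0]:
        raise ValueError(f"weight vector length {w.shape[0]} != n classes {p.shape[1]}")
    py = np.clip(p[np.arange(len(y)), y], 1e-12, None)
    losses = -w[y] * np.log(py)
    if reduction == "none":
        return losses
    if reduction == "sum":
        return float(losses.sum())
    if reduction == "mean":
        return float(losses.sum() / w[y].sum())
    raise ValueError(f"unknown reduction {reduction!r}")


class EarlyStopper:
    """Stop when validation loss has not improved for `patience` epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = math.inf
        self.best_epoch = -1
        self._since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


# ---------------------------------------------------------------------------
# data handling

class _Dataset:
    """Decoded images + integer targets, with cached eval tensors.

    Images are standardized to the target size once at load; training-time
    augmentation then operates on the resized images (resize-first order,
    matching the workflow where sizes are unified before the dynamically
    augmented training loop)."""

    def __init__(self, manifest: CorpusManifest, label_map: dict[str, int],
                 pre_cfg: PreprocessConfig, root=None):
        t = pre_cfg.target_size
        self.images = []
        for r in manifest:
            im = load_pixels(r, root)
            if im.shape[:2] != (t, t):
                im = np.asarray(Image.fromarray(im).resize((t, t), Image.BILINEAR))
            self.images.append(im)
        self.y = np.array([label_map[r.label] for r in manifest], dtype=int)
        self.pre_cfg = pre_cfg
        self._eval_x: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.images)

    def eval_tensor(self) -> np.ndarray:
        if self._eval_x is None:
            stack = np.stack([resize_normalize(im, self.pre_cfg) for im in self.images])
            self._eval_x = np.ascontiguousarray(stack.transpose(0, 3, 1, 2))
        return self._eval_x

    def train_batches(self, batch_size: int, aug_cfg: AugmentationConfig | None,
                      rng: np.random.Generator):
        order = rng.permutation(len(self.images))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            imgs = []
            for i in idx:
                im = self.images[i]
                if aug_cfg is not None:
                    im = augment(im, aug_cfg, rng)
                imgs.append(resize_normalize(im, self.pre_cfg))
            x = np.ascontiguousarray(np.stack(imgs).transpose(0, 3, 1, 2))
            yield x, self.y[idx]


def _batch_loss_grad(model: nn.Model, x, y, w):
    logits = model.forward(x, train=True)
    p = nn.softmax(logits)
    loss = weighted_cross_entropy(p, y, w, reduction="mean")
    onehot = np.zeros_like(p)
    onehot[np.arange(len(y)), y] = 1.0
    wy = np.asarray(w, dtype=float)[y]
    grad = (wy[:, None] * (p - onehot) / wy.sum()).astype(np.float32)
    return loss, grad


def _eval_loss_acc(model: nn.Model, ds: _Dataset, w, batch_size: int):
    x_all, y_all = ds.eval_tensor(), ds.y
    total, wsum, correct = 0.0, 0.0, 0
    for start in range(0, len(y_all), batch_size):
        x, y = x_all[start : start + batch_size], y_all[start : start + batch_size]
        p = nn.softmax(model.forward(x, train=False))
        total += weighted_cross_entropy(p, y, w, reduction="sum")
        wsum += np.asarray(w, dtype=float)[y].sum()
        correct += int((p.argmax(axis=1) == y).sum())
    return total / wsum, correct / len(y_all)


def fit(
    model: nn.Model,
    train_ds: _Dataset,
    val_ds: _Dataset,
    cfg: TrainConfig,
    class_weights: Sequence[float],
    aug_cfg: AugmentationConfig | None,
) -> StageResult:
    """Shared training loop for both stages."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "radam":
        opt = nn.RAdam(model.params(), weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(model.params(), weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    stopper = EarlyStopper(cfg.patience)
    history: list[dict] = []
    best_state = None
    stopped_early = False
    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(epoch, cfg.schedule)
        losses = []
        for x, y in train_ds.train_batches(cfg.batch_size, aug_cfg, rng):
            loss, grad = _batch_loss_grad(model, x, y, class_weights)
            model.backward(grad)
            opt.step(lr)
            losses.append(loss)
        val_loss, val_acc = _eval_loss_acc(model, val_ds, class_weights, cfg.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": float(val_loss), "val_accuracy": float(val_acc), "lr": lr}
        )
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        if stop:
            stopped_early = True
            break
    if cfg.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    return StageResult(model=model, history=history,
                       best_epoch=stopper.best_epoch, stopped_early=stopped_early)


# ---------------------------------------------------------------------------
# stages

def pretrain(
    corpus: CorpusManifest,
    spec: BackboneSpec,
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    root=None,
) -> StageResult:
    """Stage one: binary Normal-vs-DR training on the excess-majority subset."""
    pre_cfg = pre_cfg or PreprocessConfig(target_size=32)
    counts = corpus.counts
    bad = [c for c in CLASSES if c not in (NORMAL, DR) and counts[c] > 0]
    if bad:
        raise ManifestError(f"pre-training corpus must contain only NORMAL/DR; found {bad}")
    if counts[NORMAL] == 0 or counts[DR] == 0:
        raise ManifestError("pre-training needs both NORMAL and DR records")

    label_map = {NORMAL: 0, DR: 1}
    weights = cfg.class_weights or PRETRAIN_WEIGHTS
    if len(weights) != 2:
        raise ValueError("pre-training weight vector must have 2 entries")

    labels = [r.label for r in corpus]
    idx_train, idx_val = train_test_split(
        np.arange(len(corpus)), test_size=cfg.val_fraction,
        stratify=labels, random_state=cfg.seed % (2**32),
    )
    train_ds = _Dataset(corpus.subset(idx_train), label_map, pre_cfg, root)
    val_ds = _Dataset(corpus.subset(idx_val), label_map, pre_cfg, root)

    spec = replace(spec, n_outputs=2)
    model = build_model(spec, input_size=pre_cfg.target_size,
                        rng=np.random.default_rng(cfg.seed))
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    return fit(model, train_ds, val_ds, cfg, weights, aug_cfg)


def finetune(
    model: nn.Model,
    train_manifest: CorpusManifest,
    val_manifest: CorpusManifest,
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    root=None,
) -> StageResult:
    """Stage two: 4-class fine-tuning with a fresh head and re-applied freeze."""
    pre_cfg = pre_cfg or PreprocessConfig(target_size=32)
    if len(val_manifest) == 0:
        raise ManifestError("fine-tuning requires a nonempty validation set")
    weights = cfg.class_weights or FINETUNE_WEIGHTS
    if len(weights) != 4:
        raise ValueError(f"fine-tuning weight vector must have 4 entries, got {len(weights)}")

    rng = np.random.default_rng(cfg.seed)
    model.replace_head(4, rng)
    model.set_freeze(model.freeze_fraction)

    train_ds = _Dataset(train_manifest, CLASS_INDEX, pre_cfg, root)
    val_ds = _Dataset(val_manifest, CLASS_INDEX, pre_cfg, root)
    if aug_cfg is None:
        aug_cfg = AugmentationConfig()
    return fit(model, train_ds, val_ds, cfg, weights, aug_cfg)


def predict_probs(
    model: nn.Model,
    manifest: CorpusManifest,
    pre_cfg: PreprocessConfig,
    batch_size: int = 64,
    label_map: dict[str, int] | None = None,
    root=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax class probabilities and integer truths for a manifest (no augmentation)."""
    ds = _Dataset(manifest, label_map or CLASS_INDEX, pre_cfg, root)
    x_all = ds.eval_tensor()
    probs = [
        nn.softmax(model.forward(x_all[s : s + batch_size], train=False))
        for s in range(0, len(ds), batch_size)
    ]
    return np.concatenate(probs), ds.y
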