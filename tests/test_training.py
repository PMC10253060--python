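"""Trainer building blocks: schedule, weighted loss, freezing, optimization,
early stopping and the two stages themselves."""

import math

import numpy as np
import pytest

from fundusbalance import (CLASSES, FINETUNE_WEIGHTS, SynthesisParams,
                           generate_corpus)
from fundusbalance.corpus import ManifestError, counts_manifest
from fundusbalance.labels import AMD, DR, GLAUCOMA, NORMAL
from fundusbalance.preprocess import AugmentationConfig, PreprocessConfig
from fundusbalance import nn
from fundusbalance.training import (BackboneSpec, BackboneError, CosineSchedule,
                                    EarlyStopper, TrainConfig, build_model,
                                    cosine_lr, finetune, pretrain,
                                    weighted_cross_entropy)


# -- cosine schedule --------------------------------------------------------

def test_cosine_schedule_closed_form():
    sched = CosineSchedule(t_max=20, eta_min=1e-5, eta_max=3e-4)
    assert cosine_lr(0, sched) == pytest.approx(3e-4, rel=1e-12)
    assert cosine_lr(20, sched) == pytest.approx(1e-5, rel=1e-12)
    assert cosine_lr(10, sched) == pytest.approx(1.55e-4, rel=1e-12)
    values = [cosine_lr(t, sched) for t in range(21)]
    assert all(a >= b for a, b in zip(values, values[1:]))  # nonincreasing


# -- weighted cross-entropy -------------------------------------------------

def test_weighted_ce_certain_prediction_is_free():
    p = np.array([[0.0, 1.0]])
    assert weighted_cross_entropy(p, 1, (1.0, 2.0)) == pytest.approx(0.0, abs=1e-9)


def test_weighted_ce_per_sample_value():
    p = np.array([[0.5, 0.5]])
    loss = weighted_cross_entropy(p, 1, (1.0, 2.0), reduction="none")
    assert loss[0] == pytest.approx(2 * math.log(2), rel=1e-9)


def test_weighted_ce_weight_normalized_batch():
    # one AMD sample with p_AMD = 0.5 under the fine-tuning weights:
    # 1.5 ln2 / 1.5 = ln2
    p = np.zeros((1, 4))
    p[0] = [0.5 / 3, 0.5 / 3, 0.5, 0.5 / 3]
    loss = weighted_cross_entropy(p, CLASSES.index(AMD), FINETUNE_WEIGHTS)
    assert loss == pytest.approx(math.log(2), rel=1e-9)


def test_weighted_ce_reduces_to_plain_ce():
    rng = np.random.default_rng(0)
    raw = rng.random((16, 4))
    p = raw / raw.sum(axis=1, keepdims=True)
    y = rng.integers(0, 4, 16)
    ours = weighted_cross_entropy(p, y, (1.0, 1.0, 1.0, 1.0))
    plain = float(-np.log(p[np.arange(16), y]).mean())
    assert ours == pytest.approx(plain, rel=1e-12)


def test_weighted_ce_floors_zero_probability():
    p = np.array([[1.0, 0.0]])
    loss = weighted_cross_entropy(p, 1, (1.0, 1.0))
    assert np.isfinite(loss)


# -- freezing ---------------------------------------------------------------

def test_freeze_fraction_extremes():
    m0 = build_model(BackboneSpec(freeze_fraction=0.0), 32, 0)
    assert all(p.trainable for p in m0.params())
    m1 = build_model(BackboneSpec(freeze_fraction=1.0), 32, 0)
    feature_params = [p for b in m1.blocks for l in b for p in l.params()]
    assert not any(p.trainable for p in feature_params)
    assert all(p.trainable for p in m1.head.params())


def test_freeze_half_of_four_blocks():
    m = build_model(BackboneSpec(freeze_fraction=0.5), 32, 0)
    assert len(m.blocks) == 4
    flags = []
    for block in m.blocks:
        block_params = [p for l in block for p in l.params()]
        states = {p.trainable for p in block_params}
        assert len(states) == 1
        flags.append(states.pop())
    assert flags == [False, False, True, True]


def test_frozen_parameters_never_move():
    model = build_model(BackboneSpec(freeze_fraction=0.5), 32, 0)
    frozen_before = [p.value.copy() for p in model.params() if not p.trainable]
    opt = nn.RAdam(model.params(), weight_decay=1e-5)
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(size=(8, 3, 32, 32)).astype(np.float32)
        logits = model.forward(x)
        p = nn.softmax(logits)
        grad = (p - 0.5).astype(np.float32) / 8
        model.backward(grad)
        opt.step(3e-4)
    frozen_after = [p.value for p in model.params() if not p.trainable]
    for a, b in zip(frozen_before, frozen_after):
        assert a.tobytes() == b.tobytes()


def test_unknown_backbone_rejected():
    with pytest.raises(BackboneError):
        build_model(BackboneSpec(family="resnet50"), 32, 0)


# -- gradient oracle --------------------------------------------------------

def test_sgd_step_matches_hand_gradient():
    """One SGD step on a 1-layer softmax model equals the closed-form
    gradient-descent update."""
    rng = np.random.default_rng(3)
    head = nn.Linear(5, 3, rng)
    model = nn.Model([], head, head_in=5, freeze_fraction=0.0)
    x = rng.normal(size=(4, 5)).astype(np.float32)
    y = np.array([0, 2, 1, 2])
    w0 = head.w.value.copy()
    b0 = head.b.value.copy()

    p = nn.softmax(x @ w0 + b0)
    onehot = np.zeros_like(p)
    onehot[np.arange(4), y] = 1
    dlogits = (p - onehot) / 4
    expected_w = w0 - 0.1 * (x.T @ dlogits)
    expected_b = b0 - 0.1 * dlogits.sum(axis=0)

    logits = model.forward(x)
    probs = nn.softmax(logits)
    grad = ((probs - onehot) / 4).astype(np.float32)
    model.backward(grad)
    nn.SGD(model.params(), weight_decay=0.0).step(0.1)
    assert np.allclose(head.w.value, expected_w, rtol=1e-5, atol=1e-7)
    assert np.allclose(head.b.value, expected_b, rtol=1e-5, atol=1e-7)


# -- early stopping ---------------------------------------------------------

def test_early_stopper_scripted_sequence():
    """Loss improves once then rises: stop exactly `patience` epochs after
    the best epoch."""
    stopper = EarlyStopper(patience=5)
    losses = [0.50, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70]
    stopped_at = None
    for epoch, loss in enumerate(losses):
        if stopper.update(epoch, loss):
            stopped_at = epoch
            break
    assert stopper.best_epoch == 1
    assert stopped_at == 6  # five non-improving epochs after the best


def test_training_never_runs_past_patience(balanced_corpus):
    corpus = counts_to_pretrain(balanced_corpus)
    cfg = TrainConfig(max_epochs=30, patience=2, seed=0)
    res = pretrain(corpus, BackboneSpec(freeze_fraction=0.0), cfg,
                   PreprocessConfig(target_size=32),
                   AugmentationConfig.disabled())
    assert len(res.history) <= res.best_epoch + cfg.patience + 1


def counts_to_pretrain(manifest):
    """Restrict a manifest to its NORMAL/DR records."""
    from fundusbalance.corpus import CorpusManifest
    return CorpusManifest([r for r in manifest if r.label in (NORMAL, DR)])


# -- stages -----------------------------------------------------------------

def test_pretrain_rejects_minority_classes():
    m = counts_manifest({NORMAL: 5, GLAUCOMA: 1, DR: 5})
    with pytest.raises(ManifestError):
        pretrain(m, BackboneSpec(), TrainConfig(max_epochs=1))


def test_single_epoch_history(balanced_corpus):
    res = pretrain(counts_to_pretrain(balanced_corpus),
                   BackboneSpec(freeze_fraction=0.0),
                   TrainConfig(max_epochs=1, seed=0),
                   PreprocessConfig(target_size=32),
                   AugmentationConfig.disabled())
    assert len(res.history) == 1
    assert not res.stopped_early


def test_pretrain_learns_separable_classes():
    """Binary N-vs-DR validation accuracy clears the binomial chance band."""
    corpus = generate_corpus({NORMAL: 120, DR: 120}, SynthesisParams(), seed=21)
    cfg = TrainConfig(max_epochs=15, val_fraction=1 / 6, seed=2)
    res = pretrain(corpus, BackboneSpec(freeze_fraction=0.0), cfg,
                   PreprocessConfig(target_size=32),
                   AugmentationConfig.disabled())
    best = res.history[res.best_epoch]
    n_val = 40
    chance_band = 0.5 + 3 * np.sqrt(0.25 / n_val)
    assert best["val_accuracy"] > chance_band


def test_pretrain_deterministic_first_epoch(balanced_corpus):
    corpus = counts_to_pretrain(balanced_corpus)
    kwargs = dict(spec=BackboneSpec(freeze_fraction=0.0),
                  cfg=TrainConfig(max_epochs=1, seed=5),
                  pre_cfg=PreprocessConfig(target_size=32))
    a = pretrain(corpus, **kwargs)
    b = pretrain(corpus, **kwargs)
    assert a.history[0]["train_loss"] == b.history[0]["train_loss"]


def test_finetune_contracts(balanced_corpus):
    from fundusbalance.corpus import CorpusManifest
    records = list(balanced_corpus.records)
    train_m = CorpusManifest(records[:120])
    val_m = CorpusManifest(records[120:])
    model = build_model(BackboneSpec(n_outputs=2), 32, 0)
    with pytest.raises(ManifestError):
        finetune(model, train_m, CorpusManifest([]), TrainConfig(max_epochs=1))
    with pytest.raises(ValueError):
        finetune(model, train_m, val_m,
                 TrainConfig(max_epochs=1, class_weights=(1.0, 2.0)),
                 PreprocessConfig(target_size=32))
    res = finetune(model, train_m, val_m, TrainConfig(max_epochs=1, seed=0),
                   PreprocessConfig(target_size=32),
                   AugmentationConfig.disabled())
    assert res.model.n_outputs == 4
    assert len(res.history) == 1
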