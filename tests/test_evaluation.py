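"""Fold construction, one-vs-rest metrics, AUC and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusbalance import (aggregate, auc_ovr, confusion, evaluate_predictions,
                           make_folds, ovr_metrics, roc_band)
from fundusbalance.corpus import ManifestError, counts_manifest
from fundusbalance.labels import AMD, CLASSES, DR, GLAUCOMA, NORMAL


# -- folds ------------------------------------------------------------------

def test_fold_partition_single_class():
    m = counts_manifest({NORMAL: 20})
    plan = make_folds(m, k=10, seed=0)
    sizes = [len(plan.fold_ids(f)) for f in range(10)]
    assert sizes == [2] * 10
    seen = [rid for i in range(10) for rid in plan.iteration(i)[0]]
    assert sorted(seen) == sorted(plan.ids)  # each record tested exactly once


def test_fold_roles_disjoint_and_rotating():
    m = counts_manifest({NORMAL: 30, GLAUCOMA: 30, AMD: 30, DR: 30})
    plan = make_folds(m, k=5, seed=1)
    for i in range(5):
        test, val, train = plan.iteration(i)
        assert not set(test) & set(val)
        assert not (set(test) | set(val)) & set(train)
        assert len(test) + len(val) + len(train) == 120


def test_fold_stratification_minority_allocation():
    m = counts_manifest({NORMAL: 379, GLAUCOMA: 379, AMD: 63, DR: 379})
    plan = make_folds(m, k=10, seed=2)
    amd_ids = {r.id for r in m if r.label == AMD}
    per_fold = [len(amd_ids & set(plan.fold_ids(f))) for f in range(10)]
    assert all(c in (6, 7) for c in per_fold)


def test_folds_deterministic_and_validated():
    m = counts_manifest({NORMAL: 40, GLAUCOMA: 12, AMD: 12, DR: 12})
    a = make_folds(m, k=4, seed=3)
    b = make_folds(m, k=4, seed=3)
    assert np.array_equal(a.assignment, b.assignment)
    with pytest.raises(ValueError):
        make_folds(m, k=2, seed=0)
    with pytest.raises(ManifestError, match="AMD"):
        make_folds(counts_manifest({NORMAL: 40, AMD: 3}), k=4, seed=0)


# -- confusion matrix -------------------------------------------------------

def test_confusion_diagonal_and_off_diagonal():
    preds = [NORMAL, GLAUCOMA, AMD, DR]
    cm = confusion(preds, preds)
    assert np.array_equal(cm, np.eye(4, dtype=int))
    cm1 = confusion([DR], [NORMAL])
    assert cm1[0, 3] == 1 and cm1.sum() == 1


def test_confusion_matches_independent_tally():
    rng = np.random.default_rng(4)
    truths = rng.choice(CLASSES, 1000)
    preds = rng.choice(CLASSES, 1000)
    cm = confusion(preds, truths)
    assert cm.sum() == 1000
    for i, c in enumerate(CLASSES):
        assert cm[i].sum() == (truths == c).sum()
        assert cm[:, i].sum() == (preds == c).sum()
    # brute-force recount of one arbitrary cell
    assert cm[1, 2] == sum(1 for p, t in zip(preds, truths)
                           if t == GLAUCOMA and p == AMD)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion([NORMAL], [NORMAL, DR])


# -- one-vs-rest metrics ----------------------------------------------------

def test_ovr_perfect_classifier():
    cm = np.diag([10, 10, 10, 10])
    for c in range(4):
        m = ovr_metrics(cm, c)
        assert (m["accuracy"], m["f1"], m["sensitivity"], m["specificity"]) == \
            (100.0, 100.0, 100.0, 100.0)


def test_ovr_degenerate_conventions():
    cm = np.array([[5, 0], [0, 0]])  # class 1 absent and never predicted
    m = ovr_metrics(cm, 1)
    assert m["sensitivity"] == 0.0 and "sensitivity" in m["degenerate"]
    assert m["specificity"] == 100.0
    assert m["f1"] == 0.0 and "f1" in m["degenerate"]


def test_ovr_hand_arithmetic():
    cm = np.array([[50, 10], [5, 35]])
    m = ovr_metrics(cm, 0)
    assert m["sensitivity"] == pytest.approx(83.33, abs=0.01)
    assert m["specificity"] == pytest.approx(87.5, abs=1e-9)
    assert m["f1"] == pytest.approx(86.96, abs=0.01)
    assert m["accuracy"] == pytest.approx(85.0, abs=1e-9)


def test_binary_sensitivity_specificity_duality():
    rng = np.random.default_rng(5)
    cm = rng.integers(0, 30, (2, 2))
    cm[0, 0] += 1
    cm[1, 1] += 1
    assert ovr_metrics(cm, 0)["sensitivity"] == pytest.approx(
        ovr_metrics(cm, 1)["specificity"])


def test_ovr_tp_sums_to_trace():
    rng = np.random.default_rng(6)
    cm = rng.integers(0, 20, (4, 4))
    tps = [cm[c, c] for c in range(4)]
    assert sum(tps) == np.trace(cm)


# -- AUC --------------------------------------------------------------------

def brute_force_auc(scores, truths):
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


def test_auc_endpoints():
    assert auc_ovr([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 100.0
    assert auc_ovr([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 50.0
    assert auc_ovr([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 75.0


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc_ovr([0.5, 0.6], [1, 1])


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_auc_matches_pair_counting(data):
    n = data.draw(st.integers(min_value=2, max_value=40))
    scores = data.draw(st.lists(
        st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]),
        min_size=n, max_size=n))
    truths = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if sum(truths) in (0, n):
        truths[0] = 1 - truths[0]
    assert auc_ovr(scores, truths) == pytest.approx(
        brute_force_auc(scores, truths), abs=1e-9)


# -- aggregation and ROC bands ----------------------------------------------

def _report_from_predictions(seed, accuracy_boost=0.0):
    rng = np.random.default_rng(seed)
    truths = rng.integers(0, 4, 200)
    probs = rng.dirichlet(np.ones(4), size=200)
    boost = np.zeros((200, 4))
    boost[np.arange(200), truths] = accuracy_boost
    probs = probs + boost
    probs /= probs.sum(axis=1, keepdims=True)
    return evaluate_predictions(probs, truths)


def test_aggregate_identical_reports_zero_std():
    r = _report_from_predictions(0)
    summary = aggregate([r, r, r])
    for metrics in summary.per_class.values():
        for mean, std in metrics.values():
            assert std == pytest.approx(0.0, abs=1e-12)
    assert summary.overall_accuracy[1] == pytest.approx(0.0, abs=1e-12)


def test_aggregate_population_std():
    a = _report_from_predictions(1)
    b = _report_from_predictions(2)
    a.per_class[GLAUCOMA]["auc"] = 90.0
    b.per_class[GLAUCOMA]["auc"] = 94.0
    summary = aggregate([a, b], ddof=0)
    mean, std = summary.per_class[GLAUCOMA]["auc"]
    assert mean == pytest.approx(92.0)
    assert std == pytest.approx(2.0)


def test_macro_is_unweighted_class_mean():
    r = _report_from_predictions(3, accuracy_boost=0.3)
    assert r.macro["f1"] == pytest.approx(
        np.mean([r.per_class[c]["f1"] for c in CLASSES]))


def test_aggregate_requires_two_reports():
    with pytest.raises(ValueError):
        aggregate([_report_from_predictions(0)])


def test_roc_band_identical_and_mixed_curves():
    diag = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
    grid, mean, std = roc_band([diag, diag])
    assert np.allclose(mean, grid)
    assert np.allclose(std, 0.0)

    steep = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0, 1.0]))
    grid, mean, std = roc_band([diag, steep])
    i = np.argmin(np.abs(grid - 0.5))
    assert mean[i] == pytest.approx(0.75)
    assert std[i] == pytest.approx(0.25)


def test_roc_band_errors():
    diag = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        roc_band([diag])
    with pytest.raises(ValueError):
        roc_band([diag, (np.array([0.0]), np.array([0.0]))])


def test_overall_accuracy_from_trace():
    r = _report_from_predictions(7, accuracy_boost=0.5)
    cm = r.cm
    assert r.overall_accuracy == pytest.approx(100.0 * np.trace(cm) / cm.sum())
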