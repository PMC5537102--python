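"""Confusion metrics, ROC/AUC against the pairwise oracle, CV plans."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thyroprep import (ValidationError, confusion_metrics, make_cv_plan,
                       roc_auc)

from conftest import brute_force_auc


def test_perfect_agreement():
    y = np.array([0, 1, 0, 1, 1])
    rep = confusion_metrics(y, y)
    assert rep.accuracy == 1.0 and rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_hand_counted_confusion():
    # (TP, FP, TN, FN) = (8, 1, 9, 2)
    truth = np.array([1] * 8 + [0] * 1 + [0] * 9 + [1] * 2)
    pred = np.array([1] * 8 + [1] * 1 + [0] * 9 + [0] * 2)
    rep = confusion_metrics(pred, truth)
    assert rep.confusion == (8, 1, 9, 2)
    assert rep.accuracy == pytest.approx(17 / 20)
    assert rep.sensitivity == pytest.approx(0.8)
    assert rep.specificity == pytest.approx(0.9)


def test_all_benign_truth_flags_undefined_sensitivity():
    rep = confusion_metrics(np.zeros(5, dtype=int), np.zeros(5, dtype=int))
    assert rep.sensitivity is None
    assert any("sensitivity" in u for u in rep.undefined)


def test_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        confusion_metrics([0, 1], [0, 1, 1])


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_auc_equals_pairwise_rank_statistic(data):
    n = data.draw(st.integers(min_value=4, max_value=200))
    truth = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if truth.sum() == 0:
        truth[0] = 1
    if truth.sum() == n:
        truth[0] = 0
    # coarse score grid to provoke ties
    scores = np.array(data.draw(st.lists(st.integers(0, 10), min_size=n, max_size=n)),
                      dtype=float)
    auc, _ = roc_auc(scores, truth)
    assert auc == pytest.approx(brute_force_auc(scores, truth), abs=1e-12)


def test_auc_extremes():
    truth = np.array([0, 0, 0, 1, 1, 1])
    assert roc_auc(np.array([.1, .2, .3, .7, .8, .9]), truth)[0] == 1.0
    assert roc_auc(np.full(6, 0.5), truth)[0] == 0.5


def test_auc_on_twelve_hand_listed_pairs():
    scores = np.array([0.9, 0.8, 0.8, 0.7, 0.6, 0.55, 0.5, 0.5, 0.4, 0.3, 0.2, 0.1])
    truth = np.array([1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0])
    auc, points = roc_auc(scores, truth)
    assert auc == pytest.approx(brute_force_auc(scores, truth))
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    assert fpr == sorted(fpr) and tpr == sorted(tpr)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    scores = rng.uniform(size=50)
    truth = rng.integers(0, 2, size=50)
    truth[0], truth[1] = 0, 1
    base, _ = roc_auc(scores, truth)
    for f in (lambda s: 3 * s + 2, np.exp, lambda s: s ** 3):
        assert roc_auc(f(scores), truth)[0] == pytest.approx(base)


def test_auc_requires_both_classes():
    with pytest.raises(ValidationError):
        roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


@settings(deadline=None, max_examples=40)
@given(tp=st.integers(0, 30), fp=st.integers(0, 30),
       tn=st.integers(0, 30), fn=st.integers(0, 30))
def test_metric_identities_on_random_confusions(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    if n == 0:
        return
    truth = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
    pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
    rep = confusion_metrics(pred, truth)
    assert rep.confusion == (tp, fp, tn, fn)
    assert rep.accuracy == pytest.approx((tp + tn) / n)
    if tp + fn:
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
    if tn + fp:
        assert rep.specificity == pytest.approx(tn / (tn + fp))


def test_cv_exact_division():
    plan = make_cv_plan(list(range(20)), [i % 2 for i in range(20)], k=10, seed=1)
    sizes = [len(plan.fold_cases(f)) for f in range(10)]
    assert sizes == [2] * 10


def test_cv_61_cases_pigeonhole():
    labels = [1] * 50 + [0] * 11
    plan = make_cv_plan(list(range(61)), labels, k=10, seed=2)
    sizes = sorted(len(plan.fold_cases(f)) for f in range(10))
    assert set(sizes) <= {6, 7} and sum(sizes) == 61


def test_cv_deterministic_and_leak_free():
    ids = [f"case{i}" for i in range(23)]
    labels = [i % 3 == 0 for i in range(23)]
    a = make_cv_plan(ids, labels, k=5, seed=7)
    b = make_cv_plan(ids, labels, k=5, seed=7)
    assert a.fold_of == b.fold_of
    assert sorted(a.fold_of) == sorted(ids)  # every case in exactly one fold


def test_cv_stratification_balances_classes():
    labels = [1] * 40 + [0] * 20
    plan = make_cv_plan(list(range(60)), labels, k=10, seed=3)
    for f in range(10):
        cases = plan.fold_cases(f)
        pos = sum(1 for c in cases if labels[c])
        assert pos == 4 and len(cases) - pos == 2


def test_cv_rejects_more_folds_than_cases():
    with pytest.raises(ValidationError):
        make_cv_plan([1, 2, 3], [0, 1, 0], k=5, seed=0)
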