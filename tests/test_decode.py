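"""ANOVA-F selection, linear SVM, cross-validation, confusion metrics."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_sample_set
from fmvpa import decode
from fmvpa.decode import ConfusionMatrix

# confusion matrices as printed for the two encoding conditions
FM_MATRIX = ConfusionMatrix(tp=161, fn=119, fp=113, tn=167)
EE_MATRIX = ConfusionMatrix(tp=173, fn=134, fp=136, tn=171)


def test_anova_f_hand_computed_example():
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    y = np.array([True, True, True, False, False, False])
    f = decode.anova_f_per_voxel(X, y)
    assert f[0] == pytest.approx(13.5)


def test_anova_f_zero_when_means_equal():
    X = np.array([[1.0], [3.0], [1.0], [3.0]])
    y = np.array([True, True, False, False])
    assert decode.anova_f_per_voxel(X, y)[0] == pytest.approx(0.0)


def test_anova_f_equals_squared_pooled_t():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n1, n0 = rng.integers(3, 12, size=2)
        X = rng.standard_normal((n1 + n0, 5))
        y = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
        f = decode.anova_f_per_voxel(X, y)
        t = stats.ttest_ind(X[y], X[~y], axis=0).statistic
        assert np.allclose(f, t**2, atol=1e-10)


def test_anova_f_zero_within_variance_sentinel():
    X = np.array([[1.0, 2.0], [1.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    y = np.array([True, True, False, False])
    f = decode.anova_f_per_voxel(X, y)
    assert np.isinf(f[0])  # perfectly separating, zero spread
    assert f[1] == 0.0  # globally constant


def test_anova_f_requires_both_classes():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError):
        decode.anova_f_per_voxel(X, np.array([True, True, True, True]))


def test_select_top_k_order_and_ties():
    f = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    assert decode.select_top_k(f, 3).tolist() == [0, 1, 2]
    tied = np.ones(10)
    assert decode.select_top_k(tied, 5).tolist() == [0, 1, 2, 3, 4]


def test_select_top_k_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamp"):
        sel = decode.select_top_k(np.arange(4.0), 10)
    assert sel.tolist() == [0, 1, 2, 3]


def test_svm_separates_separable_points():
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    y = np.array([False, True])
    model = decode.fit_linear_classifier(X, y)
    assert model.predict(X).tolist() == [False, True]


def test_svm_label_flip_flips_decision():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 4))
    y = rng.random(20) < 0.5
    test = rng.standard_normal((5, 4))
    m = decode.fit_linear_classifier(X, y)
    m_flip = decode.fit_linear_classifier(X, ~y)
    assert np.all(np.sign(m.decision(test)) == -np.sign(m_flip.decision(test)))


def test_svm_duplication_invariant():
    # on separable data the max-margin solution ignores sample multiplicity
    rng = np.random.default_rng(2)
    X = rng.standard_normal((16, 4))
    y = X[:, 0] > 0
    X[:, 0] += np.where(y, 2.0, -2.0)
    m = decode.fit_linear_classifier(X, y)
    m2 = decode.fit_linear_classifier(np.vstack([X, X]), np.r_[y, y])
    w1 = m.weights / np.linalg.norm(m.weights)
    w2 = m2.weights / np.linalg.norm(m2.weights)
    assert np.allclose(w1, w2, atol=1e-8)


def test_svm_rejects_single_class():
    with pytest.raises(ValueError, match="single class"):
        decode.fit_linear_classifier(np.zeros((3, 2)), np.array([True, True, True]))


def test_fold_plan_three_runs_three_folds():
    ss = random_sample_set(np.random.default_rng(0))
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    assert len(plan.folds) == 3
    for train, test in plan.folds:
        assert np.intersect1d(train, test).size == 0
        assert len(np.unique(ss.runs[test])) == 1


def test_fold_plan_rejects_unknown_scheme():
    ss = random_sample_set(np.random.default_rng(0))
    with pytest.raises(ValueError, match="scheme"):
        decode.make_fold_plan(ss, "bogus")


def test_oracle_features_reach_perfect_accuracy():
    rng = np.random.default_rng(3)
    ss = random_sample_set(rng, n_voxels=10)
    ss.X[:, 0] = ss.y.astype(float) + rng.normal(0, 0.01, ss.n_samples)
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    res = decode.cross_validate(ss, plan, k=3)
    assert res.mean_accuracy == 1.0


def test_null_accuracy_near_chance():
    rng = np.random.default_rng(4)
    accs = []
    for _ in range(30):
        ss = random_sample_set(rng)
        plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
        accs.append(decode.cross_validate(ss, plan, k=16).mean_accuracy)
    assert np.mean(accs) == pytest.approx(0.5, abs=0.05)


def test_pooled_confusion_matches_weighted_fold_mean():
    rng = np.random.default_rng(5)
    ss = random_sample_set(rng, n_per_run_class=6)
    plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
    res = decode.cross_validate(ss, plan, k=8)
    weights = [len(test) for _, test in plan.folds]
    weighted = np.average(res.fold_accuracies, weights=weights)
    assert res.confusion.accuracy == pytest.approx(weighted, abs=1e-12)
    assert res.confusion.n == ss.n_samples


def test_k_insensitivity_on_null_data():
    """Raising k from 100 to 500 moves null accuracy by < 0.05."""
    rng = np.random.default_rng(6)
    diffs = []
    for _ in range(10):
        ss = random_sample_set(rng, n_voxels=600, grid_shape=(10, 10, 8))
        plan = decode.make_fold_plan(ss, decode.LEAVE_ONE_RUN_OUT)
        a100 = decode.cross_validate(ss, plan, k=100).mean_accuracy
        a500 = decode.cross_validate(ss, plan, k=500).mean_accuracy
        diffs.append(a500 - a100)
    assert abs(np.mean(diffs)) < 0.05


def test_cross_subject_plan_groups_subjects():
    rng = np.random.default_rng(7)
    sets = []
    for i in range(4):
        s = random_sample_set(rng)
        s.subjects = np.array([f"sub-{i:02d}"] * s.n_samples)
        sets.append(s)
    from fmvpa.preprocess import SampleSet

    pooled = SampleSet.concatenate(sets)
    plan = decode.make_fold_plan(pooled, decode.LEAVE_ONE_SUBJECT_OUT)
    assert len(plan.folds) == 4
    for _, test in plan.folds:
        assert len(np.unique(pooled.subjects[test])) == 1


@pytest.mark.parametrize(
    "cm,expected_precision,expected_f",
    [(FM_MATRIX, 0.59, 0.58), (EE_MATRIX, 0.56, 0.56)],
)
def test_table_metrics_match_printed_values(cm, expected_precision, expected_f):
    assert round(decode.precision(cm), 2) == expected_precision
    assert round(decode.f_score(cm), 2) == expected_f


def test_metric_edge_cases():
    assert decode.precision(ConfusionMatrix(tp=5, fp=0, fn=2, tn=3)) == 1.0
    assert decode.f_score(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5)) == 1.0
    with pytest.raises(ZeroDivisionError):
        decode.precision(ConfusionMatrix(tp=0, fp=0, fn=3, tn=3))
    with pytest.raises(ZeroDivisionError):
        decode.f_score(ConfusionMatrix(tp=0, fp=0, fn=0, tn=6))
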