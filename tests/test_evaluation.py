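"""Metrics against brute-force oracles; comparison statistics; ROI analyses."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from complexion.evaluation import (
    ConfusionMatrix,
    cohens_d,
    compare_methods,
    confusion_matrix,
    paired_ttest,
    per_class_metrics,
    roi_correlation,
    roi_importance,
)
from complexion.roi import ROI_ORDER, ROIName
from complexion.stacking import MetaFeatureTable, train_meta


def brute_force_metrics(counts):
    """Independent per-class P/R/F1 straight from the TP/FP/FN definitions."""
    k = counts.shape[0]
    p, r, f = [], [], []
    for i in range(k):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        pi = tp / (tp + fp) if tp + fp else np.nan
        ri = tp / (tp + fn) if tp + fn else np.nan
        if np.isnan(pi) or np.isnan(ri):
            fi = np.nan
        elif pi + ri == 0:
            fi = 0.0
        else:
            fi = 2 * pi * ri / (pi + ri)
        p.append(pi), r.append(ri), f.append(fi)
    return np.array(p), np.array(r), np.array(f)


def test_confusion_hand_count():
    cm = confusion_matrix([1, 1, 2], [1, 2, 2], k=2)
    np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])
    assert cm.tp().tolist() == [1, 1]
    assert cm.fp().tolist() == [0, 1]
    assert cm.fn().tolist() == [1, 0]


def test_confusion_marginals_match_frequencies():
    rng = np.random.default_rng(0)
    t = rng.integers(1, 6, 200)
    p = rng.integers(1, 6, 200)
    cm = confusion_matrix(t, p)
    for k in range(1, 6):
        assert cm.counts[k - 1].sum() == (t == k).sum()
        assert cm.counts[:, k - 1].sum() == (p == k).sum()


def test_perfect_predictions_are_diagonal():
    t = np.tile(np.arange(1, 6), 4)
    cm = confusion_matrix(t, t)
    assert (cm.counts == np.diag(np.diag(cm.counts))).all()
    rep = per_class_metrics(cm)
    assert rep.accuracy == 1.0
    np.testing.assert_array_equal(rep.precision, np.ones(5))
    np.testing.assert_array_equal(rep.f1, np.ones(5))


def test_metrics_from_published_formulas():
    """TP=8, FP=2, FN=2 gives P = R = F1 = 0.8."""
    counts = np.array([[8, 2], [2, 88]])
    rep = per_class_metrics(ConfusionMatrix(counts))
    assert rep.precision[0] == rep.recall[0] == 0.8
    assert np.isclose(rep.f1[0], 0.8)


def test_metrics_match_brute_force_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(300):
        counts = rng.integers(0, 30, (5, 5))
        rep = per_class_metrics(ConfusionMatrix(counts))
        p, r, f = brute_force_metrics(counts)
        np.testing.assert_allclose(rep.precision, p, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rep.recall, r, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rep.f1, f, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(rep.macro_f1, np.nanmean(f) if not np.isnan(f).all() else np.nan,
                                   rtol=1e-12, equal_nan=True)


def test_absent_class_excluded_from_macro():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 0] = 5
    counts[1, 1] = 5
    rep = per_class_metrics(ConfusionMatrix(counts))
    assert np.isnan(rep.precision[2])
    assert rep.macro_precision == 1.0


def test_macro_invariant_under_class_permutation():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 20, (5, 5))
    rep = per_class_metrics(ConfusionMatrix(counts))
    perm = rng.permutation(5)
    rep_p = per_class_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
    assert np.isclose(rep.macro_f1, rep_p.macro_f1)
    assert np.isclose(rep.accuracy, rep_p.accuracy)


def test_paired_ttest_examples():
    t, p = paired_ttest([1.0, 2.0, 3.0], [0.0, 2.0, 2.0])
    assert np.isclose(t, 2.0)
    t0, p0 = paired_ttest([1, 2, 3], [1, 2, 3])
    assert t0 == 0.0 and p0 == 1.0
    ts, ps = paired_ttest([0.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert np.isclose(ts, -2.0) and np.isclose(ps, p)


def test_paired_ttest_degenerate_variance():
    with pytest.raises(ValueError, match="degenerate"):
        paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="n >= 2"):
        paired_ttest([1.0], [0.0])


def test_paired_ttest_matches_scipy_exhaustively():
    """Closed form agrees with the reference implementation on every pair of
    3-element integer sequences with |values| <= 3."""
    vals = np.arange(-3, 4)
    grids = np.array(np.meshgrid(*[vals] * 6)).reshape(6, -1).T
    a, b = grids[:, :3].astype(float), grids[:, 3:].astype(float)
    d = a - b
    sd = d.std(axis=1, ddof=1)
    ok = sd > 0
    t_ref, p_ref = scipy_stats.ttest_rel(a[ok], b[ok], axis=1)
    step = 977  # sample the lattice; scipy above is vectorised over all of it
    for i, (ai, bi) in enumerate(zip(a[ok][::step], b[ok][::step])):
        t, p = paired_ttest(ai, bi)
        assert np.isclose(t, t_ref[::step][i], rtol=1e-10)
        assert np.isclose(p, p_ref[::step][i], rtol=1e-10)
    # and the closed form itself, fully vectorised over the whole lattice
    t_mine = d[ok].mean(axis=1) / (sd[ok] / np.sqrt(3))
    np.testing.assert_allclose(t_mine, t_ref, rtol=1e-12)


def test_cohens_d_paired():
    assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
    d = cohens_d([1.0, 2.0, 3.0], [0.0, 2.0, 2.0])
    assert np.isclose(d, (2 / 3) / np.std([1, 0, 1], ddof=1))
    assert np.isclose(d, 1.1547005)


def test_cohens_d_scale_invariant():
    a = np.array([1.0, 2.0, 4.0])
    b = np.array([0.5, 1.8, 2.0])
    assert np.isclose(cohens_d(a, b), cohens_d(b + 2 * (a - b), b + (a - b)))


def test_compare_methods_flags_large_effect():
    res = compare_methods([0.97, 0.98, 0.99, 0.97], [0.93, 0.94, 0.96, 0.92])
    assert res.large_effect and res.p < 0.05 and res.n == 4


def test_correlation_self_and_anticorrelation():
    codes = np.stack([np.array([1, 2, 3, 4, 5]), 6 - np.array([1, 2, 3, 4, 5]),
                      np.full(5, 3)], axis=1)
    table = MetaFeatureTable(ROI_ORDER[:3], codes, np.arange(1, 6))
    corr = roi_correlation(table)
    assert corr.values[0, 0] == 1.0
    assert np.isclose(corr.values[0, 1], -1.0)
    assert np.isnan(corr.values[0, 2])  # constant column: undefined
    np.testing.assert_allclose(corr.absolute().values[0, 1], 1.0)


def test_correlation_matches_brute_force():
    rng = np.random.default_rng(11)
    codes = rng.integers(1, 6, (500, 6))
    table = MetaFeatureTable(ROI_ORDER, codes, rng.integers(1, 6, 500))
    corr = roi_correlation(table).values
    x = codes.astype(float)
    mu = x.mean(axis=0)
    cov = (x - mu).T @ (x - mu) / len(x)
    sd = np.sqrt(np.diag(cov))
    expected = cov / np.outer(sd, sd)
    np.testing.assert_allclose(corr, expected, atol=1e-12)
    assert np.allclose(corr, corr.T) and np.all(np.abs(corr) <= 1 + 1e-12)


def _fit_xgb_table(codes, targets, rois):
    table = MetaFeatureTable(rois, codes, targets)
    model = train_meta(table.codes, table.targets, algo="xgboost", seed=0, rois=rois)
    return model, table


def test_importances_sum_to_one_and_rank_noise_last():
    rng = np.random.default_rng(2)
    targets = np.repeat(np.arange(1, 6), 40)
    codes = np.stack([targets] * 6, axis=1).astype(int)
    flips = rng.random(codes.shape) < 0.15
    codes[flips] = rng.integers(1, 6, int(flips.sum()))
    codes[:, 3] = rng.permutation(codes[:, 3])  # chin column becomes pure noise
    model, table = _fit_xgb_table(codes, targets, ROI_ORDER)
    imp = roi_importance(model, table)
    assert np.isclose(imp.sum(), 1.0, atol=1e-9)
    assert imp[3] == imp.min()


def test_single_roi_importance_is_one():
    targets = np.repeat(np.arange(1, 6), 10)
    model, table = _fit_xgb_table(targets[:, None], targets, (ROIName.NOSE,))
    np.testing.assert_allclose(roi_importance(model, table), [1.0])


def test_importance_requires_boosting_model():
    targets = np.repeat(np.arange(1, 6), 10)
    table = MetaFeatureTable((ROIName.NOSE,), targets[:, None], targets)
    knn = train_meta(table.codes, table.targets, algo="knn", rois=table.rois)
    with pytest.raises(ValueError, match="importances"):
        roi_importance(knn, table)
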