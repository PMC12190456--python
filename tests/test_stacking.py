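"""Stacking pipeline: meta tables, scaling, meta-learners, CV protocol."""

import numpy as np
import pytest

import complexion.stacking as stacking
from complexion.labels import LABELS
from complexion.roi import ROI_ORDER, ROIName
from complexion.stacking import (
    META_ALGORITHMS,
    MetaFeatureTable,
    OracleROIModel,
    ROI_CONFIGURATIONS,
    build_meta_table,
    scale_meta_features,
    stacking_cross_validate,
    train_meta,
)


def _oracle_table(n_per_class=10, rois=ROI_ORDER, seed=0):
    targets = np.repeat(np.arange(1, 6), n_per_class)
    codes = np.stack([targets] * len(rois), axis=1)
    return MetaFeatureTable(rois, codes, targets)


def _noisy_table(flip_rate, n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    targets = np.repeat(np.arange(1, 6), n_per_class)
    codes = np.stack([targets] * 6, axis=1).astype(int)
    flips = rng.random(codes.shape) < flip_rate
    codes[flips] = rng.integers(1, 6, int(flips.sum()))
    return MetaFeatureTable(ROI_ORDER, codes, targets)


def test_meta_table_validates_codes():
    with pytest.raises(ValueError, match="ordinal"):
        MetaFeatureTable(ROI_ORDER, np.full((3, 6), 7), np.array([1, 2, 3]))


def test_scale_minmax_then_zscore_example():
    table = MetaFeatureTable((ROIName.NOSE,), np.array([[1], [3], [5]]), np.array([1, 2, 3]))
    scaled, state = scale_meta_features(table)
    np.testing.assert_allclose(scaled.ravel(), [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(state.inverse_transform(scaled).ravel(), [1.0, 3.0, 5.0])


def test_scale_constant_column_maps_to_zero():
    table = MetaFeatureTable((ROIName.NOSE, ROIName.CHIN),
                             np.array([[2, 1], [2, 3], [2, 5]]), np.array([1, 2, 3]))
    scaled, _ = scale_meta_features(table)
    np.testing.assert_array_equal(scaled[:, 0], 0.0)


def test_scale_fit_rows_only():
    table = MetaFeatureTable((ROIName.NOSE,), np.array([[1], [3], [5], [5]]), np.array([1, 2, 3, 3]))
    scaled, state = scale_meta_features(table, fit_rows=[0, 1, 2])
    np.testing.assert_allclose(scaled[:3, 0].mean(), 0.0, atol=1e-9)
    with pytest.raises(ValueError, match="non-empty"):
        scale_meta_features(table, fit_rows=[])


def test_oracle_models_fill_constant_rows(small_samples):
    models = {roi: OracleROIModel() for roi in ROI_ORDER}
    table = build_meta_table(models, small_samples, ROI_ORDER)
    for row, s in zip(table.codes, small_samples):
        assert (row == s.label.code).all()


def test_meta_table_roi_subset(small_samples):
    models = {roi: OracleROIModel() for roi in ROI_CONFIGURATIONS["philtrum"]}
    table = build_meta_table(models, small_samples, ROI_CONFIGURATIONS["philtrum"])
    assert table.codes.shape[1] == 5
    assert ROIName.CHIN not in table.rois and ROIName.PHILTRUM in table.rois


def test_meta_table_missing_model_errors(small_samples):
    with pytest.raises(ValueError, match="chin"):
        build_meta_table({ROIName.NOSE: OracleROIModel()}, small_samples,
                         (ROIName.NOSE, ROIName.CHIN))


@pytest.mark.parametrize("algo", META_ALGORITHMS)
def test_meta_learners_solve_oracle_table(algo):
    table = _oracle_table()
    model = train_meta(table.codes, table.targets, algo=algo, seed=0, rois=table.rois)
    pred = model.predict_codes(table.codes)
    assert (pred == table.targets).all()


def test_unknown_meta_algo_lists_names():
    table = _oracle_table()
    with pytest.raises(ValueError, match="xgboost"):
        train_meta(table.codes, table.targets, algo="perceptron")


def test_single_class_targets_error():
    with pytest.raises(ValueError, match="two classes"):
        train_meta(np.ones((4, 2)), np.ones(4, dtype=int), algo="knn")


def test_cross_validation_protocol_oracle():
    table = _oracle_table(n_per_class=10)
    result = stacking_cross_validate(table, algo="knn", k=10, seed=0)
    assert len(result.fold_accuracies) == 10
    assert result.mean == 1.0 and result.sd == 0.0
    with pytest.raises(ValueError, match="k >= 2"):
        stacking_cross_validate(table, k=1)


def test_cross_validation_partitions_each_row_once(monkeypatch):
    """Every row is validated exactly once across the k folds."""
    rng = np.random.default_rng(0)
    n = 60
    targets = np.repeat(np.arange(1, 6), n // 5)
    codes = rng.integers(1, 6, (n, 6))
    codes[:, 0] = np.arange(n) % 5 + 1
    table = MetaFeatureTable(ROI_ORDER, codes, targets)
    seen_rows = []

    class _Spy:
        def predict_codes(self, rows):
            seen_rows.append(np.asarray(rows))
            return np.ones(len(rows), dtype=int)

    monkeypatch.setattr(stacking, "train_meta", lambda *a, **k: _Spy())
    stacking_cross_validate(table, algo="knn", k=10, seed=0)
    stacked = np.concatenate(seen_rows)
    assert stacked.shape[0] == n
    # row multiset of validated rows equals the table's rows exactly
    key = lambda arr: sorted(map(tuple, arr))
    assert key(stacked) == key(codes)


def test_cross_validation_refits_scaler_per_fold(monkeypatch):
    table = _noisy_table(0.2)
    fit_sets = []
    orig = stacking.scale_meta_features

    def spy(table_, fit_rows=None, **kw):
        fit_sets.append(None if fit_rows is None else np.sort(np.asarray(list(fit_rows))))
        return orig(table_, fit_rows=fit_rows, **kw)

    monkeypatch.setattr(stacking, "scale_meta_features", spy)
    stacking_cross_validate(table, algo="knn", k=5, seed=0)
    assert len(fit_sets) == 5
    assert all(fs is not None and fs.size < len(table.targets) for fs in fit_sets)


def test_out_of_fold_never_uses_own_model(small_samples):
    """A stub base model brands samples it trained on; with out-of-fold
    tables enabled no cell may carry the brand."""

    class _Stub:
        def __init__(self, train_ids):
            self.train_ids = train_ids

        def predict_codes(self, samples):
            return np.array([1 if s.sample_id in self.train_ids else 2 for s in samples])

    def trainer(roi, samples):
        return _Stub({s.sample_id for s in samples})

    table = build_meta_table(None, small_samples, ROI_ORDER[:2], out_of_fold=True,
                             trainer=trainer, n_folds=4, seed=0)
    assert (table.codes == 2).all()


def test_out_of_fold_requires_trainer(small_samples):
    with pytest.raises(ValueError, match="trainer"):
        build_meta_table(None, small_samples, ROI_ORDER, out_of_fold=True)


def test_oracle_beats_noisy_base_models():
    """Meta accuracy with perfect base predictions dominates noisy ones."""
    clean = stacking_cross_validate(_noisy_table(0.0), algo="xgboost", k=5, seed=1)
    noisy = stacking_cross_validate(_noisy_table(0.4, seed=1), algo="xgboost", k=5, seed=1)
    assert clean.mean >= noisy.mean


def test_roi_classifier_recovers_nose_class(small_samples):
    from complexion.backbone import TrainConfig
    from complexion.stacking import train_roi_classifier, _predict_codes

    model = train_roi_classifier(
        ROIName.NOSE, small_samples, TrainConfig(epochs=6, input_side=32, seed=0))
    codes = _predict_codes(model, small_samples)
    truth = np.array([s.label.code for s in small_samples])
    assert (codes == truth).mean() >= 0.85
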