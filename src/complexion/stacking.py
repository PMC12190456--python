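"""Multi-feature classification with machine-learning stacking.

One convolutional classifier is trained per ROI dataset; its hard class
predictions, encoded as the ordinal codes 1-5, become one column of a
numerical meta-feature table.  The table is normalised (min-max to [0, 1])
then standardised (z-score), and a second-stage learner — KNN, decision
tree, random forest, two linear variants, SVM or gradient boosting
(XGBoost) — is trained on it and assessed by stratified 10-fold
cross-validation.

Meta-features default to out-of-fold predictions: a sample's row is
produced only by base models that never saw that sample, which removes the
stacking leak.  ``out_of_fold=False`` reproduces the leaky variant where
the trained base models re-predict their own training images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .backbone import TrainConfig
from .data_model import DatasetManifest, FaceSample
from .fusion import FusionClassifier, FusionConfig, predict_fusion, train_fusion
from .labels import LABELS, N_CLASSES, ComplexionLabel, encode_label
from .roi import ROI_ORDER, ROIName

META_ALGORITHMS = ("knn", "decision_tree", "random_forest", "linear1", "linear2", "svm", "xgboost")


@dataclass
class MetaFeatureTable:
    """Rows of per-ROI ordinal prediction codes plus the true label code."""

    rois: tuple[ROIName, ...]
    codes: np.ndarray          # (n_samples, n_rois) ints in 1..5
    targets: np.ndarray        # (n_samples,) ints in 1..5
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        self.targets = np.asarray(self.targets, dtype=int)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.rois):
            raise ValueError("codes must be (n_samples, n_rois)")
        if self.codes.shape[0] != self.targets.shape[0]:
            raise ValueError("codes and targets disagree on sample count")
        for arr, what in ((self.codes, "codes"), (self.targets, "targets")):
            if arr.size and (arr.min() < 1 or arr.max() > N_CLASSES):
                raise ValueError(f"{what} must be ordinal codes in 1..{N_CLASSES}")


@dataclass
class ScalerState:
    """Min-max then z-score parameters fitted on training rows only."""

    col_min: np.ndarray
    col_max: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    use_minmax: bool = True
    use_zscore: bool = True

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.use_minmax:
            span = self.col_max - self.col_min
            safe = np.where(span > 0, span, 1.0)
            x = (x - self.col_min) / safe
            x[:, span == 0] = 0.0
        if self.use_zscore:
            safe_sd = np.where(self.sd > 0, self.sd, 1.0)
            x = (x - self.mean) / safe_sd
            x[:, self.sd == 0] = 0.0
        return x

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.use_zscore:
            x = x * np.where(self.sd > 0, self.sd, 1.0) + self.mean
        if self.use_minmax:
            span = self.col_max - self.col_min
            x = x * span + self.col_min
        return x


def scale_meta_features(
    table: MetaFeatureTable,
    fit_rows: Sequence[int] | None = None,
    use_minmax: bool = True,
    use_zscore: bool = True,
) -> tuple[np.ndarray, ScalerState]:
    """Normalise then standardise the code columns.

    Per column: min-max rescale to [0, 1] using the fit rows' extremes, then
    z-score using the fit rows' mean and sd (ddof=1, so a column like
    (1, 3, 5) maps to (-1, 0, 1)).  Constant columns map to zero.  The
    scaler is fitted on ``fit_rows`` only (all rows when omitted) and
    returned so held-out rows can be transformed without re-fitting.
    """
    x = table.codes.astype(float)
    idx = np.arange(x.shape[0]) if fit_rows is None else np.asarray(list(fit_rows), dtype=int)
    if idx.size == 0:
        raise ValueError("fit row set must be non-empty")
    fit = x[idx]
    col_min, col_max = fit.min(axis=0), fit.max(axis=0)
    span = col_max - col_min
    fit_mm = np.where(span > 0, (fit - col_min) / np.where(span > 0, span, 1.0), 0.0)
    mean = fit_mm.mean(axis=0) if use_minmax else fit.mean(axis=0)
    sd = (fit_mm if use_minmax else fit).std(axis=0, ddof=1) if idx.size > 1 else np.zeros(x.shape[1])
    state = ScalerState(col_min, col_max, mean, sd, use_minmax, use_zscore)
    return state.transform(x), state


def train_roi_classifier(
    roi: ROIName | str,
    manifest: DatasetManifest | list[FaceSample],
    config: TrainConfig | None = None,
    channels: int = 3,
    architecture: str = "tiny",
) -> FusionClassifier:
    """Train a single-crop classifier for one ROI (base learner)."""
    roi = ROIName.from_name(roi) if isinstance(roi, str) else roi
    fc = FusionConfig(roi_set=(roi,), channels=channels, architecture=architecture,
                      train=config or TrainConfig())
    model, _ = train_fusion(manifest, fc)
    return model


def _predict_codes(model, samples: list[FaceSample]) -> np.ndarray:
    """Hard ordinal predictions 1..5 for one ROI model."""
    if hasattr(model, "predict_codes"):            # oracle/stub models
        return np.asarray(model.predict_codes(samples), dtype=int)
    labels, _ = predict_fusion(model, samples)
    return np.array([encode_label(name) for name in labels], dtype=int)


class OracleROIModel:
    """Always-correct base model, for protocol tests and ceiling analyses."""

    def predict_codes(self, samples: list[FaceSample]) -> np.ndarray:
        return np.array([s.label.code for s in samples], dtype=int)


def build_meta_table(
    models: dict[ROIName, object] | None,
    manifest: DatasetManifest | list[FaceSample],
    rois: tuple[ROIName, ...] = ROI_ORDER,
    out_of_fold: bool = False,
    trainer: Callable[[ROIName, list[FaceSample]], object] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> MetaFeatureTable:
    """Collect per-ROI ordinal predictions into a meta-feature table.

    In-sample mode (``out_of_fold=False``) uses the supplied fitted
    ``models`` directly.  Out-of-fold mode re-trains base models per
    stratified fold via ``trainer(roi, train_samples)`` so that no cell is
    predicted by a model that saw its own sample.
    """
    samples = list(manifest)
    rois = tuple(ROIName.from_name(r) if isinstance(r, str) else r for r in rois)
    targets = np.array([s.label.code for s in samples], dtype=int)
    ids = [s.sample_id for s in samples]
    if out_of_fold:
        if trainer is None:
            raise ValueError("out_of_fold meta tables need a trainer(roi, samples) callable")
        codes = np.zeros((len(samples), len(rois)), dtype=int)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train_idx, val_idx in skf.split(np.zeros(len(samples)), targets):
            fold_train = [samples[i] for i in train_idx]
            fold_val = [samples[i] for i in val_idx]
            for j, roi in enumerate(rois):
                fold_model = trainer(roi, fold_train)
                codes[val_idx, j] = _predict_codes(fold_model, fold_val)
        return MetaFeatureTable(rois, codes, targets, ids)
    if models is None:
        raise ValueError("in-sample meta tables need fitted per-ROI models")
    missing = [r.value for r in rois if r not in models]
    if missing:
        raise ValueError(f"no model supplied for ROI(s): {missing}")
    cols = [_predict_codes(models[roi], samples) for roi in rois]
    return MetaFeatureTable(rois, np.stack(cols, axis=1), targets, ids)


class _RoundedRidge:
    """Ridge-regularised least squares on the ordinal codes, predictions
    rounded to the nearest valid code — the second 'linear' meta variant."""

    def __init__(self, seed: int = 0):
        self.model = Ridge(alpha=1.0, random_state=seed)

    def fit(self, x, y):
        self.model.fit(x, y)
        return self

    def predict(self, x):
        raw = np.rint(self.model.predict(x))
        return np.clip(raw, 1, N_CLASSES).astype(int)


def _make_meta(algo: str, seed: int):
    if algo == "knn":
        return KNeighborsClassifier()
    if algo == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if algo == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if algo == "linear1":
        return LogisticRegression(max_iter=1000)
    if algo == "linear2":
        return _RoundedRidge(seed)
    if algo == "svm":
        return SVC(random_state=seed)
    if algo == "xgboost":
        return XGBClassifier(random_state=seed, importance_type="gain")
    raise ValueError(f"unknown meta algorithm {algo!r}; choose one of {META_ALGORITHMS}")


class MetaModel:
    """A fitted second-stage learner over scaled meta features."""

    def __init__(self, algo: str, estimator, scaler: ScalerState, rois: tuple[ROIName, ...]):
        self.algo = algo
        self.estimator = estimator
        self.scaler = scaler
        self.rois = rois

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(np.asarray(codes, dtype=float))
        pred = self.estimator.predict(x)
        if self.algo == "xgboost":
            pred = pred + 1          # xgboost consumes 0-based targets
        return np.asarray(pred, dtype=int)

    def importances(self) -> np.ndarray:
        if not hasattr(self.estimator, "feature_importances_"):
            raise ValueError(f"meta algorithm {self.algo!r} exposes no importances")
        imp = np.asarray(self.estimator.feature_importances_, dtype=float)
        total = imp.sum()
        return imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)


def train_meta(
    rows: np.ndarray,
    targets: np.ndarray,
    algo: str = "xgboost",
    seed: int = 0,
    rois: tuple[ROIName, ...] = ROI_ORDER,
    scaler: ScalerState | None = None,
) -> MetaModel:
    """Fit one meta-learner on code rows (codes 1..5) and true codes."""
    rows = np.asarray(rows, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if np.unique(targets).size < 2:
        raise ValueError("meta training needs at least two classes present")
    if scaler is None:
        table = MetaFeatureTable(rois, rows.astype(int), targets)
        x, scaler = scale_meta_features(table)
    else:
        x = scaler.transform(rows)
    est = _make_meta(algo, seed)
    y = targets - 1 if algo == "xgboost" else targets
    est.fit(x, y)
    return MetaModel(algo, est, scaler, rois)


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean: float
    sd: float

    def __iter__(self):
        return iter(self.fold_accuracies)


def stacking_cross_validate(
    table: MetaFeatureTable,
    algo: str = "xgboost",
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a meta-learner over a meta-feature table.

    The scaler is re-fitted inside each training fold; every sample is
    validated exactly once.  Reports the k fold accuracies with their mean
    and standard deviation (ddof=1).
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2 folds")
    codes, targets = table.codes, table.targets
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, val_idx in skf.split(codes, targets):
        scaled, scaler = scale_meta_features(table, fit_rows=train_idx)
        model = train_meta(codes[train_idx], targets[train_idx], algo=algo, seed=seed,
                           rois=table.rois, scaler=scaler)
        pred = model.predict_codes(codes[val_idx])
        accs.append(float(np.mean(pred == targets[val_idx])))
    accs = np.array(accs)
    return CVResult(accs, float(accs.mean()), float(accs.std(ddof=1)))


#: Table-6-style ROI configurations: all six; five with chin; five with philtrum
ROI_CONFIGURATIONS: dict[str, tuple[ROIName, ...]] = {
    "all": ROI_ORDER,
    "chin": tuple(r for r in ROI_ORDER if r is not ROIName.PHILTRUM),
    "philtrum": tuple(r for r in ROI_ORDER if r is not ROIName.CHIN),
}
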