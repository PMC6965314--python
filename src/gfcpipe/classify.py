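"""Patient/control discrimination from GFC-derived features.

A soft-margin RBF-kernel support vector classifier (C = 1, gamma =
1/n_features — the classic library defaults) is evaluated under three
schemes: leave-one-out, stratified k-fold rotation, and a label-permutation
test of the LOO accuracy. The kernel machine itself is delegated to
scikit-learn's SVC; all validation loops are implemented here. Patients are
the positive class: sensitivity is computed on patients, specificity on
controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    x: np.ndarray  # (n_subjects, n_features)
    ids: list[str]
    labels: np.ndarray  # bool, True = patient
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=np.float64))
        if self.x.shape[0] == 1 and len(self.ids) > 1:
            self.x = self.x.T
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.x.shape[0] != self.labels.size or len(self.ids) != self.labels.size:
            raise ValueError("x rows, ids and labels must agree in length")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("feature table contains missing/non-finite values")
        if self.labels.all() or not self.labels.any():
            raise ValueError("labels must cover both classes")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.x.shape[1])]

    @property
    def n(self) -> int:
        return self.labels.size


@dataclass
class ClassifierReport:
    scheme: str
    accuracy: float  # percent
    sensitivity: float  # percent, on patients
    specificity: float  # percent, on controls
    balanced_accuracy: float  # percent, mean of sensitivity and specificity
    predictions: np.ndarray  # bool per subject, pooled held-out predictions
    labels: np.ndarray
    k: int | None = None
    n_perm: int | None = None
    perm_p: float | None = None
    seed: int | None = None


def _metrics(labels: np.ndarray, pred: np.ndarray) -> tuple[float, float, float, float]:
    tp = np.sum(pred & labels)
    tn = np.sum(~pred & ~labels)
    acc = 100.0 * (tp + tn) / labels.size
    sens = 100.0 * tp / labels.sum()
    spec = 100.0 * tn / (~labels).sum()
    return float(acc), float(sens), float(spec), float((sens + spec) / 2.0)


def _fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    C: float,
    gamma: float | None,
) -> np.ndarray:
    """Train the kernel classifier and predict; z-scores multi-feature inputs
    with training-fold statistics only (no leakage)."""
    if y_train.all() or not y_train.any():
        raise ValueError("training fold contains a single class")
    if x_train.shape[1] > 1:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd
    g = gamma if gamma is not None else 1.0 / x_train.shape[1]
    clf = SVC(C=C, kernel="rbf", gamma=g)
    clf.fit(x_train, y_train)
    return clf.predict(x_test).astype(bool)


def svm_loo(features: FeatureTable, C: float = 1.0, gamma: float | None = None) -> ClassifierReport:
    """Leave-one-out validation: n iterations, each training on n-1 samples."""
    n = features.n
    if n < 4 or features.labels.sum() < 2 or (~features.labels).sum() < 2:
        raise ValueError("need n >= 4 with at least 2 subjects per class")
    pred = np.zeros(n, dtype=bool)
    for i in range(n):
        train = np.arange(n) != i
        pred[i] = _fit_predict(
            features.x[train], features.labels[train], features.x[i : i + 1], C, gamma
        )[0]
    acc, sens, spec, bal = _metrics(features.labels, pred)
    return ClassifierReport(
        scheme="loo", accuracy=acc, sensitivity=sens, specificity=spec,
        balanced_accuracy=bal, predictions=pred, labels=features.labels.copy(),
    )


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment dealing each class's shuffled members round-robin."""
    folds = np.empty(labels.size, dtype=np.int64)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def svm_kfold(
    features: FeatureTable,
    k: int = 5,
    stratified: bool = True,
    seed: int = 0,
    C: float = 1.0,
    gamma: float | None = None,
) -> ClassifierReport:
    """Full k-fold rotation (each fold tested once); pooled global accuracy."""
    n = features.n
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects {n}")
    rng = np.random.default_rng(seed)
    if stratified:
        folds = _stratified_folds(features.labels, k, rng)
    else:
        folds = rng.permutation(np.arange(n) % k)
    pred = np.zeros(n, dtype=bool)
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        train = ~test
        pred[test] = _fit_predict(
            features.x[train], features.labels[train], features.x[test], C, gamma
        )
    acc, sens, spec, bal = _metrics(features.labels, pred)
    return ClassifierReport(
        scheme="kfold", accuracy=acc, sensitivity=sens, specificity=spec,
        balanced_accuracy=bal, predictions=pred, labels=features.labels.copy(),
        k=k, seed=seed,
    )


def svm_permutation_test(
    features: FeatureTable,
    n_perm: int = 10000,
    seed: int = 0,
    C: float = 1.0,
    gamma: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation test of the LOO accuracy.

    Labels are permuted ``n_perm`` times and the LOO accuracy recomputed;
    p = (1 + #{null >= observed}) / (n_perm + 1). Returns (observed accuracy
    in percent, p, null accuracies in percent).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = svm_loo(features, C=C, gamma=gamma).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm_labels = rng.permutation(features.labels)
        shuffled = FeatureTable(
            x=features.x, ids=features.ids, labels=perm_labels,
            feature_names=features.feature_names,
        )
        null[j] = svm_loo(shuffled, C=C, gamma=gamma).accuracy
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(observed), float(p), null


def region_features(
    z_maps: np.ndarray,
    mask,
    atlas: np.ndarray,
    ids: list[str],
    labels: np.ndarray,
) -> FeatureTable:
    """Mean GFC z per integer-labeled atlas region (intersected with the mask).

    Regions with no in-mask voxels are dropped with a warning.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != mask.mask.shape:
        raise ValueError("atlas grid does not match the mask grid")
    region_ids = [int(v) for v in np.unique(atlas) if v != 0]
    if not region_ids:
        raise ValueError("atlas has no nonzero labels")
    z = np.asarray(z_maps, dtype=np.float64)
    cols, names = [], []
    for rid in region_ids:
        sel = (atlas == rid) & mask.mask
        if not sel.any():
            warnings.warn(f"atlas region {rid} has no gray-matter voxels; dropped",
                          stacklevel=2)
            continue
        positions = mask.lookup[sel]
        cols.append(z[:, positions].mean(axis=1))
        names.append(f"region_{rid}")
    if not cols:
        raise ValueError("no atlas region intersects the gray-matter mask")
    return FeatureTable(
        x=np.column_stack(cols), ids=list(ids), labels=labels, feature_names=names
    )
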