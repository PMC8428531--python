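"""Cross-validated classifier comparison.

Four classifiers are compared under stratified 10-fold cross-validation:
a linear-kernel SVM with its cost parameter grid-searched, a C4.5-style
gain-ratio decision tree, a single-hidden-layer back-propagation network
whose hidden width follows the sqrt(n_in * n_out) rule, and brute-force
k-nearest-neighbours with k itself selected exhaustively. All
hyperparameter selection and any feature normalisation happen strictly
inside the training folds, so a label-permutation null stays at chance.

Two evaluation schemes mirror the study design: "whole" pools every
subject's epochs into one cross-validation; "single" cross-validates each
subject separately and reports the unweighted mean across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, FeatureNormalizer
from .tree import GainRatioTree

CLASSIFIER_KINDS = ("svm_linear", "dt_c45", "bpnn", "knn_brute")

SVM_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
KNN_K_GRID = tuple(range(1, 32, 2))


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and with which hyperparameter search space."""

    kind: str
    seed: int = 0
    svm_c_grid: tuple[float, ...] = SVM_C_GRID
    knn_k_grid: tuple[int, ...] = KNN_K_GRID
    hidden_nodes: int | None = None  # BPNN override of the node-count rule
    tree_max_depth: int = 25
    inner_cv: int = 3

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; known: {CLASSIFIER_KINDS}"
            )
        if self.kind == "svm_linear" and not self.svm_c_grid:
            raise ValueError("empty SVM C grid")
        if self.kind == "knn_brute" and not self.knn_k_grid:
            raise ValueError("empty kNN k grid")


def bpnn_hidden_nodes(n_inputs: int, n_outputs: int = 2) -> int:
    """Hidden-layer width rule m = round(sqrt(n * l)), minimum 2."""
    return max(int(round(np.sqrt(n_inputs * n_outputs))), 2)


@dataclass
class CVResult:
    """Per-fold train/test accuracy under one classifier and scheme."""

    scheme: str  # "whole" | "single"
    classifier: str
    train_acc: list[float]
    test_acc: list[float]
    feature_set: str = ""
    electrode_scheme: str = ""
    per_subject: dict[str, float] = field(default_factory=dict)

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_acc))

    @property
    def mean_test(self) -> float:
        if self.scheme == "single" and self.per_subject:
            return float(np.mean(list(self.per_subject.values())))
        return float(np.mean(self.test_acc))


def kfold_split(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold partition: disjoint, exhaustive, sizes within one.

    Returns the list of test-index arrays; fold i's training set is every
    other fold. Deterministic under seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n), labels)]


def _make_model(spec: ClassifierSpec, n_features: int, n_train: int):
    if spec.kind == "svm_linear":
        return GridSearchCV(
            SVC(kernel="linear"),
            {"C": list(spec.svm_c_grid)},
            cv=spec.inner_cv,
            n_jobs=None,
        )
    if spec.kind == "dt_c45":
        return GainRatioTree(max_depth=spec.tree_max_depth)
    if spec.kind == "bpnn":
        m = spec.hidden_nodes or bpnn_hidden_nodes(n_features)
        # the net standardises its input internally (fit on the training
        # folds only, like any of its weights): back-propagation stalls on
        # features with large offsets and small spread, e.g. raw band DEs.
        # lbfgs converges reliably for these small single-hidden-layer nets.
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(m,),
                solver="lbfgs",
                max_iter=500,
                random_state=spec.seed,
            ),
        )
    if spec.kind == "knn_brute":
        # keep k below the smallest inner training split
        k_cap = max(n_train * (spec.inner_cv - 1) // spec.inner_cv, 1)
        grid = [k for k in spec.knn_k_grid if k <= k_cap] or [1]
        return GridSearchCV(
            KNeighborsClassifier(algorithm="brute"),
            {"n_neighbors": grid},
            cv=spec.inner_cv,
            n_jobs=None,
        )
    raise ValueError(spec.kind)


def train_and_score(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    normalize: str = "none",
) -> CVResult:
    """Cross-validate one classifier over the given test folds.

    Normalisation statistics and hyperparameter searches are fit on the
    training folds only (no leakage into the held-out fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("feature rows and labels disagree")
    all_idx = np.arange(len(y))
    train_acc, test_acc = [], []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fi}: training data has a single class")
        norm = FeatureNormalizer(normalize).fit(X[train_idx])
        X_tr = norm.transform(X[train_idx])
        X_te = norm.transform(X[test_idx])
        model = _make_model(spec, X.shape[1], len(train_idx))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence at small n
            model.fit(X_tr, y_tr)
        train_acc.append(float(np.mean(model.predict(X_tr) == y_tr)))
        test_acc.append(float(np.mean(model.predict(X_te) == y_te)))
    return CVResult(
        scheme="whole",
        classifier=spec.kind,
        train_acc=train_acc,
        test_acc=test_acc,
    )


def evaluate_whole(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    normalize: str = "none",
) -> CVResult:
    """Pool all subjects' epochs into one stratified k-fold CV."""
    y = matrix.labels
    folds = kfold_split(y, k=k, seed=seed)
    result = train_and_score(spec, matrix.values.to_numpy(), y, folds, normalize)
    result.scheme = "whole"
    result.feature_set = matrix.feature_set
    return result


def evaluate_single(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    normalize: str = "none",
) -> CVResult:
    """Per-subject k-fold CV; headline accuracy is the unweighted mean of
    the subjects' mean test accuracies. Subjects with fewer than k epochs
    (or a missing class) are skipped with a warning."""
    X = matrix.values.to_numpy()
    y = matrix.labels
    subjects = matrix.subjects
    train_acc, test_acc = [], []
    per_subject: dict[str, float] = {}
    per_subject_train: list[float] = []
    for subj in sorted(set(subjects)):
        mask = subjects == subj
        y_s = y[mask]
        if len(y_s) < k or len(np.unique(y_s)) < 2:
            warnings.warn(
                f"subject {subj}: too few epochs for {k}-fold CV; skipped",
                stacklevel=2,
            )
            continue
        counts = np.unique(y_s, return_counts=True)[1]
        k_eff = min(k, int(counts.min()))
        folds = kfold_split(y_s, k=k_eff, seed=seed)
        res = train_and_score(spec, X[mask], y_s, folds, normalize)
        train_acc.extend(res.train_acc)
        test_acc.extend(res.test_acc)
        per_subject[subj] = res.mean_test
        per_subject_train.append(res.mean_train)
    if not per_subject:
        raise ValueError("no subject had enough epochs for cross-validation")
    return CVResult(
        scheme="single",
        classifier=spec.kind,
        train_acc=per_subject_train,
        test_acc=test_acc,
        feature_set=matrix.feature_set,
        per_subject=per_subject,
    )
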