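"""Eight classifier configurations behind one train/predict contract.

SVM (linear / polynomial / RBF), random forest, decision tree, AdaBoost
and XGBoost delegate to scikit-learn / xgboost configured with the
benchmark's fixed hyperparameters; quadratic discriminant analysis is
implemented natively (regularized per-class Gaussians, log-determinant
discriminant), as is the AdaBoost round-weight formula.  A stratified
k-fold scheme and a pooled cross-validated prediction harness with
explicit fold-hygiene bookkeeping round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _linalg
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

KINDS = (
    "SVM_LINEAR", "SVM_POLY", "SVM_RBF", "RANDOM_FOREST",
    "DECISION_TREE", "QDA", "ADABOOST", "XGBOOST",
)

#: fixed benchmark hyperparameters per classifier kind
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "SVM_LINEAR": {"C": 10.0},
    "SVM_POLY": {"degree": 3, "C": 1.0},
    "SVM_RBF": {"C": 0.5, "gamma": 0.1},
    "RANDOM_FOREST": {"n_estimators": 100, "max_depth": 5, "max_features": 10},
    "DECISION_TREE": {"max_depth": 10, "min_samples_leaf": 1},
    "QDA": {"regularization": 0.5},
    "ADABOOST": {"n_estimators": 100, "learning_rate": 0.1},
    "XGBOOST": {"n_estimators": 100, "learning_rate": 0.01},
}

# stopping contract shared by the iterative solvers: tolerance 1e-5 or
# 1000 iterations, whichever is earlier (applied where the backend
# exposes such controls)
_SVM_TOL = 1e-5
_SVM_MAX_ITER = 1000


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus its (fixed-default) hyperparameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        merged = {**DEFAULT_HYPERPARAMS[self.kind], **self.hyperparams}
        unknown = set(merged) - set(DEFAULT_HYPERPARAMS[self.kind])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        object.__setattr__(self, "hyperparams", merged)

    def __hash__(self) -> int:
        return hash((self.kind, tuple(sorted(self.hyperparams.items())), self.seed))


# ---------------------------------------------------------------------------
# Native QDA
# ---------------------------------------------------------------------------

@dataclass
class QDAParams:
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray        # (n_classes, d)
    covariances: np.ndarray  # (n_classes, d, d), regularized SPD
    log_det: np.ndarray
    _chol: np.ndarray | None = None


def qda_fit(X: np.ndarray, y: np.ndarray, regularization: float = 0.5) -> QDAParams:
    """Per-class Gaussians with shrinkage toward the diagonal:
    Sigma_k <- (1 - rho) Sigma_k + rho diag(Sigma_k), rho = 0.5 by default."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    d = X.shape[1]
    priors, means, covs, log_dets, chols = [], [], [], [], []
    floor = 1e-9 * max(float(X.var()), np.finfo(float).tiny)
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        diff = Xc - mu
        cov = diff.T @ diff / Xc.shape[0]
        cov = (1.0 - regularization) * cov + regularization * np.diag(np.diag(cov))
        cov[np.diag_indices(d)] += floor
        chol = _linalg.cholesky(cov, lower=True)
        priors.append(Xc.shape[0] / X.shape[0])
        means.append(mu)
        covs.append(cov)
        log_dets.append(2.0 * np.log(np.diag(chol)).sum())
        chols.append(chol)
    return QDAParams(
        classes=classes,
        priors=np.asarray(priors),
        means=np.asarray(means),
        covariances=np.asarray(covs),
        log_det=np.asarray(log_dets),
        _chol=np.asarray(chols),
    )


def qda_discriminant(params: QDAParams, x: np.ndarray) -> np.ndarray:
    """Discriminant scores g_k(x) = ln P(y=k) - ln|Sigma_k|/2
    - (x - mu_k)^T Sigma_k^{-1} (x - mu_k)/2 for each class; the
    predicted class is the argmax over k.  Accepts a single vector or a
    (n, d) matrix and returns (n_classes,) or (n, n_classes) scores."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != fitted dimension {params.means.shape[1]}")
    scores = np.empty((X.shape[0], params.classes.size))
    for k in range(params.classes.size):
        diff = (X - params.means[k]).T
        z = _linalg.solve_triangular(params._chol[k], diff, lower=True)
        maha = (z**2).sum(axis=0)
        scores[:, k] = np.log(params.priors[k]) - 0.5 * params.log_det[k] - 0.5 * maha
    return scores[0] if single else scores


class QDAClassifier:
    """Minimal sklearn-style wrapper over the native QDA routines."""

    def __init__(self, regularization: float = 0.5):
        self.regularization = regularization
        self.params_: QDAParams | None = None

    def fit(self, X, y):
        self.params_ = qda_fit(X, y, self.regularization)
        return self

    def predict(self, X):
        scores = np.atleast_2d(qda_discriminant(self.params_, X))
        return self.params_.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# AdaBoost round weight
# ---------------------------------------------------------------------------

def adaboost_round_weight(error: float, learning_rate: float) -> float:
    """Round weight alpha_t = learning_rate * ln((1 - eps_t)/eps_t).

    Errors outside (0, 1) are clamped to [1e-10, 1 - 1e-10] with a
    warning; alpha_t is 0 at chance level and antisymmetric about it.
    """
    if not 0.0 < error < 1.0:
        warnings.warn(f"weighted error {error} outside (0, 1); clamping")
        error = min(max(error, 1e-10), 1.0 - 1e-10)
    return learning_rate * np.log((1.0 - error) / error)


# ---------------------------------------------------------------------------
# Estimator construction and training
# ---------------------------------------------------------------------------

def build_estimator(spec: ClassifierSpec, n_features: int):
    hp = spec.hyperparams
    if spec.kind == "SVM_LINEAR":
        return SVC(kernel="linear", C=hp["C"], tol=_SVM_TOL,
                   max_iter=_SVM_MAX_ITER, random_state=spec.seed)
    if spec.kind == "SVM_POLY":
        return SVC(kernel="poly", degree=hp["degree"], C=hp["C"], tol=_SVM_TOL,
                   max_iter=_SVM_MAX_ITER, random_state=spec.seed)
    if spec.kind == "SVM_RBF":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], tol=_SVM_TOL,
                   max_iter=_SVM_MAX_ITER, random_state=spec.seed)
    if spec.kind == "RANDOM_FOREST":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            max_features=min(hp["max_features"], n_features),
            random_state=spec.seed, n_jobs=1)
    if spec.kind == "DECISION_TREE":
        return DecisionTreeClassifier(
            max_depth=hp["max_depth"], min_samples_leaf=hp["min_samples_leaf"],
            random_state=spec.seed)
    if spec.kind == "QDA":
        return QDAClassifier(regularization=hp["regularization"])
    if spec.kind == "ADABOOST":
        return AdaBoostClassifier(
            n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
            random_state=spec.seed)
    if spec.kind == "XGBOOST":
        return XGBClassifier(
            n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
            objective="binary:logistic", tree_method="hist",
            random_state=spec.seed, n_jobs=1, verbosity=0)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    n_samples: int
    n_features: int
    class_counts: dict

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {self.n_features}")
        return np.asarray(self.estimator.predict(X))


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a samples x d matrix with d >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    est = build_estimator(spec, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SVC max_iter cap warns by design
        est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, n_samples=X.shape[0],
                        n_features=X.shape[1],
                        class_counts=dict(zip(classes.tolist(), counts.tolist())))


# ---------------------------------------------------------------------------
# Stratified folds and pooled cross-validated predictions
# ---------------------------------------------------------------------------

@dataclass
class FoldScheme:
    k: int
    test_folds: list  # list of index arrays, disjoint, covering all samples
    seed: int

    def iter_splits(self):
        all_idx = np.concatenate(self.test_folds)
        for test in self.test_folds:
            train = np.setdiff1d(all_idx, test)
            yield train, test


def stratified_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> FoldScheme:
    """Deterministic stratified k-fold scheme.

    Each class's shuffled indices are dealt across folds so per-fold
    class counts are within one of exact proportionality.  k equal to
    the sample count gives leave-one-out.
    """
    y = np.asarray(y)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if k != n and counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has only {counts.min()} members; use k <= {counts.min()}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[(pos + offset) % k].append(int(i))
        offset += idx.size  # rotate so remainder folds differ across classes
    return FoldScheme(k=k, test_folds=[np.sort(np.asarray(f, dtype=int)) for f in folds],
                      seed=seed)


def cross_val_predict(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                      folds: FoldScheme) -> np.ndarray:
    """Pooled out-of-fold predictions: each sample is predicted by the
    model trained on all folds except its own (asserted by index
    bookkeeping)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    covered = np.sort(np.concatenate(folds.test_folds))
    if covered.size != X.shape[0] or not np.array_equal(covered, np.arange(X.shape[0])):
        raise ValueError("fold scheme does not partition the samples")
    preds = np.empty(X.shape[0], dtype=y.dtype)
    for train, test in folds.iter_splits():
        assert np.intersect1d(train, test).size == 0, "fold hygiene violation"
        model = train_classifier(spec, X[train], y[train])
        preds[test] = model.predict(X[test])
    return preds
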