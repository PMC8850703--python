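"""Dataset splitting, grid-search tuning with stratified 5-fold CV, and evaluation.

Five classifier families are supported: k-NN, SVM, random forest, a
single-hidden-layer ANN (54-32-3, ReLU hidden, softmax output, Adam,
lr 1e-3, 200 epochs) and an RBF network (32 Gaussian centers from
k-means, linear output layer trained with RMSprop on MSE, lr 1e-3,
500 epochs). Hyperparameter grids follow the study design:

* k-NN: k in {1, 3, ..., 31} x {euclidean, minkowski (order 3), chebyshev}
* SVM: kernel {linear, rbf, poly} x gamma {1e-1..1e-6} x C {1..1e5}
  (decade steps), one-vs-rest
* RF: trees {10, 50, 100, 150, 200, 300, 400, 500} x {gini, entropy}
* ANN / RBFN: fixed architecture (single grid cell)

Grid enumeration order is fixed and documented in ``default_grid``; ties
on mean CV accuracy break toward the first cell in that order, so the
selected model is identical across runs with the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix
from .signal_io import CLASS_LABELS

logger = logging.getLogger("ecgsubband")

FAMILIES = ("knn", "svm", "rf", "ann", "rbfn")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Per-class held-out test counts (default 12 AF / 14 CHF / 12 NSR = 38)."""

    test_counts: dict = field(default_factory=lambda: {"AF": 12, "CHF": 14, "NSR": 12})
    seed: int = 0


def split_dataset(fm: FeatureMatrix, spec: SplitSpec) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded per-class sampling without replacement into train/test.

    Train and test are disjoint and their union is the input; the test set
    holds exactly the per-class counts in ``spec``.
    """
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    for cls in sorted(spec.test_counts):
        members = np.flatnonzero((fm.labels == cls).to_numpy())
        k = spec.test_counts[cls]
        if k > members.size:
            raise ValueError(
                f"class {cls!r} has {members.size} rows, cannot hold out {k}"
            )
        test_idx.extend(rng.permutation(members)[:k].tolist())
    test_mask = np.zeros(fm.n_rows, dtype=bool)
    test_mask[test_idx] = True
    return fm.select_rows(np.flatnonzero(~test_mask)), fm.select_rows(np.flatnonzero(test_mask))


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

class RBFNetworkClassifier(BaseEstimator, ClassifierMixin):
    """Radial-basis-function network: one Gaussian hidden layer, linear output.

    Centers are initialized by k-means on the training features (seeded),
    widths set to the mean nearest-center distance, and the output weights
    are trained with RMSprop on the mean-squared error against one-hot
    targets. Prediction takes the argmax of the output layer.
    """

    def __init__(self, n_centers: int = 32, learning_rate: float = 1e-3,
                 epochs: int = 500, batch_size: int = 16, random_state: int = 0):
        self.n_centers = n_centers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _phi(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(X, self.centers_, metric="sqeuclidean")
        phi = np.exp(-d2 / (2.0 * self.width_**2))
        return np.hstack([phi, np.ones((len(X), 1))])  # bias column

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_centers = min(self.n_centers, len(X))
        km = KMeans(n_clusters=n_centers, n_init=4, random_state=self.random_state)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        if n_centers > 1:
            dc = cdist(self.centers_, self.centers_)
            np.fill_diagonal(dc, np.inf)
            self.width_ = float(np.mean(dc.min(axis=1)))
        else:
            self.width_ = 1.0
        if self.width_ == 0:
            self.width_ = 1.0
        Y = np.eye(len(self.classes_))[y_idx]
        phi = self._phi(X)
        rng = np.random.default_rng(self.random_state)
        W = 0.01 * rng.standard_normal((phi.shape[1], Y.shape[1]))
        cache = np.zeros_like(W)
        rho, eps = 0.9, 1e-8
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                err = phi[b] @ W - Y[b]
                g = 2.0 * phi[b].T @ err / len(b)
                cache = rho * cache + (1 - rho) * g**2
                W -= self.learning_rate * g / (np.sqrt(cache) + eps)
        self.weights_ = W
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        return self._phi(np.asarray(X, dtype=float)) @ self.weights_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


# ---------------------------------------------------------------------------
# Grids and estimators
# ---------------------------------------------------------------------------

def default_grid(family: str) -> list[dict]:
    """The documented grid for a family, in enumeration (tie-break) order."""
    if family == "knn":
        return [
            {"n_neighbors": k, "metric": metric}
            for k in range(1, 32, 2)
            for metric in ("euclidean", "minkowski", "chebyshev")
        ]
    if family == "svm":
        return [
            {"kernel": kern, "gamma": g, "C": c}
            for kern in ("linear", "rbf", "poly")
            for g in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
            for c in (1.0, 1e1, 1e2, 1e3, 1e4, 1e5)
        ]
    if family == "rf":
        return [
            {"n_estimators": n, "criterion": crit}
            for n in (10, 50, 100, 150, 200, 300, 400, 500)
            for crit in ("gini", "entropy")
        ]
    if family in ("ann", "rbfn"):
        return [{}]  # fixed architecture
    raise ValueError(f"unknown classifier family {family!r}")


def build_estimator(family: str, params: dict, seed: int = 0, standardize: bool = False):
    """Instantiate the estimator for one grid cell."""
    if family == "knn":
        kwargs = dict(params)
        if kwargs.get("metric") == "minkowski":
            kwargs["p"] = 3  # distinct from Euclidean
        est = KNeighborsClassifier(**kwargs)
    elif family == "svm":
        est = SVC(degree=3, decision_function_shape="ovr", random_state=seed, **params)
    elif family == "rf":
        est = RandomForestClassifier(random_state=seed, **params)
    elif family == "ann":
        est = MLPClassifier(
            hidden_layer_sizes=(32,), activation="relu", solver="adam",
            learning_rate_init=1e-3, max_iter=200, batch_size=16,
            random_state=seed, **params,
        )
    elif family == "rbfn":
        est = RBFNetworkClassifier(n_centers=32, learning_rate=1e-3, epochs=500,
                                   batch_size=16, random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    if standardize:
        logger.info("z-score standardization enabled for %s", family)
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass(frozen=True)
class GridSpec:
    family: str
    grid: list[dict] | None = None  # None -> default_grid(family)
    cv_folds: int = 5
    seed: int = 0
    standardize: bool = False

    def cells(self) -> list[dict]:
        return self.grid if self.grid is not None else default_grid(self.family)


@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    best_mean_accuracy: float
    cv_table: pd.DataFrame  # one row per cell: params json, fold accuracies, mean


def make_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Class-stratified fold indices (each fold within +/-1 of global proportions)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def grid_search(train: FeatureMatrix, spec: GridSpec) -> GridSearchResult:
    """Exhaustive search over the family grid, scored by mean CV accuracy.

    Folds are class-stratified and fixed across cells; the argmax breaks
    ties toward the first cell in documented grid order.
    """
    X = train.data.to_numpy()
    y = train.labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < spec.cv_folds).any():
        raise ValueError(
            f"need at least {spec.cv_folds} rows per class for {spec.cv_folds}-fold CV"
        )
    folds = make_folds(y, spec.cv_folds, spec.seed)
    min_train = min(len(tr) for tr, _ in folds)
    cells = spec.cells()
    if spec.family == "knn":
        # k cannot exceed the smallest CV training fold; inapplicable cells
        # are skipped (they only arise far below the study's sample sizes)
        kept = [c for c in cells if c.get("n_neighbors", 1) <= min_train]
        if len(kept) < len(cells):
            logger.warning("skipping %d k-NN cells with k > %d training rows",
                           len(cells) - len(kept), min_train)
        cells = kept
    if not cells:
        raise ValueError("no evaluable grid cells for this training set")
    rows = []
    best_i, best_mean = 0, -1.0
    for i, params in enumerate(cells):
        accs = []
        for tr, va in folds:
            est = build_estimator(spec.family, params, seed=spec.seed,
                                  standardize=spec.standardize)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[va]) == y[va])))
        mean_acc = float(np.mean(accs))
        rows.append({"params": json.dumps(params, sort_keys=True),
                     **{f"fold{j}": a for j, a in enumerate(accs)},
                     "mean_accuracy": mean_acc})
        if mean_acc > best_mean:  # strict: first-in-order tie-break
            best_i, best_mean = i, mean_acc
    return GridSearchResult(
        family=spec.family,
        best_params=cells[best_i],
        best_mean_accuracy=best_mean,
        cv_table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Final training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    estimator: object
    family: str
    params: dict
    feature_names: list[str]
    cv_accuracies: list[float]
    config_hash: str | None = None


def train_final(train: FeatureMatrix, family: str, best_params: dict, seed: int = 0,
                standardize: bool = False, cv_accuracies: list[float] | None = None,
                config_hash: str | None = None) -> FittedModel:
    est = build_estimator(family, best_params, seed=seed, standardize=standardize)
    est.fit(train.data.to_numpy(), train.labels.to_numpy())
    return FittedModel(est, family, dict(best_params), train.feature_names,
                       list(cv_accuracies or []), config_hash)


@dataclass
class EvaluationReport:
    accuracy: float
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    family: str
    best_params: dict
    cv_accuracies: list[float]
    feature_family: str = "all"
    config_hash: str | None = None

    def to_text(self) -> str:
        lines = [
            f"classifier: {self.family}",
            f"feature_family: {self.feature_family}",
            f"best_params: {json.dumps(self.best_params, sort_keys=True)}",
            f"cv_accuracies: {json.dumps([round(a, 6) for a in self.cv_accuracies])}",
            f"test_accuracy: {self.accuracy:.6f}",
        ]
        if self.config_hash:
            lines.append(f"config_hash: {self.config_hash}")
        lines.append("confusion_matrix (rows=true, cols=predicted):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines) + "\n"


def evaluate(model: FittedModel, test: FeatureMatrix,
             feature_family: str = "all") -> EvaluationReport:
    """Held-out accuracy and 3x3 confusion matrix (rows = true class)."""
    if test.feature_names != model.feature_names:
        raise ValueError("test feature columns do not match the fitted model")
    y_true = test.labels.to_numpy()
    y_pred = model.estimator.predict(test.data.to_numpy())
    labels = [c for c in CLASS_LABELS if c in set(y_true) | set(y_pred)]
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return EvaluationReport(
        accuracy=float(np.mean(y_pred == y_true)),
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        family=model.family,
        best_params=model.params,
        cv_accuracies=model.cv_accuracies,
        feature_family=feature_family,
        config_hash=model.config_hash,
    )
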