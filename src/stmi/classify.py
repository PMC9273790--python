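"""Base classifiers, Bayesian hyperparameter search, majority-vote fusion.

Five classifiers operate on the 2-D SDA projections: SVM (kernel chosen
among linear / quadratic / cubic / gaussian), a Gaussian discriminant
(linear / quadratic / diagonal variants), k-nearest neighbors, a Gini
decision tree, and a 100-tree random forest.  Each classifier's
hyperparameters maximize 5-fold stratified cross-validated accuracy
under sequential model-based (Bayesian) optimization with a
Gaussian-process surrogate and expected-improvement acquisition; the
discriminant's four types are simply grid-searched.  At decision level,
the ensemble label is the one receiving more than half of the five
votes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, ParameterError

__all__ = [
    "Real",
    "Integer",
    "Categorical",
    "SearchSpace",
    "default_search_space",
    "train_classifier",
    "bayes_optimize",
    "optimize_classifier",
    "majority_vote",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("svm", "discriminant", "knn", "dt", "rf")


# ---------------------------------------------------------------- search space


@dataclass(frozen=True)
class Real:
    lo: float
    hi: float
    log: bool = False

    def decode(self, u: float) -> float:
        if self.log:
            return float(math.exp(math.log(self.lo) + u * (math.log(self.hi) - math.log(self.lo))))
        return float(self.lo + u * (self.hi - self.lo))


@dataclass(frozen=True)
class Integer:
    lo: int
    hi: int

    def decode(self, u: float) -> int:
        return int(min(self.hi, self.lo + math.floor(u * (self.hi - self.lo + 1))))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def decode(self, u: float):
        i = min(len(self.choices) - 1, int(u * len(self.choices)))
        return self.choices[i]


@dataclass(frozen=True)
class SearchSpace:
    """Named hyperparameter dimensions, each decoded from the unit cube."""

    dims: dict

    def __post_init__(self) -> None:
        if not self.dims:
            raise ParameterError("search space must not be empty")

    def decode(self, u: np.ndarray) -> dict:
        return {name: dim.decode(ui) for (name, dim), ui in zip(self.dims.items(), u)}

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    def contains(self, params: dict) -> bool:
        for name, dim in self.dims.items():
            v = params[name]
            if isinstance(dim, Categorical):
                if v not in dim.choices:
                    return False
            elif not dim.lo <= v <= dim.hi:
                return False
        return True


def default_search_space(name: str, n_train: int, d: int = 2) -> SearchSpace:
    """Hyperparameter domains per classifier."""
    if name == "svm":
        dims = {
            "C": Real(1e-3, 1e3, log=True),
            "kernel": Categorical(("linear", "quadratic", "cubic", "gaussian")),
            "gamma": Real(1e-3, 1e3, log=True),  # used by the gaussian kernel
        }
    elif name == "knn":
        dims = {
            "k": Integer(1, min(30, max(2, n_train - 1))),
            "metric": Categorical(("euclidean", "mahalanobis", "cubic", "cosine")),
            "weight": Categorical(("equal", "inverse", "squared-inverse")),
        }
    elif name == "dt":
        dims = {"max_splits": Integer(1, max(2, n_train - 1))}
    elif name == "discriminant":
        dims = {
            "kind": Categorical(("linear", "quadratic", "diag-linear", "diag-quadratic"))
        }
    elif name == "rf":
        dims = {
            "min_leaf": Integer(1, 20),
            "predictors_per_split": Integer(1, max(1, d)),
        }
    else:
        raise ParameterError(f"unknown classifier {name!r}")
    return SearchSpace(dims=dims)


# ---------------------------------------------------------------- classifiers


class GaussianDiscriminant:
    """Gaussian class-conditional discriminant with four covariance models.

    'linear' pools one full covariance across classes, 'quadratic' fits
    one per class, and the diagonal variants constrain it to a diagonal.
    Prediction is the Bayes rule under the fitted Gaussians.
    """

    def __init__(self, kind: str = "linear", reg: float = 1e-6):
        if kind not in ("linear", "quadratic", "diag-linear", "diag-quadratic"):
            raise ParameterError(f"unknown discriminant type {kind!r}")
        self.kind = kind
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianDiscriminant":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, self.covs_, self.priors_ = {}, {}, {}
        pooled = np.zeros((d, d))
        for k in self.classes_:
            Xk = X[y == k]
            self.means_[k] = Xk.mean(axis=0)
            C = np.cov(Xk.T, bias=False) if len(Xk) > 1 else np.eye(d)
            C = np.atleast_2d(C)
            pooled += C * max(len(Xk) - 1, 1)
            self.covs_[k] = C
            self.priors_[k] = len(Xk) / len(X)
        pooled /= max(len(X) - len(self.classes_), 1)
        for k in self.classes_:
            C = pooled if self.kind in ("linear", "diag-linear") else self.covs_[k]
            if self.kind.startswith("diag"):
                C = np.diag(np.diag(C))
            C = C + self.reg * np.trace(C) / max(d, 1) * np.eye(d)
            self.covs_[k] = C
        return self

    def _log_post(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((len(X), len(self.classes_)))
        for j, k in enumerate(self.classes_):
            diff = X - self.means_[k]
            Cinv = np.linalg.inv(self.covs_[k])
            _, logdet = np.linalg.slogdet(self.covs_[k])
            maha = np.einsum("ij,jk,ik->i", diff, Cinv, diff)
            scores[:, j] = -0.5 * (maha + logdet) + math.log(self.priors_[k])
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return self.classes_[self._log_post(X).argmax(axis=1)]


def _inverse_weights(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12)


def _squared_inverse_weights(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


def train_classifier(name: str, X: np.ndarray, y: np.ndarray, hyperparams: dict, seed: int = 0):
    """Fit one named base classifier with the given hyperparameters."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training requires both classes")
    hp = dict(hyperparams)
    if name == "svm":
        kernel = hp.get("kernel", "linear")
        common = dict(C=hp.get("C", 1.0), random_state=seed)
        if kernel == "linear":
            model = SVC(kernel="linear", **common)
        elif kernel in ("quadratic", "cubic"):
            model = SVC(
                kernel="poly",
                degree=2 if kernel == "quadratic" else 3,
                coef0=1.0,
                gamma="scale",
                **common,
            )
        elif kernel == "gaussian":
            model = SVC(kernel="rbf", gamma=hp.get("gamma", 1.0), **common)
        else:
            raise ParameterError(f"unknown SVM kernel {kernel!r}")
    elif name == "discriminant":
        model = GaussianDiscriminant(kind=hp.get("kind", "linear"))
    elif name == "knn":
        k = min(int(hp.get("k", 5)), len(y))
        metric = hp.get("metric", "euclidean")
        weight = hp.get("weight", "equal")
        weights = {
            "equal": "uniform",
            "inverse": _inverse_weights,
            "squared-inverse": _squared_inverse_weights,
        }[weight]
        kwargs: dict = dict(n_neighbors=k, weights=weights)
        if metric == "euclidean":
            kwargs["metric"] = "euclidean"
        elif metric == "cubic":  # Minkowski with exponent 3
            kwargs.update(metric="minkowski", p=3)
        elif metric == "cosine":
            kwargs["metric"] = "cosine"
        elif metric == "mahalanobis":
            cov = np.cov(X.T) + 1e-6 * np.eye(X.shape[1])
            kwargs.update(metric="mahalanobis", metric_params={"VI": np.linalg.inv(cov)})
        else:
            raise ParameterError(f"unknown kNN metric {metric!r}")
        model = KNeighborsClassifier(**kwargs)
    elif name == "dt":
        model = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=int(hp.get("max_splits", 10)) + 1,
            random_state=seed,
        )
    elif name == "rf":
        model = RandomForestClassifier(
            n_estimators=100,
            criterion="gini",
            min_samples_leaf=int(hp.get("min_leaf", 1)),
            max_features=min(int(hp.get("predictors_per_split", X.shape[1])), X.shape[1]),
            random_state=seed,
        )
    else:
        raise ParameterError(f"unknown classifier {name!r}")
    return model.fit(X, y)


# ---------------------------------------------------------------- optimization


@dataclass
class OptimizeResult:
    best_params: dict
    best_value: float
    trace: list  # best-so-far objective after each evaluation
    evaluated: list  # (params, value) pairs


def bayes_optimize(
    objective,
    space: SearchSpace,
    n_iter: int = 30,
    seed: int = 0,
    n_initial: int = 8,
) -> OptimizeResult:
    """Sequential model-based maximization over the search space.

    Random exploration for the first ``n_initial`` evaluations, then a
    Gaussian-process surrogate (Matern 5/2 on the unit cube) ranks 256
    random candidates by expected improvement.  Returns the argmax over
    all evaluated points; the best-so-far trace is non-decreasing.
    """
    if n_iter < 1:
        raise ParameterError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    U: list[np.ndarray] = []
    vals: list[float] = []
    trace: list[float] = []
    evaluated = []
    for it in range(n_iter):
        if it < n_initial or len(set(np.round(vals, 12))) < 2:
            u = rng.random(space.n_dims)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=0.3),
                alpha=1e-6,
                normalize_y=True,
                random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                # the surrogate's length-scale hitting its bound is harmless
                warnings.simplefilter("ignore")
                gp.fit(np.array(U), np.array(vals))
            cand = rng.random((256, space.n_dims))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(vals)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / sd
                ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd < 1e-12] = 0.0
            u = cand[int(np.argmax(ei))]
        params = space.decode(u)
        v = float(objective(params))
        U.append(u)
        vals.append(v)
        evaluated.append((params, v))
        trace.append(max(vals))
    i_best = int(np.argmax(vals))
    return OptimizeResult(
        best_params=space.decode(U[i_best]), best_value=vals[i_best], trace=trace, evaluated=evaluated
    )


def cv_accuracy_objective(name: str, X: np.ndarray, y: np.ndarray, cv: int = 5, seed: int = 0):
    """Deterministic stratified k-fold CV accuracy as the search objective."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    n_splits = int(min(cv, counts.min()))
    skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    def objective(params: dict) -> float:
        correct = 0
        for tr, te in folds:
            try:
                model = train_classifier(name, X[tr], y[tr], params, seed=seed)
                correct += int((model.predict(X[te]) == y[te]).sum())
            except (np.linalg.LinAlgError, ValueError):
                return 0.0  # degenerate hyperparameters score worst
        return correct / len(y)

    return objective


def optimize_classifier(
    name: str, X: np.ndarray, y: np.ndarray, n_iter: int = 30, seed: int = 0, cv: int = 5
):
    """Search hyperparameters, then refit on the full training data.

    The discriminant's single categorical dimension is grid-searched;
    the other classifiers use :func:`bayes_optimize`.
    """
    space = default_search_space(name, n_train=len(y), d=np.asarray(X).shape[1])
    objective = cv_accuracy_objective(name, X, y, cv=cv, seed=seed)
    if name == "discriminant":
        kinds = space.dims["kind"].choices
        vals = [objective({"kind": k}) for k in kinds]
        best = {"kind": kinds[int(np.argmax(vals))]}
        result = OptimizeResult(
            best_params=best,
            best_value=float(max(vals)),
            trace=list(np.maximum.accumulate(vals)),
            evaluated=[({"kind": k}, v) for k, v in zip(kinds, vals)],
        )
    else:
        result = bayes_optimize(objective, space, n_iter=n_iter, seed=seed)
    model = train_classifier(name, X, y, result.best_params, seed=seed)
    return model, result


# ---------------------------------------------------------------- fusion


def majority_vote(labels, fallback: int | str | None = None):
    """Label receiving more than half of the five base-classifier votes.

    With five binary voters a strict majority always exists; the
    ``fallback`` (by convention the SVM's label) only matters if a voter
    abstains (None), which can make the count even.
    """
    votes = [v for v in labels if v is not None]
    if len(labels) != 5:
        raise DataError(f"expected exactly 5 votes, got {len(labels)}")
    uniq = set(votes)
    if len(uniq) > 2:
        raise DataError(f"votes must be binary, got labels {sorted(map(str, uniq))}")
    vals, counts = np.unique(np.asarray(votes), return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    if len(winners) == 1:
        return winners[0].item() if hasattr(winners[0], "item") else winners[0]
    if fallback is None:
        fallback = labels[0]
    return fallback
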