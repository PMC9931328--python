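"""Classifiers: native LDA plus a uniform backend contract.

The screening method's primary classifier is linear discriminant
analysis, implemented natively here.  LDA models each class as a
Gaussian with its own mean and a shared (pooled within-class)
covariance, and classifies by the Bayes posterior

    P(y = k | x)  proportional to  N(x; mu_k, Sigma) * pi_k,

normalised over classes.  Because the cohorts of interest have far more
features than samples, the pooled covariance is regularised by shrinkage
toward a scaled identity::

    Sigma_shrunk = (1 - alpha) * Sigma + alpha * (tr(Sigma) / d) * I

which is positive definite for any alpha > 0.  Class priors pi_k enter
the posterior directly and are the knob used to trade sensitivity
against specificity for screening.

The nonlinear comparison methods — SVM (linear / polynomial / RBF /
sigmoid kernels), random forest, and gradient boosting — are delegated
to scikit-learn and xgboost behind a shared spec: every backend exposes
``fit``, ``predict`` and a continuous decision score, and takes class
weights (the prior-analogue) fixed, never tuned.  Hyperparameter tuning
uses stratified 10-fold CV: grid search for LDA and SVM, random search
for the tree ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    RandomizedSearchCV,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LdaModel",
    "lda_fit",
    "lda_posterior",
    "lda_predict",
    "NativeLda",
    "ClassifierSpec",
    "BACKENDS",
    "make_estimator",
    "tune",
]


# ---------------------------------------------------------------------------
# Native LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """A fitted LDA: class means, shrunk pooled covariance, priors."""

    classes: np.ndarray
    means: np.ndarray            # (k, d)
    covariance: np.ndarray       # (d, d) pooled, before shrinkage
    shrinkage: float
    priors: np.ndarray           # (k,), sums to 1
    _chol: Any = field(default=None, repr=False)
    _logdet: float = field(default=0.0, repr=False)

    @property
    def shrunk_covariance(self) -> np.ndarray:
        d = self.covariance.shape[0]
        target = (np.trace(self.covariance) / d) * np.eye(d)
        return (1.0 - self.shrinkage) * self.covariance + self.shrinkage * target


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular; refit with shrinkage > 0."""


def lda_fit(
    X,
    y,
    shrinkage: float = 0.0,
    priors: Sequence[float] | str | None = None,
) -> LdaModel:
    """Fit LDA by plug-in estimates.

    mu_k are the class means; the pooled within-class covariance divides
    the summed scatter by (n - k).  ``priors`` may be an explicit
    per-class vector (in sorted class order), or None / ``"empirical"``
    for the training class frequencies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("lda_fit requires at least 2 classes")
    n, d = X.shape
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")

    means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
    scatter = np.zeros((d, d))
    for k in range(len(classes)):
        resid = X[y_idx == k] - means[k]
        scatter += resid.T @ resid
    cov = scatter / (n - len(classes))

    if priors is None or (isinstance(priors, str) and priors == "empirical"):
        pri = counts / n
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (len(classes),) or pri.min() < 0 or not np.isclose(pri.sum(), 1.0):
            raise ValueError(
                f"priors must be {len(classes)} nonnegative values summing to 1"
            )

    model = LdaModel(
        classes=classes, means=means, covariance=cov,
        shrinkage=float(shrinkage), priors=pri,
    )
    sigma = model.shrunk_covariance
    try:
        chol = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled covariance is singular (d >= n?); refit with "
            "shrinkage > 0"
        ) from exc
    model._chol = chol
    model._logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    return model


def _log_posterior(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Unnormalised per-class log posterior via the shared covariance."""
    log_post = np.empty((X.shape[0], len(model.classes)))
    with np.errstate(divide="ignore"):
        log_priors = np.log(model.priors)
    for k in range(len(model.classes)):
        diff = X - model.means[k]
        solved = cho_solve(model._chol, diff.T).T
        maha = np.sum(diff * solved, axis=1)
        log_post[:, k] = -0.5 * (maha + model._logdet) + log_priors[k]
    return log_post


def lda_posterior(model: LdaModel, X) -> np.ndarray:
    """Per-class posterior probabilities, rows summing to 1.

    Computed in the log domain with a stabilising normalisation
    (log-sum-exp), so extreme Mahalanobis distances cannot overflow.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"x has {X.shape[1]} features, model expects {model.means.shape[1]}"
        )
    log_post = _log_posterior(model, X)
    return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))


def lda_predict(model: LdaModel, X) -> np.ndarray:
    """Class of maximum posterior for each row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.classes[np.argmax(_log_posterior(model, X), axis=1)]


class NativeLda(BaseEstimator, ClassifierMixin):
    """Scikit-learn-compatible wrapper around the native LDA.

    Exposes ``coef_`` (the discriminant direction) so recursive feature
    elimination can rank features by absolute coefficient.
    """

    def __init__(self, shrinkage: float = 0.0, priors=None):
        self.shrinkage = shrinkage
        self.priors = priors

    def fit(self, X, y):
        self.model_ = lda_fit(X, y, shrinkage=self.shrinkage, priors=self.priors)
        self.classes_ = self.model_.classes
        # binary discriminant direction: Sigma^-1 (mu_1 - mu_0)
        if len(self.classes_) == 2:
            diff = self.model_.means[1] - self.model_.means[0]
            self.coef_ = cho_solve(self.model_._chol, diff)[np.newaxis, :]
        return self

    def predict(self, X):
        return lda_predict(self.model_, X)

    def predict_proba(self, X):
        return lda_posterior(self.model_, X)

    def decision_function(self, X):
        """Log posterior odds of the last (positive) class."""
        log_post = _log_posterior(self.model_, np.atleast_2d(np.asarray(X, float)))
        return log_post[:, 1] - log_post[:, 0]


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------

BACKENDS = (
    "lda", "svm_linear", "svm_poly", "svm_rbf", "svm_sigmoid", "rf", "xgboost",
)

#: Backends tuned by random search (the tree ensembles); the rest use grid.
_RANDOM_SEARCH_BACKENDS = {"rf", "xgboost"}

_DEFAULT_GRIDS: dict[str, dict] = {
    "lda": {"shrinkage": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]},
    "svm_linear": {"C": [0.1, 1.0, 10.0]},
    "svm_poly": {"C": [0.1, 1.0, 10.0], "degree": [2, 3]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "svm_sigmoid": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "rf": {
        "n_estimators": [50, 100, 200],
        "max_depth": [2, 3, 5, None],
        "max_features": ["sqrt", 0.5, None],
    },
    "xgboost": {
        "n_estimators": [50, 100, 200],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1, 0.3],
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A backend id plus its (fixed) class weighting and search grid.

    ``priors`` applies to LDA; ``class_weight`` to the other backends.
    Neither is ever part of the searched grid.
    """

    backend: str = "lda"
    grid: Mapping[str, Sequence] | None = None
    priors: tuple[float, float] | None = None
    class_weight: Mapping | str | None = None
    n_random_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(
                f"unknown backend {self.backend!r}; expected one of {BACKENDS}"
            )
        if self.priors is not None and not np.isclose(sum(self.priors), 1.0):
            raise ValueError("priors must sum to 1")

    def effective_grid(self) -> dict:
        grid = dict(self.grid) if self.grid is not None else dict(
            _DEFAULT_GRIDS[self.backend]
        )
        if self.backend.startswith("svm_"):
            # SVM backends are scaler+SVC pipelines
            grid = {
                (k if "__" in k else f"svc__{k}"): v for k, v in grid.items()
            }
        return grid


def make_estimator(spec: ClassifierSpec) -> BaseEstimator:
    """Instantiate a backend honouring the spec's fixed priors/weights."""
    if spec.backend == "lda":
        priors = list(spec.priors) if spec.priors is not None else None
        return NativeLda(shrinkage=0.5, priors=priors)
    if spec.backend.startswith("svm_"):
        kernel = spec.backend.split("_", 1)[1]
        # SVC is scale-sensitive; standardisation is fit per training set
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel=kernel, class_weight=spec.class_weight,
                            random_state=spec.seed)),
            ]
        )
    if spec.backend == "rf":
        return RandomForestClassifier(
            class_weight=spec.class_weight, random_state=spec.seed
        )
    if spec.backend == "xgboost":
        from xgboost import XGBClassifier

        weight = 1.0
        if isinstance(spec.class_weight, Mapping) and 1 in spec.class_weight:
            weight = spec.class_weight[1]
        return XGBClassifier(
            scale_pos_weight=weight, random_state=spec.seed,
            eval_metric="logloss", n_jobs=1,
        )
    raise ValueError(f"unknown backend {spec.backend!r}")  # pragma: no cover


def tune(
    spec: ClassifierSpec,
    X,
    y,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[BaseEstimator, dict]:
    """Stratified k-fold hyperparameter search, then refit on all data.

    Grid search for LDA/SVM, random search for the tree ensembles; class
    weights/priors are passed through fixed, never searched.  Folds that
    fail to fit (e.g. LDA with zero shrinkage on singular data) score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{n_folds} folds"
        )
    base = make_estimator(spec)
    grid = spec.effective_grid()
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    if spec.backend in _RANDOM_SEARCH_BACKENDS:
        n_iter = min(
            spec.n_random_iter,
            int(np.prod([len(v) for v in grid.values()])),
        )
        search = RandomizedSearchCV(
            base, grid, n_iter=n_iter, cv=cv, scoring="accuracy",
            random_state=seed, error_score=0.0, n_jobs=None, refit=False,
        )
    else:
        search = GridSearchCV(
            base, grid, cv=cv, scoring="accuracy", error_score=0.0,
            n_jobs=None, refit=False,
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
        # refit on the full training set, walking the score-ranked grid:
        # a point that fit in every fold can still be singular on the
        # full data (e.g. LDA at zero shrinkage) — fall through to the
        # next-best parameters instead of failing
        scores = search.cv_results_["mean_test_score"]
        order = np.argsort(-np.asarray(scores), kind="stable")
        last_exc: Exception | None = None
        for idx in order:
            params = search.cv_results_["params"][idx]
            est = clone(base).set_params(**params)
            try:
                est.fit(X, y)
            except Exception as exc:  # singular fit at this grid point
                last_exc = exc
                continue
            return est, dict(params)
    raise RuntimeError("no hyperparameter point could be fit") from last_exc
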