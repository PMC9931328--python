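"""Two-step feature selection: Pearson redundancy filter, then RFECV.

Step 1 removes redundant features: scanning columns in table order, a
feature is dropped if its absolute Pearson correlation with any
already-kept feature reaches the threshold (default |r| >= 0.99).
First-seen columns win ties, so the result is deterministic in the
canonical feature-dictionary order.  Constant columns (zero variance,
for which r is undefined) are dropped with a warning.

Step 2 is recursive feature elimination with cross-validation (RFECV):
features are removed one at a time by lowest estimator importance (for
LDA, the absolute discriminant coefficient), each candidate count is
scored by stratified k-fold CV accuracy (default 5 folds), and the
feature set at the score-maximising count is kept (smallest count on
ties).  The elimination loop and CV scoring are delegated to
scikit-learn's RFECV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["SelectionReport", "correlation_filter", "rfecv", "default_rfecv_estimator"]


@dataclass
class SelectionReport:
    """What the selection kept and why."""

    kept: list[str]
    dropped_redundant: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)
    cv_curve: list[tuple[int, float]] = field(default_factory=list)
    n_optimal: int | None = None

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped_redundant": [
                {"dropped": d, "kept_correlate": k, "r": r}
                for d, k, r in self.dropped_redundant
            ],
            "dropped_constant": self.dropped_constant,
            "cv_curve": [{"n_features": n, "mean_cv_score": s} for n, s in self.cv_curve],
            "n_optimal": self.n_optimal,
        }


def correlation_filter(
    table: FeatureTable, r_threshold: float = 0.99
) -> tuple[FeatureTable, SelectionReport]:
    """Drop features |r|-redundant with an earlier-kept feature.

    Deterministic given column order.  All-constant columns are dropped
    with a warning (Pearson r is undefined for them).
    """
    if len(table) < 2:
        raise ValueError("correlation filter needs at least 2 samples")
    X = table.values.to_numpy(dtype=float)
    names = table.feature_names
    sd = X.std(axis=0)
    centered = X - X.mean(axis=0)

    kept_idx: list[int] = []
    report = SelectionReport(kept=[])
    for j, name in enumerate(names):
        if sd[j] == 0.0:
            report.dropped_constant.append(name)
            continue
        redundant_with = None
        for i in kept_idx:
            r = float(
                centered[:, i] @ centered[:, j] / (len(X) * sd[i] * sd[j])
            )
            if abs(r) >= r_threshold:
                redundant_with = (names[i], r)
                break
        if redundant_with is None:
            kept_idx.append(j)
        else:
            report.dropped_redundant.append(
                (name, redundant_with[0], redundant_with[1])
            )
    report.kept = [names[i] for i in kept_idx]
    if report.dropped_constant:
        logger.warning(
            "dropped %d constant feature(s): %s",
            len(report.dropped_constant), ", ".join(report.dropped_constant),
        )
    return table.select(report.kept), report


def default_rfecv_estimator() -> BaseEstimator:
    """The selection-stage classifier: LDA, whose ``coef_`` magnitudes
    rank feature importance during elimination."""
    return LinearDiscriminantAnalysis()


def rfecv(
    table: FeatureTable,
    labels,
    estimator: BaseEstimator | None = None,
    n_folds: int = 5,
    step: int = 1,
    seed: int = 0,
) -> tuple[FeatureTable, SelectionReport]:
    """Recursive feature elimination with stratified k-fold CV.

    Returns the reduced table at the accuracy-maximising feature count
    (smallest count on ties) plus the CV curve.  Labels may be any
    binary array-like aligned with the table's rows.
    """
    y = np.asarray(labels)
    if len(y) != len(table):
        raise ValueError("labels length does not match table")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("rfecv requires binary labels")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{n_folds} CV folds"
        )
    est = clone(estimator) if estimator is not None else default_rfecv_estimator()
    X = table.values.to_numpy(dtype=float)

    if X.shape[1] == 1:
        # nothing to eliminate; score the single feature for the curve
        from sklearn.model_selection import cross_val_score

        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        score = float(np.mean(cross_val_score(est, X, y, cv=cv, scoring="accuracy")))
        report = SelectionReport(
            kept=list(table.feature_names),
            cv_curve=[(1, score)],
            n_optimal=1,
        )
        return table.select(report.kept), report

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    selector = RFECV(est, step=step, cv=cv, scoring="accuracy", n_jobs=None)
    selector.fit(X, y)
    kept = [n for n, keep in zip(table.feature_names, selector.support_) if keep]
    curve = list(
        zip(
            (int(n) for n in selector.cv_results_["n_features"]),
            (float(s) for s in selector.cv_results_["mean_test_score"]),
        )
    )
    report = SelectionReport(
        kept=kept,
        cv_curve=sorted(curve),
        n_optimal=int(selector.n_features_),
    )
    return table.select(kept), report
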