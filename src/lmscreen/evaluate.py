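"""Evaluation: confusion metrics, MCVT, and the sensitivity/specificity
trade-off.

Monte-Carlo cross-validation and testing (MCVT) is the small-cohort
evaluation protocol used throughout: each run (1) holds out one test
sample per class, drawn uniformly; (2) builds the feature table from the
remaining samples only; (3) balances the training classes with SMOTE;
(4) performs feature selection and 10-fold stratified hyperparameter
tuning on the balanced training set; and (5) predicts the two held-out
samples.  The held-out samples never influence the synthetic rows, the
selected features, or the tuned hyperparameters.  Aggregating 50 runs,
the mean sensitivity is the fraction of runs whose disordered test
sample was caught, and likewise for specificity — a robust comparison of
modelling techniques despite the two-sample test sets.

Sensitivity, specificity and accuracy are the standard confusion-matrix
ratios, with the disordered class as positive::

    sensitivity = nTP / (nTP + nFN)
    specificity = nTN / (nTN + nFP)
    accuracy    = (nTP + nTN) / (nTP + nTN + nFP + nFN)

The ROC curve for the screening trade-off is swept through LDA class
priors: one full MCVT aggregate per prior yields one (1 - specificity,
sensitivity) point; the curve is anchored at (0,0) and (1,1) and AUC is
the trapezoid area.  A conventional score-threshold ROC is also
provided for diagnostics on scored samples.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import ClassifierSpec, tune
from .features import (
    FeatureTable,
    assemble_features,
    cohort_alphabet,
    compute_features,
)
from .landmark_io import CohortManifest, LandmarkStream
from .resampling import SmoteConfig, smote_balance
from .selection import correlation_filter, rfecv

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "metrics",
    "MCVTConfig",
    "MCVTReport",
    "mcvt_run",
    "mcvt",
    "RocCurve",
    "roc_by_priors",
    "roc_from_scores",
]

POSITIVE_LABEL = "disordered"
NEGATIVE_LABEL = "normal"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts; positive = disordered."""

    n_tp: int = 0
    n_fp: int = 0
    n_tn: int = 0
    n_fn: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_tn, self.n_fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_tn + self.n_fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.n_tp + other.n_tp, self.n_fp + other.n_fp,
            self.n_tn + other.n_tn, self.n_fn + other.n_fn,
        )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts.

    A zero denominator yields NaN for that metric (and for accuracy when
    there are no samples at all); callers exclude NaNs from aggregation.
    """
    pos = counts.n_tp + counts.n_fn
    neg = counts.n_tn + counts.n_fp
    sens = counts.n_tp / pos if pos > 0 else math.nan
    spec = counts.n_tn / neg if neg > 0 else math.nan
    if pos == 0 or neg == 0:
        logger.warning("zero denominator in metrics: P=%d N=%d", pos, neg)
    acc = (counts.n_tp + counts.n_tn) / counts.total if counts.total else math.nan
    return sens, spec, acc


# ---------------------------------------------------------------------------
# MCVT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCVTConfig:
    """Protocol parameters for Monte-Carlo cross-validation and testing."""

    n_runs: int = 50
    master_seed: int = 0
    selection_mode: str = "per-run"     # 'per-run' | 'fixed-global' | 'none'
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    corr_threshold: float = 0.99
    rfecv_folds: int = 5
    tune_folds: int = 10

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.selection_mode not in ("per-run", "fixed-global", "none"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


@dataclass
class MCVTReport:
    """Per-run records plus their aggregate means.

    With one test sample per class, per-run sensitivity and specificity
    are 0/1 indicators, so their across-run standard deviations are
    degenerate; they are stored but flagged and not used for comparison.
    """

    runs: list[dict]
    mean_sensitivity: float
    mean_specificity: float
    mean_accuracy: float
    std_sensitivity: float
    std_specificity: float
    std_degenerate: bool = True

    @classmethod
    def from_runs(cls, runs: list[dict]) -> "MCVTReport":
        sens = np.array([r["sensitivity"] for r in runs], dtype=float)
        spec = np.array([r["specificity"] for r in runs], dtype=float)
        acc = np.array([r["accuracy"] for r in runs], dtype=float)
        return cls(
            runs=runs,
            mean_sensitivity=float(np.nanmean(sens)),
            mean_specificity=float(np.nanmean(spec)),
            mean_accuracy=float(np.nanmean(acc)),
            std_sensitivity=float(np.nanstd(sens)),
            std_specificity=float(np.nanstd(spec)),
        )

    def to_dict(self) -> dict:
        return {
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_accuracy": self.mean_accuracy,
            "std_sensitivity": self.std_sensitivity,
            "std_specificity": self.std_specificity,
            "std_degenerate": self.std_degenerate,
            "n_runs": len(self.runs),
            "runs": self.runs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _labels_by_id(manifest: CohortManifest) -> dict[str, str]:
    return manifest.labels()


def _encode(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if lbl == POSITIVE_LABEL else 0 for lbl in labels])


def _featurize_test(
    stream: LandmarkStream,
    alphabet: dict[int, list[str]],
    columns: Sequence[str],
    train_means: np.ndarray,
) -> np.ndarray:
    """Feature vector for a held-out sample over training-defined columns.

    Values the sample cannot define (absent token, zero denominator) are
    imputed with the training-column mean — an imputation fit on training
    data only.
    """
    raw = compute_features(stream, alphabet)
    vec = np.array([raw.get(c, math.nan) for c in columns], dtype=float)
    missing = ~np.isfinite(vec)
    vec[missing] = train_means[missing]
    return vec


def run_selection(
    table: FeatureTable,
    y: np.ndarray,
    config: MCVTConfig,
    seed: int,
):
    """Correlation filter then RFECV; returns (reduced table, reports)."""
    filtered, corr_report = correlation_filter(table, config.corr_threshold)
    selected, rfe_report = rfecv(
        filtered, y, n_folds=config.rfecv_folds, seed=seed
    )
    return selected, corr_report, rfe_report


def mcvt_run(
    streams: Sequence[LandmarkStream],
    manifest: CohortManifest,
    config: MCVTConfig,
    run_seed: int,
    fixed_features: Sequence[str] | None = None,
) -> dict:
    """One leave-one-per-class-out run; deterministic in run_seed.

    Returns a record with the held-out ids, the training class counts
    before and after SMOTE, the selected features and tuned
    hyperparameters, the per-run confusion counts and metrics.
    """
    labels = _labels_by_id(manifest)
    by_class: dict[str, list[LandmarkStream]] = {
        NEGATIVE_LABEL: [], POSITIVE_LABEL: []
    }
    for s in streams:
        by_class[labels[s.sample_id]].append(s)
    for lbl, group in by_class.items():
        if len(group) < 2:
            raise ValueError(
                f"class {lbl!r} has {len(group)} samples; MCVT needs >= 2"
            )

    rng = np.random.default_rng(run_seed)
    test_streams: list[LandmarkStream] = []
    train_streams: list[LandmarkStream] = []
    for lbl in (NEGATIVE_LABEL, POSITIVE_LABEL):
        group = by_class[lbl]
        held = int(rng.integers(len(group)))
        test_streams.append(group[held])
        train_streams.extend(s for i, s in enumerate(group) if i != held)

    train_labels = [labels[s.sample_id] for s in train_streams]
    n_train_neg = train_labels.count(NEGATIVE_LABEL)
    n_train_pos = train_labels.count(POSITIVE_LABEL)

    # feature engineering and pruning on training samples only
    table = assemble_features(train_streams)
    alphabet = cohort_alphabet(train_streams)
    y_train = _encode(train_labels)

    # SMOTE balances the training classes; test samples are already out
    smote_cfg = replace(
        config.smote,
        seed=int(rng.integers(2**31)),
        integer_mask=(
            config.smote.integer_mask
            if config.smote.integer_mask is not None
            else table.integer_mask()
        ),
    )
    balanced_df, balanced_y = smote_balance(table, y_train, smote_cfg)
    balanced = FeatureTable(values=balanced_df, categories=dict(table.categories))
    n_balanced = balanced_y.value_counts().to_dict()

    # feature selection on the balanced training set
    selected_names: list[str]
    n_filtered = None
    if config.selection_mode == "per-run" and fixed_features is None:
        sel_seed = int(rng.integers(2**31))
        selected, corr_report, rfe_report = run_selection(
            balanced, balanced_y.to_numpy(), config, sel_seed
        )
        selected_names = list(selected.feature_names)
        n_filtered = len(corr_report.kept)
    elif fixed_features is not None or config.selection_mode == "fixed-global":
        wanted = list(fixed_features or [])
        selected_names = [n for n in wanted if n in balanced.feature_names]
        selected = balanced.select(selected_names)
    else:  # 'none'
        selected_names = list(balanced.feature_names)
        selected = balanced

    # hyperparameter tuning (10-fold stratified CV) and final fit
    tune_seed = int(rng.integers(2**31))
    model, best_params = tune(
        config.classifier,
        selected.values.to_numpy(dtype=float),
        balanced_y.to_numpy(),
        n_folds=config.tune_folds,
        seed=tune_seed,
    )

    # predict the two held-out samples
    train_means = table.values[selected_names].to_numpy(dtype=float).mean(axis=0)
    counts = ConfusionCounts()
    test_records = []
    for s in test_streams:
        x = _featurize_test(s, alphabet, selected_names, train_means)
        pred = int(model.predict(x[np.newaxis, :])[0])
        truth = 1 if labels[s.sample_id] == POSITIVE_LABEL else 0
        counts = counts + ConfusionCounts(
            n_tp=int(pred == 1 and truth == 1),
            n_fp=int(pred == 1 and truth == 0),
            n_tn=int(pred == 0 and truth == 0),
            n_fn=int(pred == 0 and truth == 1),
        )
        test_records.append(
            {"sample_id": s.sample_id, "truth": truth, "predicted": pred}
        )
    sens, spec, acc = metrics(counts)
    record = {
        "run_seed": int(run_seed),
        "test_samples": test_records,
        "n_train_majority": n_train_neg,
        "n_train_minority": n_train_pos,
        "n_balanced": {str(k): int(v) for k, v in n_balanced.items()},
        "n_features_filtered": n_filtered,
        "n_features_selected": len(selected_names),
        "selected_features": selected_names,
        "hyperparameters": {k: repr(v) for k, v in best_params.items()},
        "confusion": {
            "n_tp": counts.n_tp, "n_fp": counts.n_fp,
            "n_tn": counts.n_tn, "n_fn": counts.n_fn,
        },
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
    }
    logger.info(
        "MCVT run seed=%d test=%s sens=%.0f spec=%.0f features=%d params=%s",
        run_seed, [t["sample_id"] for t in test_records],
        sens, spec, len(selected_names), best_params,
    )
    return record


def _run_seed(master_seed: int, index: int) -> int:
    """Counter-based per-run seed derivation from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def mcvt(
    streams: Sequence[LandmarkStream],
    manifest: CohortManifest,
    config: MCVTConfig,
) -> MCVTReport:
    """Aggregate ``config.n_runs`` independent MCVT runs.

    In ``fixed-global`` selection mode the two-step selection is
    performed once on the full cohort feature table before any split and
    the resulting feature list reused in every run; ``per-run`` (the
    leakage-safe default) re-selects inside each training partition.
    """
    fixed_features = None
    if config.selection_mode == "fixed-global":
        table = assemble_features(streams, manifest)
        labels = _labels_by_id(manifest)
        y = _encode([labels[sid] for sid in table.sample_ids])
        selected, _, _ = run_selection(table, y, config, config.master_seed)
        fixed_features = list(selected.feature_names)
        logger.info("fixed-global selection kept %d features", len(fixed_features))
    runs = [
        mcvt_run(
            streams, manifest, config,
            run_seed=_run_seed(config.master_seed, i),
            fixed_features=fixed_features,
        )
        for i in range(config.n_runs)
    ]
    return MCVTReport.from_runs(runs)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Operating points (1 - specificity, sensitivity) and trapezoid AUC."""

    points: list[dict]
    auc: float

    def to_dict(self) -> dict:
        return {"auc": self.auc, "points": self.points}


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """AUC over points anchored at (0,0) and (1,1), sorted by x then y."""
    x = np.concatenate([[0.0], fpr, [1.0]])
    y = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def roc_by_priors(
    streams: Sequence[LandmarkStream],
    manifest: CohortManifest,
    config: MCVTConfig,
    prior_grid: Sequence[tuple[float, float]],
) -> RocCurve:
    """One MCVT aggregate per class prior, assembled into an ROC curve.

    Priors are (normal, disordered) pairs summing to 1, applied to the
    LDA classifier (or mapped to class weights for other backends via
    the spec).  Each grid point costs a full MCVT.
    """
    fprs, tprs, points = [], [], []
    for prior in prior_grid:
        if not np.isclose(sum(prior), 1.0):
            raise ValueError(f"prior {prior} does not sum to 1")
        spec_with_prior = replace(
            config.classifier, priors=(float(prior[0]), float(prior[1]))
        )
        report = mcvt(streams, manifest, replace(config, classifier=spec_with_prior))
        fpr = 1.0 - report.mean_specificity
        tpr = report.mean_sensitivity
        fprs.append(fpr)
        tprs.append(tpr)
        points.append(
            {
                "prior_normal": prior[0],
                "prior_disordered": prior[1],
                "fpr": fpr,
                "sensitivity": tpr,
                "specificity": report.mean_specificity,
                "accuracy": report.mean_accuracy,
            }
        )
    points.sort(key=lambda p: (p["fpr"], p["sensitivity"]))
    return RocCurve(points=points, auc=_trapezoid_auc(np.array(fprs), np.array(tprs)))


def roc_from_scores(y_true, scores) -> RocCurve:
    """Conventional score-threshold ROC (diagnostic view).

    Thresholds sweep the continuous decision scores of a single fitted
    classifier; positive class = 1.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = _sk_roc(y_true, scores)
    points = [
        {"fpr": float(f), "sensitivity": float(t), "threshold": float(th)}
        for f, t, th in zip(fpr, tpr, thresholds)
    ]
    return RocCurve(points=points, auc=_trapezoid_auc(fpr, tpr))
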