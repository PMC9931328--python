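"""From-scratch SMOTE with integer-feature rounding, for training data only.

SMOTE (synthetic minority over-sampling technique) synthesises new
minority-class samples by linear interpolation between a randomly chosen
minority sample ``a`` and one of its k Euclidean nearest minority
neighbours ``b``::

    x_new = x_a + lambda * (x_b - x_a),   lambda ~ Uniform[0, 1]

Features that only take integer values (the count categories: n-gram
counts and syllabic-cluster count) are rounded to the nearest integer
(half away from zero).  Exactly (majority - minority) synthetic rows are
generated, so the output classes are fully balanced.

SMOTE belongs strictly to the training partition: held-out test samples
must never influence the synthetic rows (see the evaluation module).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["SmoteConfig", "smote_interpolate", "smote_balance"]


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE parameters: neighbourhood size, seed, integer columns."""

    k_neighbors: int = 5
    seed: int = 0
    integer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def smote_interpolate(
    x_a: np.ndarray,
    x_b: np.ndarray,
    lam: float,
    integer_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One synthetic sample on the segment from x_a to x_b.

    ``lam = 0`` returns x_a exactly and ``lam = 1`` returns x_b; masked
    coordinates are rounded to the nearest integer (half away from zero).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError("x_a and x_b must have the same shape")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    x_new = x_a + lam * (x_b - x_a)
    if integer_mask is not None:
        mask = np.asarray(integer_mask, dtype=bool)
        x_new = np.where(mask, _round_half_away(x_new), x_new)
    return x_new


def minority_knn(X_min: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority sample's k nearest minority neighbours.

    Brute-force Euclidean all-pairs distances; self excluded.  Ties are
    broken by index (stable argsort), making the neighbourhood
    deterministic.
    """
    d = cdist(X_min, X_min)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def smote_balance(
    table: FeatureTable | pd.DataFrame,
    labels,
    config: SmoteConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Balance a binary training table by SMOTE over-sampling.

    Exactly (majority - minority) synthetic minority rows are appended
    after the unchanged original rows, each built by picking a random
    minority sample, one of its k nearest minority neighbours, and a
    uniform interpolation factor.  If ``config.integer_mask`` is unset
    and *table* is a :class:`FeatureTable`, count-category columns are
    rounded automatically.
    """
    if isinstance(table, FeatureTable):
        df = table.values
        integer_mask = (
            config.integer_mask
            if config.integer_mask is not None
            else table.integer_mask()
        )
    else:
        df = table
        integer_mask = config.integer_mask

    y = pd.Series(np.asarray(labels), index=df.index, name="label")
    counts = y.value_counts()
    if len(counts) != 2:
        raise ValueError(f"smote_balance requires 2 classes, got {len(counts)}")
    if counts.min() == 0 or counts.min() < 2:
        raise ValueError("minority class needs at least 2 samples")
    minority_label = counts.idxmin()
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return df.copy(), y.copy()

    k = config.k_neighbors
    n_min = int(counts.min())
    if k >= n_min:
        k = n_min - 1
        logger.warning(
            "k_neighbors=%d >= minority size %d; reduced to %d",
            config.k_neighbors, n_min, k,
        )

    X_min = df.loc[y == minority_label].to_numpy(dtype=float)
    neighbours = minority_knn(X_min, k)
    rng = np.random.default_rng(config.seed)

    synth = np.empty((n_new, df.shape[1]))
    for i in range(n_new):
        a = int(rng.integers(n_min))
        b = int(neighbours[a][int(rng.integers(k))])
        lam = float(rng.uniform(0.0, 1.0))
        synth[i] = smote_interpolate(X_min[a], X_min[b], lam, integer_mask)

    synth_index = [f"smote_{minority_label}_{i:03d}" for i in range(n_new)]
    synth_df = pd.DataFrame(synth, index=synth_index, columns=df.columns)
    out_df = pd.concat([df, synth_df])
    out_y = pd.concat(
        [y, pd.Series([minority_label] * n_new, index=synth_index, name="label")]
    )
    return out_df, out_y
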