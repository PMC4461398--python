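"""Death-threshold estimation and fate classification.

A cell dies iff its peak C8 activity Max(C8) reaches the threshold theta.
The threshold is estimated from data by minimizing the misclassification
count

    E(theta) = #{dead cells with Max < theta} + #{surviving cells with Max >= theta}

(a cell sitting exactly on theta is classified as dying — the ">=" tie rule
is used consistently everywhere).  E is piecewise constant between
consecutive unique Max values, so scanning the midpoints of consecutive
sorted unique values (plus one candidate below the minimum and one above the
maximum) is an exact minimization; ties go to the smallest candidate.

The same threshold defines the fate boundary in the (k, tau) landscape,
``tau = theta / (2 k) + t0_bar`` with t0_bar the population-mean lag, which
is benchmarked against a linear maximum-margin (SVM) classifier trained on
(log10 k, tau).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import FATE_DIED

__all__ = [
    "ThresholdResult",
    "BoundaryClassifier",
    "misclassification_error",
    "estimate_theta",
    "accuracy_at",
    "classify_by_boundary",
    "fit_linear_margin_classifier",
    "bootstrap_sem",
]


def _as_died(fates) -> np.ndarray:
    fates = np.asarray(fates)
    if fates.dtype == bool:
        return fates
    return fates == FATE_DIED


@dataclass
class ThresholdResult:
    theta_hat: float  # a.u. min^-1
    error_count: int
    accuracy: float
    n_cells: int
    candidate_grid: np.ndarray
    sem_accuracy: float | None = None
    degenerate: bool = False


def misclassification_error(theta: float, max_values, fates) -> int:
    """E(theta): dead cells below theta plus surviving cells at/above it."""
    mv = np.asarray(max_values, dtype=float)
    died = _as_died(fates)
    return int(np.sum(died & (mv < theta)) + np.sum(~died & (mv >= theta)))


def _candidate_grid(mv: np.ndarray) -> np.ndarray:
    uniq = np.unique(mv)
    span = uniq[-1] - uniq[0]
    pad = span / 2.0 if span > 0 else max(abs(uniq[0]), 1.0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - pad], mids, [uniq[-1] + pad]])


def estimate_theta(max_values, fates) -> ThresholdResult:
    """Minimize the misclassification count over the exact candidate grid."""
    mv = np.asarray(max_values, dtype=float)
    died = _as_died(fates)
    n = len(mv)
    if n == 0:
        raise ValueError("no cells")
    grid = _candidate_grid(mv)

    if died.all() or (~died).all():
        # single-fate input: an extreme threshold classifies everything right
        theta = grid[0] if died.all() else grid[-1]
        return ThresholdResult(float(theta), 0, 1.0, n, grid, degenerate=True)

    dead_sorted = np.sort(mv[died])
    alive_sorted = np.sort(mv[~died])
    # E(theta) = #dead < theta + #alive >= theta
    n_dead_below = np.searchsorted(dead_sorted, grid, side="left")
    n_alive_at_or_above = len(alive_sorted) - np.searchsorted(alive_sorted, grid, side="left")
    errors = n_dead_below + n_alive_at_or_above
    i = int(np.argmin(errors))  # first index = smallest optimal theta
    e = int(errors[i])
    return ThresholdResult(
        theta_hat=float(grid[i]),
        error_count=e,
        accuracy=1.0 - e / n,
        n_cells=n,
        candidate_grid=grid,
    )


def accuracy_at(theta: float, max_values, fates) -> float:
    """Classification accuracy of a given threshold (same tie rule)."""
    mv = np.asarray(max_values, dtype=float)
    if len(mv) == 0:
        raise ValueError("no cells")
    return 1.0 - misclassification_error(theta, mv, fates) / len(mv)


@dataclass(frozen=True)
class BoundaryClassifier:
    """The analytic fate boundary ``tau = theta/(2k) + t0_bar``."""

    theta: float  # a.u. min^-1
    t0_bar: float = 20.0  # min, population-mean lag

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


def classify_by_boundary(k, tau, clf: BoundaryClassifier) -> np.ndarray:
    """Predict death iff ``2 k (tau - t0_bar) >= theta`` (k = 0 survives)."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    return (k > 0) & (2.0 * k * (tau - clf.t0_bar) >= clf.theta)


def fit_linear_margin_classifier(k, tau, fates) -> dict:
    """Linear SVM on standardized (log10 k, tau); returns training accuracy.

    The comparison with the analytic boundary is descriptive, so training
    accuracy (not held-out) is reported, mirroring how boundary accuracies
    are scored.
    """
    died = _as_died(fates)
    if died.all() or (~died).all():
        raise ValueError("both fates required to train a classifier")
    X = np.column_stack([np.log10(np.asarray(k, dtype=float)), np.asarray(tau, dtype=float)])
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(scaler.transform(X), died)
    pred = svm.predict(scaler.transform(X))
    return {
        "model": svm,
        "scaler": scaler,
        "predicted_died": pred.astype(bool),
        "accuracy": float(np.mean(pred == died)),
        "coef": svm.coef_[0].copy(),
        "intercept": float(svm.intercept_[0]),
    }


def bootstrap_sem(
    statistic: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """SD of a statistic over cell-level resamples with replacement.

    The single-dataset analog of a between-replicate SEM: ``statistic`` must
    be a pure function of the data frame.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(data)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[i] = statistic(data.iloc[idx])
    return float(np.std(vals, ddof=1))
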