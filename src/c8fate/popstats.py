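"""Population-level summaries and relations.

Summaries per condition: geometric-mean activation rate k (floor-fallback
cells included — the floor value is part of the population statistic), mean
activation-phase end tau, and the surviving fraction.  Across conditions the
surviving fraction follows a logistic curve in the mean of log10(k); per-cell
resistance-factor analyses use rank statistics (Spearman correlation, rank-sum
test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit
from scipy.stats import mannwhitneyu, spearmanr

from .datatypes import FATE_DIED, FATE_SURVIVED

__all__ = [
    "ConditionSummary",
    "LogisticFit",
    "summarize_condition",
    "fit_logistic_survival",
    "rank_association",
    "rank_sum_test",
]


@dataclass
class ConditionSummary:
    condition: str
    n_cells: int
    geomean_k: float  # a.u. min^-2
    mean_log10_k: float
    sem_log10_k: float
    mean_tau: float  # min
    sem_tau: float
    surviving_fraction: float
    sem_surviving_fraction: float


def summarize_condition(fits: pd.DataFrame, condition: str | None = None) -> ConditionSummary:
    """Summarize the non-discarded cells of one condition.

    ``fits`` needs columns ``k``, ``tau``, ``fate`` (and optionally
    ``discarded`` and ``condition``).  Fallback (floor-rate) cells are
    included: the floor is part of the population statistic.
    """
    df = fits
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]
    if "discarded" in df.columns:
        df = df[~df["discarded"].astype(bool)]
    if len(df) == 0:
        raise ValueError(f"no non-discarded cells in condition {condition!r}")

    n = len(df)
    log_k = np.log10(df["k"].to_numpy(float))
    tau = df["tau"].to_numpy(float)
    surviving = (df["fate"] == FATE_SURVIVED).to_numpy()
    frac = float(surviving.mean())
    return ConditionSummary(
        condition=condition if condition is not None else "(all)",
        n_cells=n,
        geomean_k=float(10.0 ** log_k.mean()),
        mean_log10_k=float(log_k.mean()),
        sem_log10_k=float(log_k.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_tau=float(tau.mean()),
        sem_tau=float(tau.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        surviving_fraction=frac,
        sem_surviving_fraction=float(np.sqrt(frac * (1 - frac) / n)),
    )


@dataclass
class LogisticFit:
    midpoint: float  # mean log10 k at half survival
    slope: float  # decades^-1 (negative: survival falls as k rises)
    r2: float
    identifiable: bool


def _logistic(x, midpoint, slope):
    return expit(slope * (x - midpoint))


def fit_logistic_survival(
    mean_log10_k: np.ndarray, surviving_fraction: np.ndarray
) -> LogisticFit:
    """Least-squares logistic fit of survival vs mean log10 k across conditions.

    Two parameters (midpoint, slope) with asymptotes fixed at 0 and 1 —
    survival is a fraction by construction.  Conditions that never cross
    half-survival cannot pin the midpoint; the fit is then flagged
    unidentifiable (parameters are still the best found).
    """
    x = np.asarray(mean_log10_k, dtype=float)
    s = np.asarray(surviving_fraction, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 conditions")
    identifiable = bool(s.min() < 0.5 < s.max())

    x0 = float(x[np.argmin(np.abs(s - 0.5))])
    span = x.max() - x.min()
    slope0 = -4.0 / span if span > 0 else -1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_logistic, x, s, p0=[x0, slope0], maxfev=10000)
        midpoint, slope = float(popt[0]), float(popt[1])
    except RuntimeError:
        midpoint, slope, identifiable = x0, slope0, False
    resid = s - _logistic(x, midpoint, slope)
    tss = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return LogisticFit(midpoint=midpoint, slope=slope, r2=r2, identifiable=identifiable)


def rank_association(levels, values, seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation between an expression proxy and a statistic.

    For n < 20 the p-value comes from a seeded permutation null (10,000
    resamples); otherwise from the large-sample approximation.  Constant
    input has no defined rank correlation: returns (nan, nan) with a warning.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need n >= 5 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: rank correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    if len(x) < 20:
        rng = np.random.default_rng(seed)
        n_perm = 10000
        count = 0
        for _ in range(n_perm):
            r_perm, _ = spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(rho), float(p)


def rank_sum_test(values, group_mask) -> tuple[float, float]:
    """Two-sample rank-sum (Mann-Whitney) comparison for a binary grouping."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_mask, dtype=bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    stat, p = mannwhitneyu(v[g], v[~g], alternative="two-sided")
    return float(stat), float(p)
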