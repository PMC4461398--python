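"""Closed-form calibration of the population simulator to printed anchors.

The generator assumes a simple extrinsic-noise model for TRAIL-induced
apoptosis.  Per cell, the peak initiator-caspase activity is
``Max(C8) = 2 k (tau - t0)`` and the cell dies iff Max(C8) reaches its private
threshold.  On a log10 scale both sides are Gaussian and independent:

    M = log10 Max(C8) ~ N(mu_M(dose), sigma_M^2)
    L = log10 theta_cell ~ N(log10 theta_pop, sigma_theta^2)

so the dying fraction at a dose is ``Phi((mu_M - mu_L) / sigma_tot)`` with
``sigma_tot = sqrt(sigma_M^2 + sigma_theta^2)``, and the best achievable
accuracy of a single fixed threshold on Max(C8), at the dose where the two
distributions are centred on each other, is

    acc* = 1 - arctan(sigma_theta / sigma_M) / pi.

These relations let a handful of published population anchors (dying fractions
at three doses, the fold change in geometric-mean k across the dose range, the
fixed-threshold classification accuracy, and the threshold value itself)
determine every distribution parameter in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .datatypes import DOSE_LADDER, PopulationParams


class CalibrationError(ValueError):
    """Raised when the anchor set admits no positive solution."""


@dataclass(frozen=True)
class PopulationAnchors:
    """Published population constants that pin down the generator.

    Defaults are the HeLa/TRAIL values: ~50% killing at 25 ng/ml, a 4% -> 92%
    rise in the dying fraction as dose goes 1 -> 500 ng/ml alongside a
    ~140-fold rise in geometric-mean k, a best fixed-threshold accuracy of
    83%, and a population threshold theta = 2.63e-3 a.u. min^-1.  The
    geometric-mean activation-phase duration (240 min) and its ±2 SD fold
    spread (2.5x) are design constants: survivor activity peaks at 2-4 h and
    the duration varies two- to threefold across cells.
    """

    theta_pop: float = 2.63e-3
    kill_by_dose: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.04, 25.0: 0.50, 500.0: 0.92}
    )
    k_fold_span: float = 140.0  # GM-k ratio between highest and lowest anchor dose
    accuracy: float = 0.83
    gm_tau_minus_t0: float = 240.0
    tau_fold_spread: float = 2.5  # +/- 2 SD band of tau - t0 across cells


def calibrate_population(
    anchors: PopulationAnchors | None = None,
    dose_ladder: tuple[float, ...] = DOSE_LADDER,
    **overrides,
) -> PopulationParams:
    """Solve the anchor constraints for the population parameters.

    Steps (all closed form):

    1. ``sigma_tot`` from the dose-extreme kill fractions and the GM-k fold
       span: ``(z_hi - z_lo) * sigma_tot = log10(fold)`` with
       ``z_d = Phi^-1(kill_d)``.
    2. Partition into ``sigma_M`` and ``sigma_theta`` from the accuracy
       anchor: ``sigma_theta / sigma_M = tan(pi (1 - accuracy))``.
    3. Partition ``sigma_M`` into ``sigma_k`` and ``sigma_tau`` with
       ``sigma_tau`` fixed by the tau fold-spread design constant.
    4. Anchor ``mu_M(dose) = log10(theta_pop) + z_d * sigma_tot`` at the
       anchor doses, interpolate linearly in log10(dose) across the ladder,
       and convert to geometric-mean k via
       ``GM k = 10^mu_M / (2 GM(tau - t0))``.

    Parameters
    ----------
    anchors:
        Anchor set; defaults to the published values.
    dose_ladder:
        Doses (ng/ml) at which to tabulate geometric-mean k.
    **overrides:
        Passed through to :class:`PopulationParams` (e.g. ``noise_sd``).

    Raises
    ------
    CalibrationError
        Naming the violated constraint if no positive solution exists.
    """
    a = anchors or PopulationAnchors()
    for dose, kill in a.kill_by_dose.items():
        if not 0.0 < kill < 1.0:
            raise CalibrationError(f"kill fraction at dose {dose} must be in (0, 1)")
    if len(a.kill_by_dose) < 2:
        raise CalibrationError("need kill anchors at >= 2 doses")
    if a.k_fold_span <= 1.0:
        raise CalibrationError("k_fold_span must exceed 1")
    if not 0.5 < a.accuracy < 1.0:
        raise CalibrationError("accuracy anchor must lie in (0.5, 1)")
    if a.tau_fold_spread <= 1.0:
        raise CalibrationError("tau_fold_spread must exceed 1")

    doses = np.array(sorted(a.kill_by_dose), dtype=float)
    z = norm.ppf([a.kill_by_dose[d] for d in doses])
    z_span = z[-1] - z[0]
    if z_span <= 0:
        raise CalibrationError("kill fraction must increase from lowest to highest dose")
    sigma_tot = float(np.log10(a.k_fold_span) / z_span)

    ratio = float(np.tan(np.pi * (1.0 - a.accuracy)))  # sigma_theta / sigma_M
    sigma_m = sigma_tot / float(np.hypot(1.0, ratio))
    sigma_theta = ratio * sigma_m

    sigma_tau = float(np.log10(a.tau_fold_spread) / 4.0)
    if sigma_tau >= sigma_m:
        raise CalibrationError(
            "tau spread alone exceeds the calibrated Max(C8) spread; "
            "no positive sigma_k exists"
        )
    sigma_k = float(np.sqrt(sigma_m**2 - sigma_tau**2))

    mu_l = float(np.log10(a.theta_pop))
    mu_m_anchor = mu_l + z * sigma_tot
    ladder = np.asarray(sorted(set(dose_ladder) | set(doses)), dtype=float)
    mu_m = np.interp(np.log10(ladder), np.log10(doses), mu_m_anchor)
    gm_k = 10.0**mu_m / (2.0 * a.gm_tau_minus_t0)
    gm_k_by_dose = {float(d): float(k) for d, k in zip(ladder, gm_k)}

    return PopulationParams(
        theta_pop=a.theta_pop,
        sigma_theta=sigma_theta,
        gm_k_by_dose=gm_k_by_dose,
        sigma_k=sigma_k,
        gm_tau_minus_t0=a.gm_tau_minus_t0,
        sigma_tau=sigma_tau,
        **overrides,
    )


def expected_kill_fraction(params: PopulationParams, dose: float,
                           k_multiplier: float = 1.0,
                           tau_multiplier: float = 1.0,
                           theta_multiplier: float = 1.0) -> float:
    """Closed-form dying fraction ``Phi((mu_M - mu_L)/sigma_tot)`` for a condition."""
    if dose not in params.gm_k_by_dose:
        raise KeyError(f"dose {dose} not in calibrated ladder")
    mu_m = np.log10(
        2.0
        * params.gm_k_by_dose[dose]
        * k_multiplier
        * params.gm_tau_minus_t0
        * tau_multiplier
    )
    mu_l = np.log10(params.theta_pop * theta_multiplier)
    sigma_tot = np.hypot(params.sigma_max, params.sigma_theta)
    return float(norm.cdf((mu_m - mu_l) / sigma_tot))


def best_threshold_accuracy(sigma_theta: float, sigma_m: float) -> float:
    """Best single-threshold accuracy when rate and threshold spreads are centred.

    ``1 - arctan(sigma_theta / sigma_M) / pi``: the misclassified cells are
    those whose private threshold and peak activity fall on opposite sides of
    the population threshold, a quadrant probability of the bivariate normal
    (M - mu, M - L).
    """
    return float(1.0 - np.arctan2(sigma_theta, sigma_m) / np.pi)
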