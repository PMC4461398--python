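"""Shared domain containers.

The analysis revolves around per-cell FRET-ratio time series FR(t) sampled on a
uniform grid (one frame every 5 min), annotated with the cell's eventual fate
(died or survived) and, for dying cells, the time of death.  The synthetic
generator additionally carries the ground-truth kinetic parameters of each
simulated cell so that parameter-recovery tests can compare estimates against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

FATE_DIED = "died"
FATE_SURVIVED = "survived"

#: Standard TRAIL dose ladder (ng/ml) carried by a calibrated population.
DOSE_LADDER: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)


@dataclass(frozen=True)
class PopulationParams:
    """Population-level distribution parameters for the trajectory generator.

    Per-cell quantities are lognormal on a log10 (decades) scale: the C8
    activation rate ``k`` (a.u. min^-2), the activation-phase duration
    ``tau - t0`` (min), and the per-cell death threshold on peak C8 activity
    (a.u. min^-1).  The lag time ``t0`` is Gaussian truncated at zero.

    Attributes
    ----------
    theta_pop:
        Population (geometric-mean) death threshold on Max(C8), a.u. min^-1.
    sigma_theta:
        SD of per-cell log10 threshold deviation, decades.
    gm_k_by_dose:
        Map from dose (ng/ml) to the geometric mean of k, a.u. min^-2.
    sigma_k:
        SD of log10 k across cells, decades.
    gm_tau_minus_t0:
        Geometric mean of the activation-phase duration tau - t0, min.
    sigma_tau:
        SD of log10(tau - t0), decades.
    t0_mean, t0_sd:
        Lag-time distribution (min); Gaussian truncated at 0.
    noise_sd:
        Additive Gaussian measurement noise on FR, a.u.
    decay_tc:
        Survivor post-peak derivative decay time constant, min.
    frame_interval:
        Imaging interval, min.
    horizon:
        Analysis window, min (activation phases are censored here).
    record_length:
        Full recording length, min (survivor trajectories span it).
    """

    theta_pop: float
    sigma_theta: float
    gm_k_by_dose: Mapping[float, float]
    sigma_k: float
    gm_tau_minus_t0: float
    sigma_tau: float
    t0_mean: float = 20.0
    t0_sd: float = 5.0
    noise_sd: float = 0.0015
    decay_tc: float = 90.0
    frame_interval: float = 5.0
    horizon: float = 600.0
    record_length: float = 1320.0

    def __post_init__(self) -> None:
        for name in ("sigma_theta", "sigma_k", "sigma_tau", "t0_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("theta_pop", "gm_tau_minus_t0", "frame_interval", "decay_tc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.gm_k_by_dose.values()):
            raise ValueError("all geometric-mean k values must be > 0")
        n_frames = self.horizon / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("horizon must be an integer multiple of frame_interval")

    @property
    def sigma_max(self) -> float:
        """SD of log10 Max(C8) across cells (decades): sqrt(sigma_k^2 + sigma_tau^2)."""
        return float(np.hypot(self.sigma_k, self.sigma_tau))


@dataclass(frozen=True)
class Scenario:
    """A named experimental condition mapped onto generator knobs.

    ``dose_key`` selects the geometric-mean k from the calibrated dose ladder;
    multipliers model perturbations: receptor clustering with anti-Fc raises k
    severalfold, proteasome inhibition (bortezomib) extends tau and suppresses
    the survivor decay, FLIP overexpression lowers k, and Bcl-2 family
    modulation shifts the death threshold (ABT-263 down, overexpression up).
    """

    label: str
    dose_key: float
    k_multiplier: float = 1.0
    tau_multiplier: float = 1.0
    theta_multiplier: float = 1.0
    suppress_decay: bool = False

    def __post_init__(self) -> None:
        for name in ("k_multiplier", "tau_multiplier", "theta_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CellParams:
    """Ground truth for one simulated cell."""

    cell_id: str
    k_true: float  # a.u. min^-2
    t0_true: float  # min
    tau_true: float  # min
    theta_cell: float  # a.u. min^-1
    fate: str  # FATE_DIED | FATE_SURVIVED
    death_time: float | None = None  # min; defined only for dying cells

    @property
    def max_c8_true(self) -> float:
        """Peak C8 activity 2 k (tau - t0), a.u. min^-1."""
        return 2.0 * self.k_true * (self.tau_true - self.t0_true)


@dataclass
class Trajectory:
    """One cell's FRET-ratio time series on a uniform grid."""

    cell_id: str
    times: np.ndarray  # min, uniform, strictly increasing
    fr: np.ndarray  # a.u.
    fate: str | None = None
    death_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fr = np.asarray(self.fr, dtype=float)
        if self.times.shape != self.fr.shape:
            raise ValueError("times and fr must have the same length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def validate(self) -> None:
        if len(self.times) < 2:
            raise ValueError(f"{self.cell_id}: trajectory too short")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError(f"{self.cell_id}: grid not uniform/increasing")
        if not np.all(np.isfinite(self.fr)):
            raise ValueError(f"{self.cell_id}: non-finite FRET ratios")
        if self.fate == FATE_DIED and self.death_time is not None:
            if self.times[-1] > self.death_time + 1e-9:
                raise ValueError(f"{self.cell_id}: samples past death time")


@dataclass
class TrajectorySet:
    """A generated dataset: trajectories plus ground truth and provenance."""

    cells: list[CellParams]
    trajectories: list[Trajectory]
    params: PopulationParams
    scenario: Scenario
    seed: int

    def __len__(self) -> int:
        return len(self.cells)
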