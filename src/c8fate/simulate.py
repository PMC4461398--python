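"""Synthetic single-cell FRET trajectory generator.

Emulates live-cell imaging of an initiator-caspase FRET reporter: each cell's
ratio FR(t) is flat until a lag t0, rises as ``k (t - t0)^2`` during the
activation phase, and then either (a) the cell dies at the derivative peak
``tau`` and the trajectory is truncated there, or (b) the cell survives and
its C8 activity (the FR derivative) relaxes exponentially back toward zero so
FR plateaus.  Cell-to-cell variability is lognormal in k, in the phase
duration tau - t0, and in the private death threshold; additive Gaussian
noise models the measurement.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datatypes import (
    FATE_DIED,
    FATE_SURVIVED,
    CellParams,
    PopulationParams,
    Scenario,
    Trajectory,
    TrajectorySet,
)

__all__ = [
    "sample_cells",
    "render_trajectory",
    "generate_dataset",
    "trajectories_frame",
    "cells_frame",
    "write_dataset",
    "load_trajectories",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_cells(
    params: PopulationParams,
    scenario: Scenario,
    n: int,
    seed,
    id_prefix: str | None = None,
) -> list[CellParams]:
    """Draw per-cell ground-truth parameters for one condition.

    Fate follows the threshold rule exactly: a cell dies iff
    ``2 k (tau - t0) >= theta_cell``, in which case death occurs at ``tau``.
    Survivors whose activation phase would outlast the analysis horizon are
    censored at the horizon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scenario.dose_key not in params.gm_k_by_dose:
        raise KeyError(f"unknown dose_key {scenario.dose_key!r}")
    rng = _rng(seed)
    prefix = id_prefix if id_prefix is not None else scenario.label

    gm_k = params.gm_k_by_dose[scenario.dose_key] * scenario.k_multiplier
    k = gm_k * 10.0 ** (params.sigma_k * rng.standard_normal(n))
    gm_dur = params.gm_tau_minus_t0 * scenario.tau_multiplier
    duration = gm_dur * 10.0 ** (params.sigma_tau * rng.standard_normal(n))
    if params.t0_sd > 0:
        lo = (0.0 - params.t0_mean) / params.t0_sd
        t0 = truncnorm.rvs(lo, np.inf, loc=params.t0_mean, scale=params.t0_sd,
                           size=n, random_state=rng)
    else:
        t0 = np.full(n, max(params.t0_mean, 0.0))
    theta_cell = params.theta_pop * scenario.theta_multiplier * 10.0 ** (
        params.sigma_theta * rng.standard_normal(n)
    )

    max_c8 = 2.0 * k * duration
    died = max_c8 >= theta_cell
    tau = t0 + duration
    # censor surviving activation phases at the analysis horizon
    tau = np.where(~died & (tau > params.horizon), params.horizon, tau)

    cells = []
    for i in range(n):
        cells.append(
            CellParams(
                cell_id=f"{prefix}_{i:05d}",
                k_true=float(k[i]),
                t0_true=float(t0[i]),
                tau_true=float(tau[i]),
                theta_cell=float(theta_cell[i]),
                fate=FATE_DIED if died[i] else FATE_SURVIVED,
                death_time=float(tau[i]) if died[i] else None,
            )
        )
    return cells


def render_trajectory(
    cell: CellParams,
    params: PopulationParams,
    seed,
    suppress_decay: bool = False,
) -> Trajectory:
    """Render one cell's noisy FR(t) series on the imaging grid.

    FR is 0 before t0 and ``k (t - t0)^2`` on [t0, tau].  For survivors the
    derivative decays exponentially after tau (time constant ``decay_tc``) so
    ``FR = FR(tau) + 2 k (tau - t0) tc (1 - exp(-(t - tau)/tc))``; with
    ``suppress_decay`` (proteasome inhibition) the derivative instead stays at
    its peak and FR continues linearly.  Dying trajectories end at the last
    grid point at or before the death time.
    """
    rng = _rng(seed)
    dt = params.frame_interval
    n_frames = int(np.floor(params.record_length / dt + 1e-9)) + 1
    times = np.arange(n_frames) * dt
    if cell.fate == FATE_DIED:
        times = times[times <= cell.death_time + 1e-9]

    k, t0, tau = cell.k_true, cell.t0_true, cell.tau_true
    u = np.clip(np.minimum(times, tau) - t0, 0.0, None)
    fr = k * u**2
    after = times > tau
    if np.any(after):
        peak_rate = 2.0 * k * max(tau - t0, 0.0)
        dt_after = times[after] - tau
        if suppress_decay:
            fr[after] += peak_rate * dt_after
        else:
            tc = params.decay_tc
            fr[after] += peak_rate * tc * (1.0 - np.exp(-dt_after / tc))
    if params.noise_sd > 0:
        fr = fr + rng.normal(0.0, params.noise_sd, size=fr.shape)

    return Trajectory(
        cell_id=cell.cell_id,
        times=times,
        fr=fr,
        fate=cell.fate,
        death_time=cell.death_time,
    )


def generate_dataset(
    params: PopulationParams,
    scenario: Scenario,
    n: int,
    seed: int,
) -> TrajectorySet:
    """Sample a condition's cells and render all trajectories (reproducible)."""
    rng = np.random.default_rng(seed)
    cells = sample_cells(params, scenario, n, rng)
    trajectories = [
        render_trajectory(c, params, rng, suppress_decay=scenario.suppress_decay)
        for c in cells
    ]
    return TrajectorySet(cells=cells, trajectories=trajectories,
                         params=params, scenario=scenario, seed=seed)


# ---------------------------------------------------------------------------
# tabular IO (long-format trajectories.csv + per-cell cells.csv)
# ---------------------------------------------------------------------------

def trajectories_frame(dataset: TrajectorySet) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {"cell_id": t.cell_id, "time_min": t.times, "fret_ratio": t.fr}
        )
        for t in dataset.trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def cells_frame(dataset: TrajectorySet) -> pd.DataFrame:
    rows = []
    for c in dataset.cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "condition": dataset.scenario.label,
                "fate": c.fate,
                "death_time_min": c.death_time,
                "k_true": c.k_true,
                "t0_true": c.t0_true,
                "tau_true": c.tau_true,
                "theta_cell": c.theta_cell,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(dataset: TrajectorySet, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectories": outdir / "trajectories.csv",
        "cells": outdir / "cells.csv",
    }
    trajectories_frame(dataset).to_csv(paths["trajectories"], index=False)
    cells_frame(dataset).to_csv(paths["cells"], index=False)
    return paths


def load_trajectories(
    trajectories_csv: str | Path, cells_csv: str | Path | None = None
) -> list[Trajectory]:
    """Read the long-format trajectory table (and optional fate table) back."""
    long = pd.read_csv(trajectories_csv)
    for col in ("cell_id", "time_min", "fret_ratio"):
        if col not in long.columns:
            raise ValueError(f"trajectories table missing column {col!r}")
    meta: dict[str, tuple[str | None, float | None]] = {}
    if cells_csv is not None:
        cells = pd.read_csv(cells_csv)
        for col in ("cell_id", "fate"):
            if col not in cells.columns:
                raise ValueError(f"cells table missing column {col!r}")
        for row in cells.itertuples(index=False):
            death = getattr(row, "death_time_min", None)
            death = None if death is None or pd.isna(death) else float(death)
            meta[str(row.cell_id)] = (str(row.fate), death)
    out = []
    for cell_id, grp in long.groupby("cell_id", sort=False):
        fate, death = meta.get(str(cell_id), (None, None))
        out.append(
            Trajectory(
                cell_id=str(cell_id),
                times=grp["time_min"].to_numpy(float),
                fr=grp["fret_ratio"].to_numpy(float),
                fate=fate,
                death_time=death,
            )
        )
    return out
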