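"""End-to-end orchestration: simulate -> preprocess -> fit -> classify -> summarize.

A :class:`RunConfig` carries every analysis constant (defaults are the
standard protocol values), resolves either a generator specification or input
CSV paths, and :func:`run_pipeline` executes the stages, writing the tabular
artifacts plus a JSON manifest (config echo, seed, per-stage cell counts).
Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import PopulationAnchors, calibrate_population
from .datatypes import FATE_DIED, FATE_SURVIVED, PopulationParams, Scenario, Trajectory
from .fitting import (
    EARLY_DEATH_CUTOFF,
    F_TEST_ALPHA,
    K_BOUNDS,
    K_FLOOR,
    R2_RETRY_CUTOFF,
    T0_LOWER,
    T0_MARGIN,
    fit_cell,
)
from .popstats import fit_logistic_survival, summarize_condition
from .preprocess import ANALYSIS_WINDOW, SMOOTH_WINDOW, preprocess_trajectory
from .simulate import cells_frame, generate_dataset, load_trajectories
from .threshold import (
    BoundaryClassifier,
    classify_by_boundary,
    estimate_theta,
    fit_linear_margin_classifier,
)

log = logging.getLogger("c8fate")

__all__ = ["RunConfig", "SchemaError", "run_pipeline", "validate_input", "fit_trajectories"]


class SchemaError(ValueError):
    """An input table violates the expected schema."""


@dataclass
class RunConfig:
    """All analysis constants plus input/output resolution.

    Defaults are the standard protocol values: 5-min frames over a 22-h
    record analysed over the first 10 h, 11-frame smoothing, fit constraints
    t0 in [-30, tau - 30] min and k in [0, 0.01], F-test alpha 0.05, r^2
    retry cutoff 0.5, floor rate 1e-7, 70-min early-death discard, and a
    >= 10 ng/ml dose filter when pooling cells to estimate theta.
    """

    # inputs: either CSV paths ...
    trajectories_csv: str | None = None
    cells_csv: str | None = None
    control_csv: str | None = None
    # ... or a generator spec
    simulate: dict | None = None  # {"doses": [...], "n": int, scenario overrides}

    analysis_window: float = ANALYSIS_WINDOW
    smoothing_window: int = SMOOTH_WINDOW
    t0_bounds: tuple[float, float] = (T0_LOWER, T0_MARGIN)  # (lower, margin below tau)
    k_bounds: tuple[float, float] = K_BOUNDS
    f_test_alpha: float = F_TEST_ALPHA
    r2_retry_cutoff: float = R2_RETRY_CUTOFF
    k_floor: float = K_FLOOR
    early_death_cutoff: float = EARLY_DEATH_CUTOFF
    theta_dose_min: float = 10.0  # ng/ml; dose filter for pooled theta
    t0_bar: float = 20.0  # min; population-mean lag for the analytic boundary
    seed: int = 0
    outdir: str = "runs/out"

    def __post_init__(self) -> None:
        if not 0.0 < self.f_test_alpha < 1.0:
            raise ValueError("f_test_alpha must be in (0, 1)")
        for name in ("analysis_window", "smoothing_window", "r2_retry_cutoff",
                     "k_floor", "early_death_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML superset also accepts JSON
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_input(trajectories: pd.DataFrame, cells: pd.DataFrame) -> list[dict]:
    """Check tabular inputs; returns a list of violations (empty when clean)."""
    violations: list[dict] = []
    for col in ("cell_id", "time_min", "fret_ratio"):
        if col not in trajectories.columns:
            violations.append({"table": "trajectories", "check": "column", "detail": col})
    for col in ("cell_id", "fate"):
        if col not in cells.columns:
            violations.append({"table": "cells", "check": "column", "detail": col})
    if violations:
        return violations

    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    for cid in dup:
        violations.append({"table": "cells", "check": "duplicate cell_id", "detail": str(cid)})
    bad_fate = cells[~cells["fate"].isin([FATE_DIED, FATE_SURVIVED])]
    for row in bad_fate.itertuples(index=False):
        violations.append({"table": "cells", "check": "fate domain",
                           "detail": f"{row.cell_id}: {row.fate!r}"})
    if "death_time_min" in cells.columns:
        for row in cells.itertuples(index=False):
            death = row.death_time_min
            has_death = death is not None and not pd.isna(death)
            if row.fate == FATE_DIED and not has_death:
                violations.append({"table": "cells", "check": "death_time missing",
                                   "detail": str(row.cell_id)})
            if row.fate == FATE_SURVIVED and has_death:
                violations.append({"table": "cells", "check": "death_time on survivor",
                                   "detail": str(row.cell_id)})

    for cell_id, grp in trajectories.groupby("cell_id", sort=False):
        t = grp["time_min"].to_numpy(float)
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                bad = t[1:][~np.isclose(steps, steps[0])]
                first = bad[0] if len(bad) else t[int(np.argmin(steps)) + 1]
                violations.append({"table": "trajectories", "check": "non-uniform grid",
                                   "detail": f"{cell_id}: t={first:g}"})
    return violations


def fit_trajectories(
    trajectories: list[Trajectory],
    control_times: np.ndarray | None = None,
    control_fr: np.ndarray | None = None,
    analysis_window: float = ANALYSIS_WINDOW,
    smoothing_window: int = SMOOTH_WINDOW,
    conditions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Preprocess and fit every trajectory; returns the fits table."""
    rows = []
    for traj in trajectories:
        dtraj = preprocess_trajectory(
            traj, control_times, control_fr,
            window_frames=smoothing_window, analysis_window=analysis_window,
        )
        fit = fit_cell(dtraj)
        rows.append(
            {
                "cell_id": fit.cell_id,
                "condition": (conditions or {}).get(fit.cell_id, ""),
                "fate": traj.fate,
                "k": fit.k,
                "t0": fit.t0,
                "tau": fit.tau,
                "r2": fit.r2,
                "f_pvalue": fit.f_pvalue,
                "fallback": fit.fallback,
                "max_c8": fit.max_c8,
                "window_end_used": fit.window_end_used,
                "discarded": fit.discarded,
                "discard_reason": fit.discard_reason,
            }
        )
    return pd.DataFrame(rows)


def _condition_dose(label: str, doses: dict[str, float] | None) -> float | None:
    if doses and label in doses:
        return doses[label]
    # labels of the form "<name>_<dose>" (generator convention)
    tail = label.rsplit("_", 1)[-1]
    try:
        return float(tail)
    except ValueError:
        return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all artifacts.

    Returns a dict with the in-memory tables and the manifest.  Artifacts:
    ``trajectories.csv``/``cells.csv`` (when simulating), ``fits.csv``,
    ``classification.csv``, ``threshold.json``, ``summaries.csv``,
    ``dose_response.json`` (>= 4 conditions), ``manifest.json``.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        # --- stage: obtain data -------------------------------------------
        t0 = time.time()
        condition_doses: dict[str, float] = {}
        if config.simulate is not None:
            sim = dict(config.simulate)
            n = int(sim.pop("n", 300))
            doses = sim.pop("doses", [25.0])
            anchors = PopulationAnchors(**sim.pop("anchors", {}))
            params = calibrate_population(anchors, **sim.pop("population", {}))
            scen_over = sim.pop("scenario", {})
            all_traj, all_cells = [], []
            for i, dose in enumerate(doses):
                scen = Scenario(label=f"TRAIL_{dose:g}", dose_key=float(dose), **scen_over)
                ds = generate_dataset(params, scen, n, seed=config.seed + i)
                all_traj.extend(ds.trajectories)
                all_cells.append(cells_frame(ds))
                condition_doses[scen.label] = float(dose)
            cells_df = pd.concat(all_cells, ignore_index=True)
            traj_long = pd.concat(
                [pd.DataFrame({"cell_id": t.cell_id, "time_min": t.times,
                               "fret_ratio": t.fr}) for t in all_traj],
                ignore_index=True,
            )
            traj_long.to_csv(outdir / "trajectories.csv", index=False)
            cells_df.to_csv(outdir / "cells.csv", index=False)
            trajectories = all_traj
        else:
            if config.trajectories_csv is None or config.cells_csv is None:
                raise SchemaError("either a simulate block or CSV paths required")
            traj_long = pd.read_csv(config.trajectories_csv)
            cells_df = pd.read_csv(config.cells_csv)
            violations = validate_input(traj_long, cells_df)
            fatal = [v for v in violations if v["check"] == "column"]
            if fatal:
                raise SchemaError(
                    "missing column(s): "
                    + ", ".join(f"{v['table']}.{v['detail']}" for v in fatal)
                )
            trajectories = load_trajectories(config.trajectories_csv, config.cells_csv)
        cond_by_cell = {}
        if "condition" in cells_df.columns:
            cond_by_cell = dict(zip(cells_df["cell_id"].astype(str), cells_df["condition"]))
        stages["data"] = {"n_cells": len(trajectories), "seconds": round(time.time() - t0, 3)}
        log.info("data: %d cells", len(trajectories))

        # --- stage: preprocess + fit --------------------------------------
        t0 = time.time()
        control_times = control_fr = None
        if config.control_csv:
            ctrl = pd.read_csv(config.control_csv)
            control_times = ctrl["time_min"].to_numpy(float)
            control_fr = ctrl["fret_ratio"].to_numpy(float)
        fits = fit_trajectories(
            trajectories, control_times, control_fr,
            analysis_window=config.analysis_window,
            smoothing_window=config.smoothing_window,
            conditions=cond_by_cell,
        )
        fits.to_csv(outdir / "fits.csv", index=False)
        n_ok = int((~fits["discarded"]).sum())
        stages["fit"] = {
            "n_cells": len(fits), "n_fitted": n_ok,
            "n_discarded": int(fits["discarded"].sum()),
            "seconds": round(time.time() - t0, 3),
        }
        log.info("fit: %d fitted, %d discarded", n_ok, int(fits["discarded"].sum()))

        # --- stage: threshold + classification ----------------------------
        t0 = time.time()
        ok = fits[~fits["discarded"]].copy()
        pool = ok
        dose_filter_applied = False
        doses_known = {
            c: _condition_dose(c, condition_doses) for c in ok["condition"].unique()
        }
        if all(d is not None for d in doses_known.values()) and len(doses_known) > 1:
            keep = [c for c, d in doses_known.items() if d >= config.theta_dose_min]
            if keep:
                pool = ok[ok["condition"].isin(keep)]
                dose_filter_applied = True
        theta_res = estimate_theta(pool["max_c8"], pool["fate"])
        boundary = BoundaryClassifier(theta=theta_res.theta_hat, t0_bar=config.t0_bar)
        pred_thresh = ok["max_c8"].to_numpy(float) >= theta_res.theta_hat
        pred_bound = classify_by_boundary(ok["k"], ok["tau"], boundary)
        both_fates = ok["fate"].nunique() == 2
        pred_svm = (
            fit_linear_margin_classifier(ok["k"], ok["tau"], ok["fate"])["predicted_died"]
            if both_fates
            else pred_thresh
        )
        classification = pd.DataFrame(
            {
                "cell_id": ok["cell_id"],
                "max_c8": ok["max_c8"],
                "fate": ok["fate"],
                "predicted_threshold": np.where(pred_thresh, FATE_DIED, FATE_SURVIVED),
                "predicted_boundary": np.where(pred_bound, FATE_DIED, FATE_SURVIVED),
                "predicted_svm": np.where(pred_svm, FATE_DIED, FATE_SURVIVED),
            }
        )
        classification.to_csv(outdir / "classification.csv", index=False)
        with open(outdir / "threshold.json", "w") as fh:
            json.dump(
                {
                    "theta_hat": theta_res.theta_hat,
                    "accuracy": theta_res.accuracy,
                    "error_count": theta_res.error_count,
                    "n_cells": theta_res.n_cells,
                    "n_candidates": len(theta_res.candidate_grid),
                    "dose_filter_applied": dose_filter_applied,
                    "theta_dose_min": config.theta_dose_min,
                },
                fh,
                indent=2,
            )
        stages["classify"] = {"n_cells": len(ok), "seconds": round(time.time() - t0, 3)}
        log.info("threshold: %.4g (accuracy %.3f)", theta_res.theta_hat, theta_res.accuracy)

        # --- stage: summaries ---------------------------------------------
        t0 = time.time()
        summaries = [
            summarize_condition(ok, c) for c in sorted(ok["condition"].unique())
        ]
        summaries_df = pd.DataFrame([asdict(s) for s in summaries])
        summaries_df.to_csv(outdir / "summaries.csv", index=False)
        logistic = None
        if len(summaries) >= 4:
            lf = fit_logistic_survival(
                summaries_df["mean_log10_k"].to_numpy(),
                summaries_df["surviving_fraction"].to_numpy(),
            )
            logistic = asdict(lf)
            with open(outdir / "dose_response.json", "w") as fh:
                json.dump(logistic, fh, indent=2)
        stages["summarize"] = {
            "n_conditions": len(summaries), "seconds": round(time.time() - t0, 3),
        }

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": stages,
            "counts_reconciled": stages["fit"]["n_fitted"] + stages["fit"]["n_discarded"]
            == stages["data"]["n_cells"],
            "total_seconds": round(time.time() - t_start, 3),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return {
            "fits": fits,
            "classification": classification,
            "threshold": theta_res,
            "summaries": summaries_df,
            "logistic": logistic,
            "manifest": manifest,
        }
    except Exception as exc:
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": stages,
            "failed": f"{type(exc).__name__}: {exc}",
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    finally:
        log.removeHandler(handler)
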