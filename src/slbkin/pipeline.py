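"""End-to-end orchestration: simulate -> survival/classify/associate -> solve -> routes.

One YAML configuration drives the full reproduction workflow for the two
measurement conditions ("free" receptor and SRP-bound "complex"), with a
single global seed fanned out deterministically to every stochastic stage.
Each stage writes its intermediates into its own subdirectory, and a
summary JSON at the output root collects the fitted rates, mode
populations, two-mode solution, fold changes and route comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import route_kinetics, survival_stats, synthetic_trajectories, two_mode_solver
from .synthetic_trajectories import GroundTruthKinetics, ImagingConfig

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("slbkin.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Settings for the full workflow; both conditions are required."""

    seed: int
    free_kinetics: GroundTruthKinetics
    complex_kinetics: GroundTruthKinetics
    imaging: dict[str, Any] = field(default_factory=dict)
    complex_imaging: dict[str, Any] = field(default_factory=dict)
    n_movies: int = 10
    cutoff: float = 0.25
    restarts: int = 16
    j_max: int | None = None
    route_rates: route_kinetics.RouteRates = field(default_factory=route_kinetics.RouteRates)
    route_t_max: float = 20.0
    write_trajectories: bool = True


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("pipeline config must set a global seed")
    for cond in ("free", "complex"):
        if cond not in raw or "kinetics" not in raw[cond]:
            raise PipelineStageError(
                "config", f"missing required condition '{cond}' (with its kinetics)"
            )
    analysis = raw.get("analysis", {})
    routes = raw.get("routes", {})
    return PipelineConfig(
        seed=int(raw["seed"]),
        free_kinetics=GroundTruthKinetics(**raw["free"]["kinetics"]),
        complex_kinetics=GroundTruthKinetics(**raw["complex"]["kinetics"]),
        imaging=dict(raw.get("imaging", {})),
        complex_imaging=dict(raw["complex"].get("imaging", {})),
        n_movies=int(raw.get("n_movies", 10)),
        cutoff=float(analysis.get("cutoff", 0.25)),
        restarts=int(analysis.get("restarts", 16)),
        j_max=analysis.get("j_max"),
        route_rates=route_kinetics.RouteRates(**routes.get("rates", {})),
        route_t_max=float(routes.get("t_max", 20.0)),
        write_trajectories=bool(raw.get("write_trajectories", True)),
    )


def _condition_stages(tag, truth, imaging_kwargs, cfg, seed, out):
    stage = f"simulate:{tag}"
    try:
        im = ImagingConfig(seed=seed, **imaging_kwargs)
        movies = synthetic_trajectories.simulate_movies(truth, im, cfg.n_movies)
        n_events = sum(len(mv) for mv in movies)
        log.info("%s: %d trajectories over %d movies (seed %d)", stage, n_events, cfg.n_movies, seed)
        if cfg.write_trajectories:
            traj_dir = out / "trajectories"
            traj_dir.mkdir(parents=True, exist_ok=True)
            import pandas as pd

            pd.concat(
                [mv.to_dataframe().assign(movie_id=i) for i, mv in enumerate(movies)],
                ignore_index=True,
            ).to_csv(traj_dir / f"{tag}.csv", index=False)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = f"survival:{tag}"
    try:
        curve = survival_stats.compute_survival(movies, j_max=cfg.j_max)
        fit = survival_stats.fit_biexponential(curve, restarts=cfg.restarts)
        pops = survival_stats.classify_modes(movies, cutoff=cfg.cutoff, biexp=fit)
        assoc = survival_stats.estimate_association(movies, conc=truth.conc, cutoff=cfg.cutoff)
        surv_dir = out / "survival"
        surv_dir.mkdir(parents=True, exist_ok=True)
        curve.to_csv(surv_dir / f"{tag}_curve.csv")
        fit.to_json(surv_dir / f"{tag}_biexp.json")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    return {
        "n_events": n_events,
        "curve": curve,
        "fit": fit,
        "populations": pops,
        "association": assoc,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and return (and write) the summary bundle.

    Identical seeds produce identical numeric outputs.  Any stage failure
    raises :class:`PipelineStageError` naming the stage; outputs written by
    earlier stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(2) >> 1]

    free = _condition_stages(
        "free", config.free_kinetics, config.imaging, config, seeds[0], out
    )
    complex_imaging = {**config.imaging, **config.complex_imaging}
    comp = _condition_stages(
        "complex", config.complex_kinetics, complex_imaging, config, seeds[1], out
    )

    stage = "solve"
    try:
        sol = two_mode_solver.solve_two_mode(
            free["association"], comp["association"],
            k_off1=free["fit"].fast_rate, k_off2=comp["fit"].slow_rate,
        )
        sol = two_mode_solver.compute_equilibria(sol, free["populations"], comp["populations"])
        folds = two_mode_solver.summarize_fold_changes(sol)
        sol.to_json(out / "two_mode_solution.json")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "routes"
    try:
        grid = route_kinetics.default_time_grid(config.route_t_max)
        comparison = route_kinetics.compare_routes(config.route_rates, grid)
        routes_dir = out / "routes"
        routes_dir.mkdir(parents=True, exist_ok=True)
        for rid, trace in comparison.traces.items():
            trace.to_csv(routes_dir / f"{rid}.csv")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    summary = {
        "seed": config.seed,
        "stage_seeds": {"free": seeds[0], "complex": seeds[1]},
        "free": _condition_summary(free),
        "complex": _condition_summary(comp),
        "two_mode": {
            k: v
            for k, v in dataclasses.asdict(sol).items()
        },
        "fold_changes": dataclasses.asdict(folds),
        "routes": {
            "targeted_at_5s": comparison.targeted_at_5s,
            "completion_times": {
                rid: {str(k): v for k, v in d.items()}
                for rid, d in comparison.completion_times.items()
            },
            "completion_time_ratios": {
                str(k): v for k, v in comparison.completion_time_ratios.items()
            },
            "dynamic_dominates": comparison.dynamic_dominates,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _condition_summary(bundle) -> dict:
    fit = bundle["fit"]
    pops = bundle["populations"]
    assoc = bundle["association"]
    return {
        "n_events": bundle["n_events"],
        "k_off1": fit.fast_rate,
        "k_off2": fit.slow_rate,
        "effectively_single": fit.effectively_single,
        "amplitude_P1": fit.P1,
        "amplitude_P2": fit.P2,
        "k_off2_near_window_limit": fit.k_off2_near_window_limit,
        "classified_P1": pops.P1,
        "classified_P2": pops.P2,
        "k1_app": assoc.k1_app,
        "k2_app": assoc.k2_app,
    }
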