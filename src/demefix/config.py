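"""Declarative experiment configs, sweeps and method comparison.

A config names a graph constructor (or a matrix file), the cycle
parameters, an initial condition, a method, and optional sweep axes
(lists over ``st``, ``mO``, ``alpha``, ``eta``, ``eta0``, ``m``, ``K``).
``run_config`` executes the Cartesian product of the sweep axes and
returns one self-describing record per point; given a seed the whole
sweep is deterministic.  ``compare_methods`` runs both the stochastic
simulator and the branching-process solver on each point and reports
z-scores ``(simulated - predicted) / SE``, attaching validity flags where
the branching-process regime does not apply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .branching import build_offspring_model, extinction_time, first_order_fixation, solve_extinction
from .graphs import DirichletCliqueSpec, MigrationGraph, StarSpec, make_clique, make_dirichlet_clique, make_star
from .io import load_graph, result_record
from .rare import coarse_chain_fixation, rare_regime_check, star_rare_fixation
from .simulation import ModelParams, estimate_fixation

__all__ = ["ExperimentConfig", "run_config", "compare_methods"]

_METHODS = ("simulate", "bp", "bp_first_order", "rare")
_SWEEP_AXES = ("st", "s", "mO", "alpha", "eta", "eta0", "m", "K")


@dataclass
class ExperimentConfig:
    graph: dict[str, Any]
    K: int = 1000
    t: float = 5.0
    s: float | None = None
    st: float | None = None
    variant: str = "independent_binomial"
    init: str = "uniform"
    method: str = "simulate"
    sweep: dict[str, list] = field(default_factory=dict)
    n_reps: int = 10_000
    seed: int = 0
    max_cycles: int = 1_000_000
    times: bool = False

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.s is None and self.st is None:
            raise ValueError("one of s or st must be given")
        for axis in self.sweep:
            if axis not in _SWEEP_AXES:
                raise ValueError(f"unknown sweep axis {axis!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _build_graph(spec: dict, overrides: dict, seed) -> MigrationGraph:
    kind = spec.get("kind", "file")
    get = lambda key, default=None: overrides.get(key, spec.get(key, default))
    if kind == "clique":
        return make_clique(int(get("D")), float(get("m")))
    if kind == "star":
        return make_star(StarSpec(D=int(get("D")), mO=float(get("mO")),
                                  alpha=float(get("alpha", 1.0))))
    if kind == "dirichlet":
        eta0 = get("eta0")
        eta = (float(eta0), 1.0) if eta0 is not None else float(get("eta", 1.0))
        return make_dirichlet_clique(
            DirichletCliqueSpec(D=int(get("D")), eta=eta, seed=seed)
        )
    if kind == "file":
        return load_graph(spec["path"])
    raise ValueError(f"unknown graph kind {kind!r}")


def _point_params(cfg: ExperimentConfig, overrides: dict) -> ModelParams:
    t = cfg.t
    st = overrides.get("st", cfg.st)
    s = overrides.get("s", cfg.s)
    if st is not None:
        s = st / t
    K = int(overrides.get("K", cfg.K))
    return ModelParams(K=K, s=float(s), t=t, variant=cfg.variant)


def _run_point(cfg: ExperimentConfig, overrides: dict, point_seed: int) -> dict:
    params = _point_params(cfg, overrides)
    g = _build_graph(cfg.graph, overrides, seed=point_seed)
    echo = {"graph": cfg.graph.get("kind", "file"), "K": params.K, "s": params.s,
            "t": params.t, "st": params.st, "variant": cfg.variant,
            "init": cfg.init, **{k: v for k, v in overrides.items()}}
    warnings: list[str] = []
    if cfg.method == "simulate":
        est = estimate_fixation(g, params, cfg.init, n_reps=cfg.n_reps,
                                seed=point_seed, max_cycles=cfg.max_cycles)
        out = {"p_fix": est.p_fix, "se": est.se, "mean_time_fix": est.mean_time_fix,
               "mean_time_ext": est.mean_time_ext, "n_reps": est.n_reps,
               "n_censored": est.n_censored}
    elif cfg.method == "bp":
        res = solve_extinction(build_offspring_model(g, params))
        warnings = list(res.validity_flags)
        out = {"rho_avg": res.rho_avg, "rho": res.rho, "p": res.p}
        if cfg.times:
            et = extinction_time(build_offspring_model(g, params))
            out.update({"tau": et.tau, "tau_avg": et.tau_avg,
                        "tau_avg_weighted": et.tau_avg_weighted})
    elif cfg.method == "bp_first_order":
        rho = first_order_fixation(g, params.st)
        out = {"rho": rho, "rho_avg": float(rho.mean())}
    else:  # rare
        check = rare_regime_check(g, params)
        if not check.in_regime:
            warnings.append(f"rare-migration ratio {check.ratio:.3g} above threshold")
        if cfg.graph.get("kind") == "star":
            D = int(cfg.graph["D"])
            alpha = float(overrides.get("alpha", cfg.graph.get("alpha", 1.0)))
            p_total = star_rare_fixation(D, params.K, params.st, alpha, "uniform")
        else:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                p_total = float(np.mean([
                    coarse_chain_fixation(g, params, d) for d in range(g.D)
                ]))
        out = {"p_fix_rare": p_total, "regime_ratio": check.ratio,
               "in_regime": check.in_regime}
    return result_record(cfg.method, echo, out, warnings, seed=point_seed)


def _sweep_points(cfg: ExperimentConfig):
    axes = [(k, list(v)) for k, v in cfg.sweep.items()]
    if not axes:
        yield {}
        return
    names = [k for k, _ in axes]
    for combo in itertools.product(*[v for _, v in axes]):
        yield dict(zip(names, combo))


def run_config(cfg: ExperimentConfig) -> list[dict]:
    """Execute the config over the Cartesian product of its sweep axes.

    Each point gets a deterministic seed derived from ``(cfg.seed, index)``;
    constructor or solver errors are collected per point and the run
    continues.
    """
    records = []
    for i, overrides in enumerate(_sweep_points(cfg)):
        point_seed = int(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        try:
            records.append(_run_point(cfg, overrides, point_seed))
        except Exception as exc:  # noqa: BLE001 - collected per point by design
            records.append(result_record(cfg.method,
                                         {"overrides": overrides},
                                         {}, [f"error: {exc}"], seed=point_seed))
    return records


def compare_methods(cfg: ExperimentConfig) -> dict:
    """Simulation vs branching-process prediction per sweep point.

    Returns per-point z-scores and a summary counting points with
    ``|z| > 3`` among those inside the branching-process validity regime.
    """
    if cfg.method != "simulate":
        raise ValueError("compare_methods needs a config with method='simulate' "
                         "(the BP prediction is added automatically)")
    points = []
    for i, overrides in enumerate(_sweep_points(cfg)):
        point_seed = int(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        params = _point_params(cfg, overrides)
        g = _build_graph(cfg.graph, overrides, seed=point_seed)
        est = estimate_fixation(g, params, cfg.init, n_reps=cfg.n_reps,
                                seed=point_seed, max_cycles=cfg.max_cycles)
        bp = solve_extinction(build_offspring_model(g, params))
        z = (est.p_fix - bp.rho_avg) / est.se if est.se > 0 else float("inf")
        points.append({"overrides": overrides, "p_fix": est.p_fix, "se": est.se,
                       "rho_avg": bp.rho_avg, "z": z,
                       "flags": list(bp.validity_flags)})
    in_regime = [p for p in points if not p["flags"]]
    return {
        "points": points,
        "n_points": len(points),
        "n_in_regime": len(in_regime),
        "n_discrepant": sum(abs(p["z"]) > 3 for p in in_regime),
    }
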