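"""Monte-Carlo study harness: run estimators over replicated simulations.

Each replication simulates one dataset and fits every requested method on
that same dataset.  Summaries per method × parameter: relative bias
reBias = (mean estimate − truth)/truth, the SD of the estimates, the Monte
Carlo standard error of the relative bias MCSE = SD/(truth √R), the MSE,
and the coverage of Wald 95% intervals (on the natural scale for α, on the
log scale for θ, λ, ρ).  Non-convergent replications are excluded from the
moments and reported as failure counts; replications that converge but lack
standard errors contribute to the moments and are excluded from coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import (
    build_calibrated_startstop,
    build_locf_startstop,
    build_rrc_schedule,
    make_dense_grid,
)
from .dataset import TwinDataset
from .frailty import fit_frailty
from .jm import fit_jm, stage1_from_lmm
from .lmm import fit_lmm
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["ScenarioSpec", "MCResult", "run_scenario", "summarize", "rep_seed"]

_KNOWN_METHODS = ("naive", "locf", "orc", "rrc", "jm")

# estimate/se dict keyed by parameter name, or None on fit failure
MethodResult = dict[str, tuple[float, float | None]] | None


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: generating config, methods, replication plan."""

    sim: SimulationConfig
    methods: tuple[str, ...] = ("naive", "locf")
    n_reps: int = 200
    base_seed: int = 0
    grid_points: int = 100
    compute_se: bool = True
    jm_nodes: int = 20
    rrc_min_pairs: int = 10
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        unknown = [m for m in self.methods if m not in _KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {_KNOWN_METHODS}")


@dataclass
class MCResult:
    """Per-method × parameter Monte-Carlo summary plus design bookkeeping."""

    table: pd.DataFrame  # method, param, truth, reBias, SD, MCSE, MSE, CP, n_used, n_se
    inc_g: float
    events: float
    n_reps: int
    failures: dict[str, int] = field(default_factory=dict)
    se_failures: dict[str, int] = field(default_factory=dict)


def rep_seed(base_seed: int, rep: int) -> int:
    """Deterministic per-replication seed below 2^31."""
    return int((base_seed + 1_000_003 * (rep + 1)) % (2**31 - 1))


def _truth_map(sim: SimulationConfig) -> dict[str, float]:
    return {
        "alpha": sim.alpha,
        "theta": sim.theta,
        "lambda": sim.weibull_scale,
        "rho": sim.weibull_shape,
        "sigma_u2": sim.sigma_u**2,
        "sigma_e2": sim.sigma_e**2,
    }


_LOG_SCALE_CI = {"theta", "lambda", "rho", "sigma_u2", "sigma_e2"}


def _frailty_result(fit) -> MethodResult:
    if not np.isfinite(fit.loglik):
        return None
    e = fit.estimates
    se = fit.se or {}

    def pick(name, value):
        return (value, se.get(name))

    if "ABNORMAL" in fit.message:
        # optimizer failure (as opposed to a merely missing Hessian) -> discard
        return None
    return {
        "alpha": pick("alpha", e.alpha),
        "lambda": pick("lambda", e.weibull.scale),
        "rho": pick("rho", e.weibull.shape),
        "theta": pick("theta", e.theta),
    }


def _fit_methods(
    dataset: TwinDataset,
    spec: ScenarioSpec,
    extra_methods: dict[str, Callable[[TwinDataset], MethodResult]] | None,
) -> dict[str, MethodResult]:
    out: dict[str, MethodResult] = {}
    methods = spec.methods
    locf_table = None
    if {"naive", "locf"} & set(methods):
        locf_table = build_locf_startstop(dataset)
    if "naive" in methods:
        out["naive"] = _frailty_result(
            fit_frailty(locf_table, truncation_adjust=False, compute_se=spec.compute_se)
        )
    if "locf" in methods:
        out["locf"] = _frailty_result(
            fit_frailty(locf_table, truncation_adjust=True, compute_se=spec.compute_se)
        )
    needs_stage1 = {"orc", "rrc", "jm"} & set(methods)
    lmm_fit = None
    grid = None
    if needs_stage1:
        try:
            lmm_fit = fit_lmm(dataset, slope=False)
            grid = make_dense_grid(dataset, n_points=spec.grid_points)
        except ValueError:
            for m in needs_stage1:
                out[m] = None
            return out
    if "orc" in methods:
        try:
            table = build_calibrated_startstop(dataset, lmm_fit, grid, method="orc")
            out["orc"] = _frailty_result(
                fit_frailty(table, truncation_adjust=True, compute_se=spec.compute_se)
            )
        except ValueError:
            out["orc"] = None
    if "rrc" in methods:
        try:
            schedule = build_rrc_schedule(dataset, min_pairs=spec.rrc_min_pairs)
            table = build_calibrated_startstop(dataset, schedule, grid, method="rrc")
            out["rrc"] = _frailty_result(
                fit_frailty(table, truncation_adjust=True, compute_se=spec.compute_se)
            )
        except ValueError:
            out["rrc"] = None
    if "jm" in methods:
        try:
            jm_fit = fit_jm(
                dataset,
                stage1_from_lmm(lmm_fit),
                n_nodes=spec.jm_nodes,
                compute_se=spec.compute_se,
            )
        except ValueError:
            out["jm"] = None
        else:
            if not np.isfinite(jm_fit.loglik):
                out["jm"] = None
            else:
                e = jm_fit.estimates
                se = jm_fit.se or {}
                out["jm"] = {
                    "alpha": (e.alpha, se.get("alpha")),
                    "lambda": (e.weibull.scale, se.get("lambda")),
                    "rho": (e.weibull.shape, se.get("rho")),
                    "theta": (e.theta, se.get("theta")),
                    "sigma_u2": (e.sigma_u2, se.get("sigma_u2")),
                    "sigma_e2": (e.sigma_e2, se.get("sigma_e2")),
                }
    for name, fn in (extra_methods or {}).items():
        out[name] = fn(dataset)
    return out


def run_scenario(
    spec: ScenarioSpec,
    extra_methods: dict[str, Callable[[TwinDataset], MethodResult]] | None = None,
    progress: Callable[[int], None] | None = None,
) -> MCResult:
    """Replicate the scenario and aggregate estimator performance.

    Replications are indexed deterministically (``rep_seed``), so the result
    is invariant to execution order and to adding further methods.
    ``extra_methods`` allows plugging custom estimators (dataset → results),
    e.g. oracle baselines in tests.
    """
    truth = _truth_map(spec.sim)
    store: dict[str, dict[str, list[tuple[float, float | None]]]] = {}
    failures: dict[str, int] = {}
    inc_g: list[int] = []
    events: list[int] = []
    for r in range(spec.n_reps):
        ds = simulate_dataset(spec.sim.with_(seed=rep_seed(spec.base_seed, r)))
        inc_g.append(ds.n_pairs)
        events.append(ds.n_events)
        results = _fit_methods(ds, spec, extra_methods)
        for method, res in results.items():
            if res is None:
                failures[method] = failures.get(method, 0) + 1
                continue
            m_store = store.setdefault(method, {})
            for param, pair in res.items():
                m_store.setdefault(param, []).append(pair)
        if progress is not None:
            progress(r)

    rows = []
    se_failures: dict[str, int] = {}
    for method, params in store.items():
        for param, vals in params.items():
            if param not in truth or truth[param] == 0:
                continue
            est = np.array([v[0] for v in vals], dtype=float)
            ses = np.array([np.nan if v[1] is None else v[1] for v in vals], dtype=float)
            R = est.size
            tv = truth[param]
            sd = est.std(ddof=1) if R > 1 else np.nan
            with_se = np.isfinite(ses) & (ses > 0)
            se_failures.setdefault(method, 0)
            se_failures[method] = max(se_failures[method], int(R - with_se.sum()))
            if with_se.any():
                e, s = est[with_se], ses[with_se]
                if param in _LOG_SCALE_CI:
                    # Wald interval on the log scale (delta method)
                    ok = e > 0
                    log_se = np.where(ok, s / np.maximum(e, 1e-300), np.inf)
                    lo = np.log(np.maximum(e, 1e-300)) - 1.96 * log_se
                    hi = np.log(np.maximum(e, 1e-300)) + 1.96 * log_se
                    cp = float(np.mean((lo <= np.log(tv)) & (np.log(tv) <= hi)))
                else:
                    cp = float(np.mean((e - 1.96 * s <= tv) & (tv <= e + 1.96 * s)))
            else:
                cp = np.nan
            rows.append(
                {
                    "method": method,
                    "param": param,
                    "truth": tv,
                    "reBias": float((est.mean() - tv) / tv),
                    "SD": float(sd),
                    "MCSE": float(sd / (abs(tv) * np.sqrt(R))) if R > 1 else np.nan,
                    "MSE": float(np.mean((est - tv) ** 2)),
                    "CP": cp,
                    "n_used": R,
                    "n_se": int(with_se.sum()),
                }
            )
    table = pd.DataFrame(rows)
    return MCResult(
        table=table,
        inc_g=float(np.mean(inc_g)),
        events=float(np.mean(events)),
        n_reps=spec.n_reps,
        failures=failures,
        se_failures=se_failures,
    )


_LAYOUTS = {
    "table1": ("naive", "locf"),
    "table2": ("locf", "rrc", "orc"),
    "table3": ("locf", "rrc", "orc", "jm"),
    "table4": ("locf", "rrc", "orc", "jm"),
}


def summarize(result: MCResult, layout: str = "table3", params: tuple[str, ...] = ("alpha", "theta")) -> pd.DataFrame:
    """Wide summary table: one row per parameter, reBias/SD columns per method."""
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(_LAYOUTS)}")
    methods = _LAYOUTS[layout]
    rows = []
    t = result.table
    for param in params:
        row: dict[str, object] = {
            "Par.": param,
            "Inc.G": round(result.inc_g),
            "Events": round(result.events),
        }
        for m in methods:
            sub = t[(t["method"] == m) & (t["param"] == param)]
            if len(sub):
                r = sub.iloc[0]
                row[f"{m}_reBias (MCSE)"] = f"{r['reBias']:.3f} ({r['MCSE']:.3f})"
                row[f"{m}_SD"] = f"{r['SD']:.3f}"
            else:
                row[f"{m}_reBias (MCSE)"] = ""
                row[f"{m}_SD"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
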