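"""CSV readers/writers and config parsing.

Dataset dialect: ``survival.csv`` (pair_id,twin_id,entry_age,exit_age,event)
and ``longitudinal.csv`` (pair_id,twin_id,time,y); comma-separated, dot
decimal, header row mandatory.  Start-stop tables use
``pair_id,twin_id,start,stop,status,z[,x...]`` via
:meth:`twinjoint.frailty.StartStopTable.from_csv`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .dataset import TwinDataset
from .mc import ScenarioSpec
from .simulate import SimulationConfig

__all__ = [
    "write_dataset",
    "read_dataset",
    "load_scenario",
    "scenario_from_dict",
    "write_manifest",
]

SURVIVAL_COLS = ["pair_id", "twin_id", "entry_age", "exit_age", "event"]
LONGITUDINAL_COLS = ["pair_id", "twin_id", "time", "y"]


def write_dataset(dataset: TwinDataset, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    surv_path = out / "survival.csv"
    long_path = out / "longitudinal.csv"
    dataset.survival_frame().to_csv(surv_path, index=False)
    dataset.longitudinal_frame().to_csv(long_path, index=False)
    return surv_path, long_path


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")


def read_dataset(path: str | Path, complete_pairs_only: bool = True) -> TwinDataset:
    """Read and validate a dataset directory (survival.csv + longitudinal.csv).

    Violations are reported with 1-based data row numbers.  Pairs with a
    missing member are dropped with a warning (the likelihoods condition on
    both twins being under observation).
    """
    d = Path(path)
    surv = pd.read_csv(d / "survival.csv")
    long = pd.read_csv(d / "longitudinal.csv")
    _check_columns(surv, SURVIVAL_COLS, "survival.csv")
    _check_columns(long, LONGITUDINAL_COLS, "longitudinal.csv")
    bad = surv["exit_age"].to_numpy() <= surv["entry_age"].to_numpy()
    if bad.any():
        row = int(bad.argmax()) + 1
        raise ValueError(f"survival.csv row {row}: exit_age must exceed entry_age")
    bad_tw = ~surv["twin_id"].isin([1, 2]).to_numpy()
    if bad_tw.any():
        row = int(bad_tw.argmax()) + 1
        raise ValueError(f"survival.csv row {row}: twin_id must be 1 or 2")
    for (pid, tid), g in long.groupby(["pair_id", "twin_id"]):
        t = g["time"].to_numpy()
        if (t[1:] <= t[:-1]).any():
            k = int((t[1:] <= t[:-1]).argmax())
            row = int(g.index[k + 1]) + 1
            raise ValueError(
                f"longitudinal.csv row {row}: times for subject ({pid}, {tid}) "
                "must be strictly increasing"
            )
    if complete_pairs_only:
        counts = surv.groupby("pair_id")["twin_id"].nunique()
        singles = counts[counts < 2].index.tolist()
        if singles:
            warnings.warn(
                f"dropping {len(singles)} incomplete pair(s): {singles[:10]}",
                stacklevel=2,
            )
            surv = surv[~surv["pair_id"].isin(singles)]
            long = long[~long["pair_id"].isin(singles)]
    return TwinDataset.from_frames(surv, long, complete_pairs_only=complete_pairs_only)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

_SIM_KEYS = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
_SCENARIO_KEYS = {
    "name",
    "sim",
    "methods",
    "n_reps",
    "base_seed",
    "grid_points",
    "compute_se",
    "jm_nodes",
    "rrc_min_pairs",
}


def scenario_from_dict(raw: dict) -> ScenarioSpec:
    """Validate a raw scenario mapping (strict: unknown keys are rejected)."""
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys {sorted(unknown)}")
    sim_raw = dict(raw.get("sim", {}))
    unknown_sim = set(sim_raw) - _SIM_KEYS
    if unknown_sim:
        raise ValueError(f"unknown sim keys {sorted(unknown_sim)}")
    sim = SimulationConfig(**sim_raw)
    kwargs = {k: v for k, v in raw.items() if k not in ("sim", "methods")}
    methods = tuple(raw.get("methods", ("naive", "locf")))
    return ScenarioSpec(sim=sim, methods=methods, **kwargs)


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must hold a mapping")
    return scenario_from_dict(raw)


def write_manifest(out_dir: str | Path, command: str, seed: int | None, config: dict) -> Path:
    """Record the effective configuration and seed of a run for provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump({"command": command, "seed": seed, "config": config}, fh, indent=2, default=str)
    return path
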