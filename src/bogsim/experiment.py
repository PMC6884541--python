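"""End-to-end natural vs ditch-drained scenario experiment.

`run_experiment` reproduces the standard two-scenario numerical experiment:
a 6,000-year natural raised-bog run and a drained run that shares the same
climate series and seed but has ten 0.5 m deep ditches cut 200 years before
the end.  Both scenarios are advanced together up to the ditch-opening year
and then branched, which is exactly equivalent to two independent runs
because the model is deterministic given the climate series.

All outputs are plain CSV plus a small JSON metadata file and a log; every
number in the comparison report can be recomputed from the CSVs it cites.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, climate as climate_mod
from .params import (ConfigError, DitchPlan, default_config, load_config,
                     merge_config, _ditch_from_config, _params_from_config)
from .simulate import Simulator

__all__ = ["run_experiment", "compare_scenarios", "ComparisonError",
           "ScenarioSpec"]

SCENARIOS = ("natural", "drained")


class ComparisonError(ValueError):
    """Raised when two scenario directories cannot be compared."""


class ScenarioSpec:
    """Label plus the shared climate/seed and the (optional) ditch plan."""

    def __init__(self, label: str, ditch_plan: DitchPlan | None):
        if label not in SCENARIOS:
            raise ConfigError(f"unknown scenario label {label!r}")
        if label == "natural" and ditch_plan is not None:
            raise ConfigError("the natural scenario has no ditch plan")
        self.label = label
        self.ditch_plan = ditch_plan


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analysis_column(cfg: dict) -> int:
    spec = cfg["run"]["analysis_column"]
    n = cfg["run"]["n_columns"]
    if spec == "midpoint":
        return n // 2
    idx = int(spec)
    if not 0 <= idx < n:
        raise ConfigError(f"analysis_column {idx} outside 0..{n - 1}")
    return idx


def _write_scenario(out: Path, label: str, sim: Simulator, cfg: dict,
                    climate_sha: str, runtime_s: float) -> dict:
    """Write one scenario's result files; returns the summary numbers."""
    result = sim.result()
    col_idx = _analysis_column(cfg)
    n_years = result.n_years
    sdir = out / label
    sdir.mkdir(parents=True, exist_ok=True)

    yearly = pd.DataFrame({
        "year": result.years,
        "transect_total_mass": result.total_mass.sum(axis=1),
        "transect_litter": result.litter_added.sum(axis=1),
        "transect_oxic_loss": result.oxic_loss.sum(axis=1),
        "transect_anoxic_loss": result.anoxic_loss.sum(axis=1),
        "transect_excavated": result.excavated.sum(axis=1),
        "transect_runoff_m": result.runoff.sum(axis=1),
        "column_mass": result.total_mass[:, col_idx],
        "column_height": result.height[:, col_idx],
        "column_wtd": result.wtd_annual_mean[:, col_idx],
        "column_litter": result.litter_added[:, col_idx],
    })
    yearly.to_csv(sdir / "yearly.csv", index=False, float_format="%.10g")

    core = analysis.extract_core(result.columns[col_idx], n_years)
    analysis.core_to_frame(core).to_csv(sdir / f"core_col{col_idx}.csv",
                                        index=False, float_format="%.10g")
    cf = cfg["model"]["carbon_fraction"]
    history = analysis.apparent_rate_history(core, cf)
    analysis.history_to_frame(history).to_csv(
        sdir / f"history_col{col_idx}.csv", index=False, float_format="%.10g")

    stock, change = analysis.net_balance_series(result, col_idx, cf)
    budget_rows = {"column": col_idx}
    if change is not None:
        budget_rows |= {
            "period_start_year": result.budget.start_year,
            "period_end_year": n_years,
            "N": change.new_addition, "A_o": change.acrotelm_loss,
            "C_s": change.catotelm_loss, "net": change.net,
            "stock_start": cf * result.budget.stock_at_start[col_idx],
            "stock_end": stock[-1],
        }
    # full precision: closure identities must survive the round trip
    pd.DataFrame([budget_rows]).to_csv(sdir / "budget.csv", index=False)

    windows = [tuple(w) for w in cfg["run"]["analysis_windows"]]
    summary = {
        "label": label,
        "lorca": analysis.lorca(core, cf),
        "final_thickness_m": core.total_thickness,
        "thickness_lt200yr_m": analysis.thickness_younger_than(core, 200.0),
    }
    for lo, hi in windows:
        try:
            rate = analysis.windowed_mean_rate(history, lo, hi)
        except analysis.EmptyWindowError:
            rate = float("nan")  # window beyond the core (short smoke runs)
        summary[f"rate_{int(lo)}_{int(hi)}"] = rate
    if change is not None:
        summary |= {"N": change.new_addition, "A_o": change.acrotelm_loss,
                    "C_s": change.catotelm_loss, "net": change.net}

    residual = float(result.mass_balance_residual().max())
    meta = {
        "scenario": label, "seed": cfg["run"]["seed"],
        "climate_sha256": climate_sha,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest(),
        "analysis_column": col_idx, "n_years": n_years,
        "analysis_windows": [list(w) for w in windows],
        "max_mass_balance_residual": residual,
    }
    (sdir / "meta.json").write_text(json.dumps(meta, indent=2))
    with open(sdir / "run.log", "w") as log:
        log.write(f"timestamp: {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        log.write(f"scenario: {label}\nseed: {cfg['run']['seed']}\n")
        log.write(f"config sha256: {meta['config_sha256']}\n")
        log.write(f"climate sha256: {climate_sha}\n")
        log.write(f"max mass-balance residual (relative): {residual:.3e}\n")
        log.write(f"runtime: {runtime_s:.1f} s\n")
    return summary


def run_experiment(config, out_dir, scenarios=SCENARIOS) -> dict:
    """Run the configured scenarios and write all result files.

    ``config`` is a path to a YAML config or an already-loaded config dict
    (defaults are used for missing keys).  Returns a dict with the per-
    scenario summary numbers.  Partially written outputs are removed if the
    run fails.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = merge_config(default_config(), config or {})
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_experiment(cfg, out, tuple(scenarios))
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run_experiment(cfg: dict, out: Path, scenarios) -> dict:
    t0 = time.time()
    for s in scenarios:
        if s not in SCENARIOS:
            raise ConfigError(f"unknown scenario {s!r}")
    run_cfg = cfg["run"]
    ccfg = cfg["climate"]
    weekly = climate_mod.default_weekly_climate(
        n_years=ccfg["n_years"], seed=run_cfg["seed"],
        amplitude=ccfg["seasonal_amplitude"],
        mean_rain=ccfg["mean_rain"], rain_sd=ccfg["rain_sd"],
        rain_autocorr=ccfg["rain_autocorr"], mean_temp=ccfg["mean_temp"],
        temp_sd=ccfg["temp_sd"], temp_autocorr=ccfg["temp_autocorr"])
    climate_path = out / "climate.csv"
    climate_mod.write_weekly_csv(weekly, climate_path)
    climate_sha = _sha256(climate_path)

    params = _params_from_config(cfg)
    plan = _ditch_from_config(cfg)
    n_years = run_cfg["n_years"]
    if n_years > weekly.n_years:
        raise ConfigError("run.n_years exceeds climate.n_years")
    open_year = n_years - plan.open_years_before_end
    if "drained" in scenarios and open_year <= 0:
        raise ConfigError(
            "ditch.open_years_before_end must be shorter than the run")

    sim = Simulator(params, weekly, run_cfg["n_columns"],
                    run_cfg["column_width_m"])
    summaries = {}
    if open_year > 0:
        sim.run_years(open_year)
        sim.snapshot()
        branch = sim.copy() if "drained" in scenarios else None
        remaining = n_years - open_year
        if "natural" in scenarios:
            sim.start_budget_tracking()
            sim.run_years(remaining)
            summaries["natural"] = _write_scenario(
                out, "natural", sim, cfg, climate_sha, time.time() - t0)
        if branch is not None:
            t1 = time.time()
            branch.start_budget_tracking()
            branch.excavate_ditches(plan)
            branch.run_years(remaining)
            summaries["drained"] = _write_scenario(
                out, "drained", branch, cfg, climate_sha, time.time() - t1)
    else:
        sim.run_years(n_years)
        summaries["natural"] = _write_scenario(
            out, "natural", sim, cfg, climate_sha, time.time() - t0)

    if summaries:
        table = pd.DataFrame(list(summaries.values()))
        rate_cols = [c for c in table.columns if c.startswith("rate_")]
        table[["label"] + rate_cols].to_csv(out / "table1.csv", index=False,
                                            float_format="%.10g")
        table.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    return summaries


def compare_scenarios(natural_dir, drained_dir, out_path=None) -> pd.DataFrame:
    """Comparison report built purely from the two run directories' CSVs.

    Refuses to compare runs driven by different climate series.
    """
    rows = []
    metas = []
    for label, d in (("natural", Path(natural_dir)),
                     ("drained", Path(drained_dir))):
        meta_path = d / "meta.json"
        if not meta_path.exists():
            raise ComparisonError(f"{d} is not a completed scenario directory")
        meta = json.loads(meta_path.read_text())
        metas.append(meta)
        col = meta["analysis_column"]
        core = analysis.core_from_frame(pd.read_csv(d / f"core_col{col}.csv"))
        history_df = pd.read_csv(d / f"history_col{col}.csv")
        history = analysis.AccumulationHistory(
            age=history_df["age"].to_numpy(),
            rate=history_df["apparent_c_rate"].to_numpy(),
            delta_age=history_df["delta_age"].to_numpy())
        budget = pd.read_csv(d / "budget.csv").iloc[0]
        row = {
            "scenario": meta["scenario"],
            "lorca": analysis.lorca(core),
            "final_thickness_m": core.total_thickness,
            "thickness_lt200yr_m": analysis.thickness_younger_than(core, 200.0),
        }
        for lo, hi in meta["analysis_windows"]:
            try:
                rate = analysis.windowed_mean_rate(history, lo, hi)
            except analysis.EmptyWindowError:
                rate = float("nan")
            row[f"rate_{int(lo)}_{int(hi)}"] = rate
        for key in ("N", "A_o", "C_s", "net"):
            row[key] = float(budget[key]) if key in budget else np.nan
        rows.append(row)
    if metas[0]["climate_sha256"] != metas[1]["climate_sha256"]:
        raise ComparisonError(
            "scenario directories were driven by different climate series "
            "(climate_sha256 mismatch); comparison refused")
    report = pd.DataFrame(rows)
    if out_path is not None:
        report.to_csv(out_path, index=False, float_format="%.10g")
    return report
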