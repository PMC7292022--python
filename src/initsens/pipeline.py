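"""End-to-end orchestration: fixture -> ensembles -> indicators -> attributes
-> CVs -> GLMs, with reproducible seeds and file outputs.

Every output that is not a timing is bit-reproducible for a fixed master
seed: per-run seeds are derived by stable hashing of the plan identity, and
the simulator itself is deterministic.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .characterization import assemble_attributes
from .config import EcosystemConfig
from .indicators import indicator_series
from .perturbation import EnsembleManifest, apply_plan, build_manifest
from .simulator import Trajectory, initial_state_from_config, make_forcing, run_simulation
from .stability import (
    CVTable,
    PerYearFits,
    StepwiseResult,
    VARIANT_VARIABLES,
    build_glm_frame,
    cv_table,
    pearson_residuals,
    per_year_fits,
    selection_summary,
    summary_fit,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and run."""


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    config: EcosystemConfig
    outdir: Path
    sets: tuple[int, ...] = (1, 2, 3)
    fishing: str = "both"              # 'on' | 'off' | 'both'
    n_runs: int = 20                   # ensemble size per (set x fishing flag), sets 2-3
    master_seed: int = 0
    summary_years: tuple[int, int] = (1910, 2015)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.fishing not in ("on", "off", "both"):
            raise ValueError("fishing must be 'on', 'off' or 'both'")
        if any(s not in (1, 2, 3) for s in self.sets):
            raise ValueError("sets must be a subset of {1, 2, 3}")
        if self.n_runs < 2 and any(s in (2, 3) for s in self.sets):
            raise ValueError("n_runs must be >= 2 for sets feeding the CV analysis")


@dataclass
class RunReport:
    """In-memory results of one pipeline run."""

    manifest: EnsembleManifest
    trajectories: list[Trajectory]
    base: Trajectory
    attributes: pd.DataFrame
    indicators: pd.DataFrame
    cv_tables: dict[str, CVTable]
    per_year: dict[str, PerYearFits]
    summaries: dict[str, StepwiseResult]
    outdir: Path
    timings: dict[str, float] = field(default_factory=dict)


# the GLM model variants run by default: (label, variant, fished_filter)
MODEL_VARIANTS = (
    ("ALL", "ALL", "all"),
    ("BP", "BP", "all"),
    ("AS", "AS", "all"),
    ("AS_fished", "AS", "fished_only"),
    ("AS_unfished", "AS", "unfished_only"),
)


def run_pipeline(pc: PipelineConfig) -> RunReport:
    """Run every stage and write the output files under ``pc.outdir``."""
    out = pc.outdir
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    log_path = out / "log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, t0: float, **extra) -> None:
        timings[stage] = time.perf_counter() - t0
        log_fh.write(json.dumps({"stage": stage, "seconds": timings[stage], **extra}) + "\n")
        log_fh.flush()

    config = pc.config
    try:
        # 1. ensemble manifest
        t0 = time.perf_counter()
        manifest = build_manifest(
            config, sets=pc.sets, fishing=pc.fishing,
            n_runs=pc.n_runs, master_seed=pc.master_seed,
        )
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.scalar_table().to_csv(out / "scalars.csv")
        log("manifest", t0, n_plans=len(manifest.plans), master_seed=pc.master_seed)

        # 2. unfished base run + attributes
        t0 = time.perf_counter()
        base = run_simulation(config, fishing_on=False, plan_id="base")
        if base.status != "ok":
            raise PipelineError(f"stage 'base-run': base run failed ({base.failure_info})")
        attributes = assemble_attributes(config, base)
        attributes.to_csv(out / "attributes.csv")
        log("base-run", t0)

        # 3. ensemble simulations
        t0 = time.perf_counter()
        virgin = initial_state_from_config(config)
        trajectories: list[Trajectory] = []
        diverged: list[str] = []
        for plan in manifest.plans:
            state = apply_plan(virgin, plan, config)
            forcing = make_forcing(config, plan.fishing_on)
            traj = run_simulation(
                config, initial_state=state, forcing=forcing,
                fishing_on=plan.fishing_on, plan_id=plan.plan_id,
            )
            if traj.status != "ok":
                diverged.append(plan.plan_id)
            trajectories.append(traj)
        ok_runs = [t for t in trajectories if t.status == "ok"]
        if not ok_runs:
            raise PipelineError("stage 'ensemble': every run diverged")
        _write_trajectories(out, ok_runs)
        log("ensemble", t0, n_runs=len(trajectories), diverged=diverged)

        # 4. indicators
        t0 = time.perf_counter()
        plan_alts = {p.plan_id: p.chaos_alt for p in manifest.plans}
        ind = indicator_series(ok_runs, config)
        ind.insert(1, "chaos_alt", ind["run_id"].map(plan_alts))
        ind.to_csv(out / "indicators.csv", index=False)
        log("indicators", t0)

        # 5. CV tables per chaos_alt label
        t0 = time.perf_counter()
        cv_tables: dict[str, CVTable] = {}
        for alt in sorted({p.chaos_alt for p in manifest.plans}):
            n_ok = sum(1 for t in ok_runs if plan_alts[t.plan_id] == alt)
            if n_ok < 2:
                continue
            cv_tables[alt] = cv_table(ok_runs, [alt], plan_alts)
        if not cv_tables:
            raise PipelineError("stage 'cv': no chaos_alt label has >= 2 completed runs")
        _write_cv_tables(out, cv_tables)
        log("cv", t0, labels=sorted(cv_tables))

        # 6. GLMs: per-year fits and pooled summary fits
        t0 = time.perf_counter()
        years = [int(y) for y in base.reporting_years]
        per_year_results: dict[str, PerYearFits] = {}
        summaries: dict[str, StepwiseResult] = {}
        for label, variant, filt in MODEL_VARIANTS:
            frame = build_glm_frame(cv_tables, attributes, config, variant, filt)
            if len(frame) == 0:
                continue
            variables = VARIANT_VARIABLES[variant]
            pyf = per_year_fits(frame, years, variables)
            per_year_results[label] = pyf
            selection_summary(pyf).to_csv(out / f"selection_summary_{label}.csv", index=False)
            sfit = summary_fit(frame, variables, years=pc.summary_years)
            summaries[label] = sfit
            _write_summary_fit(out, label, sfit)
        log("glm", t0, models=sorted(summaries))
    finally:
        log_fh.close()

    return RunReport(
        manifest=manifest,
        trajectories=trajectories,
        base=base,
        attributes=attributes,
        indicators=ind,
        cv_tables=cv_tables,
        per_year=per_year_results,
        summaries=summaries,
        outdir=out,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def trajectory_dataset(trajectories: list[Trajectory]) -> xr.Dataset:
    """Bundle per-run annual outputs into one dataset
    (dims: run, year, group, as_group, age_class)."""
    t0 = trajectories[0]
    years = t0.years
    ds = xr.Dataset(
        {
            "biomass": (
                ("run", "year", "group"),
                np.stack([t.biomass for t in trajectories]),
            ),
            "numbers_at_age": (
                ("run", "year", "as_group", "age_class"),
                np.stack([t.numbers_at_age for t in trajectories]),
            ),
            "weight_at_age": (
                ("run", "year", "as_group", "age_class"),
                np.stack([t.weight_at_age for t in trajectories]),
            ),
        },
        coords={
            "run": [t.plan_id for t in trajectories],
            "year": years,
            "group": t0.group_names,
            "as_group": t0.as_names,
            "age_class": np.arange(t0.numbers_at_age.shape[2]),
        },
    )
    ds.attrs["burn_in_years"] = t0.burn_in_years
    return ds


def read_trajectory_dataset(path: Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def _write_trajectories(out: Path, runs: list[Trajectory]) -> None:
    ds = trajectory_dataset(runs)
    ds.to_netcdf(out / "trajectories.nc", engine="scipy")
    rows = []
    for t in runs:
        frame = t.biomass_frame(reporting_only=True)
        for year, row in frame.iterrows():
            for group, value in row.items():
                rows.append((t.plan_id, int(year), group, float(value)))
    pd.DataFrame(rows, columns=["run_id", "year", "group", "biomass"]).to_csv(
        out / "annual_biomass.csv", index=False
    )
    ledgers = []
    for t in runs:
        led = t.consumption_ledger()
        led.insert(0, "run_id", t.plan_id)
        ledgers.append(led)
    pd.concat(ledgers, ignore_index=True).to_csv(out / "consumption.csv", index=False)


def _write_cv_tables(out: Path, cv_tables: dict[str, CVTable]) -> None:
    rows = []
    for alt, table in sorted(cv_tables.items()):
        long = table.values.stack()
        for (group, year), cv in long.items():
            rows.append((alt, group, int(year), float(cv)))
    pd.DataFrame(rows, columns=["chaos_alt", "group", "year", "cv"]).to_csv(
        out / "cv_tables.csv", index=False
    )


def _write_summary_fit(out: Path, label: str, fit: StepwiseResult) -> None:
    pd.DataFrame(
        {
            "term": fit.terms,
            "incremental_r2": fit.increments,
            "cumulative_r2": fit.r2_path,
        }
    ).to_csv(out / f"summary_fit_{label}.csv", index=False)
    if fit.terms:
        fit.coefficients.rename("coefficient").to_csv(out / f"summary_coefficients_{label}.csv")
        pearson_residuals(fit).to_csv(out / f"summary_residuals_{label}.csv", index=False)


def export_results(report: RunReport, formats: tuple[str, ...] = ("csv",)) -> list[Path]:
    """Re-export the selection summaries and CV-by-year series from an
    in-memory report. Returns the written paths."""
    if report is None or not report.cv_tables:
        raise ValueError("empty report: run the pipeline first")
    written: list[Path] = []
    for fmt in formats:
        if fmt == "csv":
            _write_cv_tables(report.outdir, report.cv_tables)
            written.append(report.outdir / "cv_tables.csv")
            for label, pyf in report.per_year.items():
                p = report.outdir / f"selection_summary_{label}.csv"
                selection_summary(pyf).to_csv(p, index=False)
                written.append(p)
        elif fmt == "netcdf":
            ok_runs = [t for t in report.trajectories if t.status == "ok"]
            p = report.outdir / "trajectories.nc"
            trajectory_dataset(ok_runs).to_netcdf(p, engine="scipy")
            written.append(p)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written
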