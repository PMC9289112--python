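"""Dataset file dialect, run configuration and the staged analysis pipeline.

The dataset CSV dialect is the conventional rectangular pharmacometric
layout: columns ID, TIME (h since first dose), EVID (1 dose / 0
observation), AMT (mg lithium carbonate, dose rows), DV (mmol/L,
observation rows), MDV, BLQ, plus the per-subject covariates WT, AGE, SEX
(1 = male), SCR, CRCL, TDD, FORM (1 = sustained release).  A missing CRCL
column (or missing cells) is back-filled by Cockcroft-Gault; other
continuous covariates are median-imputed when less than 10% of subjects
lack them, and rejected beyond that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariate_search import default_candidates, run_scm
from .dosing_simulation import (
    ACUTE_WINDOW,
    DEFAULT_GRID,
    MAINTENANCE_WINDOW,
    recommend_dose,
    simulate_troughs,
)
from .estimation import (
    DIALECT_COLUMNS,
    EstimationResult,
    EstimationSettings,
    PKDataset,
    fit,
)
from .evaluation import bootstrap, gof_table, vpc
from .model_core import base_lithium_model, cockcroft_gault, final_lithium_model
from .synthetic_data import PopulationSpec, StudyDesign, generate_dataset, generate_population

__all__ = ["read_dataset", "write_dataset", "RunConfig", "run_pipeline"]

#: maximum tolerated fraction of missing values per continuous covariate
MISSING_MAX_FRACTION = 0.10

_CONTINUOUS_COVS = ("WT", "AGE", "SCR", "TDD")


def write_dataset(dataset: PKDataset | pd.DataFrame, path) -> None:
    """Write a dataset in the CSV dialect."""
    frame = dataset.frame if isinstance(dataset, PKDataset) else dataset
    frame.to_csv(path, index=False)


def read_dataset(path, lloq: float = 0.19) -> PKDataset:
    """Read and validate a dataset CSV, imputing covariates where allowed."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing_cols = [c for c in DIALECT_COLUMNS if c not in frame.columns and c != "CRCL"]
    if missing_cols:
        raise ValueError(f"{path.name}: missing required columns {missing_cols}")

    for col in _CONTINUOUS_COVS:
        vals = frame[col]
        frac = float(vals.isna().mean())
        if frac >= MISSING_MAX_FRACTION:
            raise ValueError(
                f"{path.name}: covariate {col} is {100 * frac:.0f}% missing "
                f"(imputation only below {100 * MISSING_MAX_FRACTION:.0f}%)"
            )
        if frac > 0:
            frame[col] = vals.fillna(vals.median())
    if frame["SEX"].isna().any():
        raise ValueError(f"{path.name}: SEX has missing values")

    if "CRCL" not in frame.columns:
        frame["CRCL"] = np.nan
    crcl = frame["CRCL"]
    if crcl.isna().any():
        need = crcl.isna()
        frame.loc[need, "CRCL"] = cockcroft_gault(
            frame.loc[need, "AGE"], frame.loc[need, "WT"],
            frame.loc[need, "SCR"], frame.loc[need, "SEX"],
        )

    bad = frame[(frame["EVID"] == 0) & (frame["MDV"] == 0) & frame["DV"].isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()  # 1-based + header
        raise ValueError(f"{path.name}: observation rows without DV at lines {lines}")
    return PKDataset(frame[list(DIALECT_COLUMNS)], lloq=lloq)


# ---------------------------------------------------------------------------
# run configuration


_STAGES = ("gen-data", "fit", "scm", "bootstrap", "vpc", "simulate-dose")


@dataclass
class RunConfig:
    """Configuration of a staged analysis run (YAML or JSON on disk)."""

    seed: int = 1
    output_dir: str = "litpk_out"
    stages: tuple = _STAGES
    dataset_path: str | None = None  # if unset, gen-data must run first
    n_subjects: int = 268
    model: str = "final"  # initial skeleton: "final" or "base"
    estimate_covariates: bool = True  # fit stage: include covariate effects
    bootstrap_replicates: int = 100
    vpc_simulations: int = 500
    vpc_bins: int = 1
    simulation_n: int = 1000
    simulation_interval_h: float = 12.0
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = data or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if any(s not in _STAGES for s in cfg.stages):
            bad = [s for s in cfg.stages if s not in _STAGES]
            raise ValueError(f"unknown stages: {bad}")
        return cfg


def _skeleton(cfg: RunConfig):
    if cfg.model == "final":
        model = final_lithium_model()
        if not cfg.estimate_covariates:
            model = base_lithium_model()
        return model
    if cfg.model == "base":
        return base_lithium_model()
    raise ValueError(f"unknown model skeleton {cfg.model!r}")


def run_pipeline(config: RunConfig, log=print) -> Path:
    """Execute the configured stages in order; returns the artifact directory.

    Stage order is fixed (gen-data, fit, scm, bootstrap, vpc,
    simulate-dose); stages that need a prior fit raise a dependency error
    when it is absent.  Every output is a CSV table; the run log records
    the package version, seeds and OFVs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"litpk {__version__}", f"seed {config.seed}"]

    dataset = None
    result: EstimationResult | None = None
    settings = EstimationSettings()

    if config.dataset_path:
        dataset = read_dataset(config.dataset_path)
        log_lines.append(f"dataset {config.dataset_path} "
                         f"({dataset.n_subjects} subjects, {dataset.n_observations} obs)")

    for stage in config.stages:
        if stage == "gen-data":
            pop = generate_population(
                PopulationSpec(n_subjects=config.n_subjects), seed=config.seed
            )
            dataset = generate_dataset(pop, final_lithium_model(),
                                       StudyDesign(), seed=config.seed + 1)
            write_dataset(dataset, out / "dataset.csv")
            pop.summary().to_csv(out / "covariate_summary.csv", index=False)
            log_lines.append(
                f"gen-data: {dataset.n_subjects} subjects, "
                f"{dataset.n_observations} observations, seed {config.seed}"
            )
        elif stage == "fit":
            if dataset is None:
                raise RuntimeError("fit requested without a dataset (run gen-data or set dataset_path)")
            result = fit(dataset, _skeleton(config), settings)
            result.param_table().to_csv(out / "estimates.csv", index=False)
            gof_table(dataset, result).to_csv(out / "gof.csv", index=False)
            log_lines.append(f"fit: OFV {result.ofv:.4f}, converged {result.converged}")
        elif stage == "scm":
            if dataset is None:
                raise RuntimeError("scm requested without a dataset")
            base = base_lithium_model()
            trace, scm_result = run_scm(dataset, base, default_candidates(), settings)
            trace.to_frame().to_csv(out / "scm_trace.csv", index=False)
            scm_result.param_table().to_csv(out / "scm_estimates.csv", index=False)
            result = scm_result
            log_lines.append(f"scm: selected {list(trace.selected)}, OFV {scm_result.ofv:.4f}")
        elif stage == "bootstrap":
            if dataset is None or result is None:
                raise RuntimeError("bootstrap requires a prior fit stage")
            rep = bootstrap(dataset, result.model, settings,
                            n_replicates=config.bootstrap_replicates,
                            seed=config.seed + 2)
            rep.table.to_csv(out / "bootstrap.csv", index=False)
            log_lines.append(
                f"bootstrap: {rep.n_replicates} replicates, "
                f"{rep.convergence_rate:.1f}% converged, seed {rep.seed}"
            )
        elif stage == "vpc":
            if dataset is None or result is None:
                raise RuntimeError("vpc requires a prior fit stage")
            rep = vpc(dataset, result.model, n_simulations=config.vpc_simulations,
                      seed=config.seed + 3, n_bins=config.vpc_bins)
            rep.table.to_csv(out / "vpc.csv", index=False)
            log_lines.append(f"vpc: {rep.n_simulations} simulations, seed {rep.seed}")
        elif stage == "simulate-dose":
            model = result.model if result is not None else final_lithium_model()
            dists = simulate_troughs(model, config.grid, n=config.simulation_n,
                                     seed=config.seed + 4,
                                     interval_h=config.simulation_interval_h)
            tables = []
            for window in (MAINTENANCE_WINDOW, ACUTE_WINDOW):
                t = recommend_dose(dists, window)
                t.insert(0, "phase", window.phase)
                tables.append(t)
            pd.concat(tables, ignore_index=True).to_csv(
                out / "dose_recommendations.csv", index=False
            )
            log_lines.append(f"simulate-dose: {len(dists)} strata, seed {config.seed + 4}")
        else:  # pragma: no cover - guarded in RunConfig
            raise ValueError(f"unknown stage {stage!r}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        log(line)
    return out
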