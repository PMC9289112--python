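"""Model qualification: goodness-of-fit, bootstrap, VPC, Ka sensitivity.

All surfaces are numeric tables (pandas DataFrames); plotting is left to
the caller.  Every randomised procedure takes an explicit seed and is
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import (
    EstimationResult,
    EstimationSettings,
    PKDataset,
    _Problem,
    fit,
)
from .model_core import PopulationModel

__all__ = [
    "BootstrapReport",
    "VPCReport",
    "gof_table",
    "bootstrap",
    "vpc",
    "ka_sensitivity",
]


def gof_table(dataset: PKDataset, result: EstimationResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Columns: ID, TIME, TAD (time after the most recent dose), DV, PRED
    (population prediction, eta = 0), IPRED (at the empirical Bayes etas),
    CWRES, IWRES.  Rows cover the observations included in the fit
    (below-LLOQ samples are absent, mirroring the estimation).
    """
    rows = dataset.frame.loc[result.obs_index]
    tad = np.full(len(rows), np.nan)
    if dataset.regular:
        keep_mask = np.isin(dataset.obs_index, result.obs_index)
        tad = dataset.sched[3][keep_mask]
    return pd.DataFrame(
        {
            "ID": rows["ID"].to_numpy(),
            "TIME": rows["TIME"].to_numpy(dtype=float),
            "TAD": tad,
            "DV": rows["DV"].to_numpy(dtype=float),
            "PRED": result.pred,
            "IPRED": result.ipred,
            "CWRES": result.cwres,
            "IWRES": result.iwres,
        }
    )


@dataclass
class BootstrapReport:
    """Percentile summary of nonparametric (subject-resampled) refits."""

    n_replicates: int
    convergence_rate: float  # percent of replicates that converged
    table: pd.DataFrame  # parameter, p2.5, median, p97.5
    estimates: pd.DataFrame  # one row per converged replicate
    seed: int

    def percentile_interval(self, parameter: str) -> tuple[float, float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["p2.5"]), float(row["median"]), float(row["p97.5"])


def _natural_params(model: PopulationModel) -> dict:
    out = {"theta_cl": model.theta_cl, "theta_v": model.theta_v}
    for e in model.covariate_effects:
        out[f"beta_{e.name}"] = e.theta
    if model.omega2_cl > 0:
        out["bsv_cl_percent"] = model.bsv_cl_percent
    if model.omega2_v > 0:
        out["bsv_v_percent"] = model.bsv_v_percent
    if model.residual.form in ("additive", "combined"):
        out["sigma_add"] = math.sqrt(model.residual.sigma2_add)
    if model.residual.form in ("proportional", "combined"):
        out["sigma_prop"] = math.sqrt(model.residual.sigma2_prop)
    return out


def bootstrap(
    dataset: PKDataset,
    model: PopulationModel,
    settings: EstimationSettings | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> BootstrapReport:
    """Subject-level nonparametric bootstrap of a fitted model.

    Subjects are resampled with replacement to the original subject count;
    each replicate is refitted starting from ``model`` (normally the final
    estimates).  Non-convergent replicates are excluded from the percentile
    table but counted in the convergence rate.
    """
    settings = settings or EstimationSettings()
    boot_settings = EstimationSettings(
        **{**settings.__dict__, "compute_uncertainty": False}
    )
    rng = np.random.default_rng(seed)
    rows = []
    n_ok = 0
    for _ in range(n_replicates):
        rep = dataset.resample_subjects(rng)
        try:
            res = fit(rep, model, boot_settings)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"bootstrap replicate failed: {exc}")
            continue
        if not res.converged:
            continue
        n_ok += 1
        rows.append(_natural_params(res.model))
    estimates = pd.DataFrame(rows)
    if len(estimates):
        q = estimates.quantile([0.025, 0.5, 0.975])
        table = pd.DataFrame(
            {
                "parameter": estimates.columns,
                "p2.5": q.loc[0.025].to_numpy(),
                "median": q.loc[0.5].to_numpy(),
                "p97.5": q.loc[0.975].to_numpy(),
            }
        )
    else:
        table = pd.DataFrame(columns=["parameter", "p2.5", "median", "p97.5"])
    return BootstrapReport(
        n_replicates=n_replicates,
        convergence_rate=100.0 * n_ok / n_replicates if n_replicates else math.nan,
        table=table,
        estimates=estimates,
        seed=seed,
    )


@dataclass
class VPCReport:
    """Observed percentiles vs simulation-based confidence bands per bin."""

    table: pd.DataFrame  # bin, n_obs, obs_p5/p50/p95, lo/hi envelopes
    n_simulations: int
    seed: int
    stratify_by: str | None = None

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside its simulated 95% envelope."""
        t = self.table
        hits = 0
        total = 0
        for p in ("p5", "p50", "p95"):
            ok = (t[f"obs_{p}"] >= t[f"sim_{p}_lo"]) & (t[f"obs_{p}"] <= t[f"sim_{p}_hi"])
            hits += int(ok.sum())
            total += len(t)
        return hits / total if total else math.nan


def _simulate_observations(prob: _Problem, model: PopulationModel,
                           rng: np.random.Generator) -> np.ndarray:
    """One replicate of the observed design: new etas and residual errors."""
    p = prob.spec.unpack(prob.spec.pack(model))
    cl_typ, v_typ = prob.typical_params(p)
    eta = np.zeros((prob.n_subj, prob.k))
    for d, which in enumerate(prob.eta_active):
        om = p["omega2_cl"] if which == 0 else p["omega2_v"]
        eta[:, d] = rng.normal(0.0, math.sqrt(om), size=prob.n_subj)
    f = prob._f_eta(cl_typ, v_typ, eta)
    sd = np.sqrt(np.maximum(p["sigma2_add"] + p["sigma2_prop"] * f * f, 0.0))
    return f + rng.normal(size=len(f)) * sd


def vpc(
    dataset: PKDataset,
    model: PopulationModel,
    n_simulations: int = 1000,
    seed: int = 0,
    n_bins: int = 1,
    settings: EstimationSettings | None = None,
) -> VPCReport:
    """Visual predictive check (numeric form, no prediction correction).

    ``n_simulations`` replicates of the dataset's own design are simulated
    from ``model``; the 5th/50th/95th percentiles of each replicate are
    summarised into a 2.5-97.5% envelope per bin and set against the
    observed percentiles.  Troughs share a common time-after-dose, so the
    default is a single bin; ``n_bins`` > 1 bins on time after first dose
    by quantiles (empty bins are merged into their neighbour).
    """
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    rng = np.random.default_rng(seed)
    y = prob.y
    times = dataset.obs["TIME"].to_numpy(dtype=float)[prob.keep]

    if n_bins <= 1:
        bin_idx = np.zeros(len(y), dtype=int)
        edges = [(times.min(), times.max())]
    else:
        qs = np.quantile(times, np.linspace(0, 1, n_bins + 1))
        qs = np.unique(qs)
        if len(qs) - 1 < n_bins:
            warnings.warn("empty VPC bins merged with neighbours")
        bin_idx = np.clip(np.searchsorted(qs, times, side="right") - 1, 0, len(qs) - 2)
        edges = [(qs[i], qs[i + 1]) for i in range(len(qs) - 1)]
    n_used_bins = len(edges)

    sim_pct = np.empty((n_simulations, n_used_bins, 3))
    for s in range(n_simulations):
        ysim = _simulate_observations(prob, model, rng)
        for b in range(n_used_bins):
            sel = ysim[bin_idx == b]
            sim_pct[s, b] = np.percentile(sel, [5, 50, 95])

    rows = []
    for b, (lo_t, hi_t) in enumerate(edges):
        sel = y[bin_idx == b]
        obs = np.percentile(sel, [5, 50, 95])
        env_lo = np.percentile(sim_pct[:, b, :], 2.5, axis=0)
        env_hi = np.percentile(sim_pct[:, b, :], 97.5, axis=0)
        rows.append(
            {
                "bin": b,
                "t_lo": lo_t,
                "t_hi": hi_t,
                "n_obs": int((bin_idx == b).sum()),
                "obs_p5": obs[0], "obs_p50": obs[1], "obs_p95": obs[2],
                "sim_p5_lo": env_lo[0], "sim_p5_hi": env_hi[0],
                "sim_p50_lo": env_lo[1], "sim_p50_hi": env_hi[1],
                "sim_p95_lo": env_lo[2], "sim_p95_hi": env_hi[2],
            }
        )
    return VPCReport(
        table=pd.DataFrame(rows), n_simulations=n_simulations, seed=seed
    )


def ka_sensitivity(
    dataset: PKDataset,
    skeleton: PopulationModel,
    settings: EstimationSettings | None = None,
    ka_values=(0.146, 0.220, 0.293, 0.440, 0.586),
) -> pd.DataFrame:
    """Refit with the absorption constant fixed at each value of a grid.

    Returns a table of (ka, theta_cl, theta_v, ofv, converged) showing how
    the clearance estimate shifts as the assumed Ka moves across the
    plausible range; with trough-only data the shift should be modest.
    """
    settings = settings or EstimationSettings()
    sens_settings = EstimationSettings(
        **{**settings.__dict__, "compute_uncertainty": False}
    )
    rows = []
    from dataclasses import replace as _replace

    for ka in ka_values:
        skel = _replace(skeleton, ka=float(ka))
        res = fit(dataset, skel, sens_settings)
        rows.append(
            {
                "ka": float(ka),
                "theta_cl": res.model.theta_cl,
                "theta_v": res.model.theta_v,
                "ofv": res.ofv,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
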