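"""Virtual bipolar-disorder populations and simulated lithium TDM datasets.

The generator emulates the covariate structure of the study population this
package's default model was built for: 268 adult and adolescent patients on
maintenance lithium carbonate, 476 steady-state trough samples drawn before
the morning dose, two-thirds female, median weight 62 kg, median daily dose
600 mg, creatinine clearance derived from age/weight/serum creatinine by
Cockcroft-Gault.  Observations are simulated from a population model
(by default the final lithium model) with lognormal between-subject
variability and additive residual error, and flagged when they fall below
the assay's lower limit of quantification (0.19 mmol/L).

Distribution families are pragmatic choices: the source study reports only
medians, ranges and means +/- SD.  Weight and serum creatinine use truncated
normals; age and daily dose are right-skewed (lognormal-based) so that the
generated medians sit below the means, as observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import PKDataset
from .model_core import (
    MMOL_PER_MG,
    PopulationModel,
    SubjectCovariates,
    _conc_profile,
    cockcroft_gault,
    final_lithium_model,
)

__all__ = [
    "PopulationSpec",
    "StudyDesign",
    "VirtualPopulation",
    "generate_population",
    "generate_dataset",
    "perturb_for_null",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling spec for the virtual covariate population.

    Defaults reproduce the study demographics: n = 268 subjects, 66.8%
    female, age median ~31 y (mean 35, SD 14.5) on [13, 77], weight
    ~N(63.7, 11.1) on [35, 110] kg, serum creatinine ~N(63.7, 12.6) on
    [40, 115] umol/L, total daily dose lognormal with median 600 mg rounded
    to the 150 mg half-tablet grid and clamped to [150, 1500], 76.1%
    sustained-release formulation.
    """

    n_subjects: int = 268
    female_fraction: float = 0.668
    age_offset: float = 13.0  # years; lower bound of the shifted lognormal
    age_median_above_offset: float = 19.0  # median age = offset + this
    age_sigma_log: float = 0.70
    age_max: float = 77.0
    weight_mean: float = 63.7  # kg
    weight_sd: float = 11.1
    weight_bounds: tuple[float, float] = (35.0, 110.0)
    scr_mean: float = 63.7  # umol/L
    scr_sd: float = 12.6
    scr_bounds: tuple[float, float] = (40.0, 115.0)
    dose_median: float = 600.0  # mg/day lithium carbonate
    dose_sigma_log: float = 0.75
    dose_grid: float = 150.0  # mg; half-tablet increments
    dose_bounds: tuple[float, float] = (150.0, 1500.0)
    sustained_release_fraction: float = 0.761

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for lo, hi, mean, sd, name in (
            (*self.weight_bounds, self.weight_mean, self.weight_sd, "weight"),
            (*self.scr_bounds, self.scr_mean, self.scr_sd, "serum creatinine"),
        ):
            if not (lo < hi):
                raise ValueError(f"{name} bounds must be increasing")
            if hi < mean - 4 * sd or lo > mean + 4 * sd:
                raise ValueError(f"infeasible truncation for {name}")


@dataclass(frozen=True)
class StudyDesign:
    """Sparse trough-only TDM sampling design.

    Each subject contributes one or two pre-dose troughs (P(two) = 0.776,
    so 268 subjects yield ~476 samples in expectation), drawn at steady
    state: every observation is preceded by at least ``min_doses`` (14)
    q12h administrations, i.e. at least seven days of dosing.
    """

    p_two_obs: float = 0.776
    interval_h: float = 12.0
    min_doses: int = 14
    max_doses: int = 56

    def __post_init__(self):
        if not (0.0 <= self.p_two_obs <= 1.0):
            raise ValueError("p_two_obs must be a probability")
        if self.min_doses < 1 or self.max_doses < self.min_doses:
            raise ValueError("invalid dose-count range")


@dataclass(frozen=True)
class VirtualPopulation:
    """Sampled covariate vectors (one row per virtual subject)."""

    frame: pd.DataFrame  # columns ID, WT, AGE, SEX, SCR, CRCL, TDD, FORM
    spec: PopulationSpec
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def subject_covariates(self) -> list[SubjectCovariates]:
        out = []
        for row in self.frame.itertuples():
            out.append(
                SubjectCovariates(
                    weight=row.WT,
                    age=row.AGE,
                    sex="male" if row.SEX == 1 else "female",
                    serum_creatinine=row.SCR,
                    total_daily_dose=row.TDD,
                    creatinine_clearance=row.CRCL,
                    dosage_form="sustained_release" if row.FORM == 1 else "ordinary",
                )
            )
        return out

    def summary(self) -> pd.DataFrame:
        """Covariate summary table (median, range, mean, SD) per covariate."""
        rows = []
        for col in ("AGE", "WT", "TDD", "SCR", "CRCL"):
            x = self.frame[col].to_numpy()
            if len(x) == 0:
                rows.append((col, *(math.nan,) * 5))
                continue
            rows.append(
                (col, float(np.median(x)), float(x.min()), float(x.max()),
                 float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else math.nan)
            )
        extra = {
            "female_fraction": float((self.frame["SEX"] == 0).mean()) if len(self.frame) else math.nan,
            "sustained_release_fraction": float((self.frame["FORM"] == 1).mean()) if len(self.frame) else math.nan,
        }
        out = pd.DataFrame(rows, columns=["covariate", "median", "min", "max", "mean", "sd"])
        out.attrs.update(extra)
        return out


def _truncated_lognormal(rng, median, sigma, low, high, size):
    """Lognormal(ln median, sigma) truncated to [low, high] by inverse CDF."""
    mu = math.log(median)
    lo = stats.norm.cdf((math.log(max(low, 1e-12)) - mu) / sigma) if low > 0 else 0.0
    hi = stats.norm.cdf((math.log(high) - mu) / sigma)
    u = rng.uniform(lo, hi, size=size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def generate_population(spec: PopulationSpec | None = None, seed: int = 0) -> VirtualPopulation:
    """Sample a virtual covariate population.

    Creatinine clearance is always derived from the sampled age, weight,
    serum creatinine and sex via Cockcroft-Gault, never drawn directly.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    sex = (rng.uniform(size=n) >= spec.female_fraction).astype(int)  # 1 = male
    age = spec.age_offset + _truncated_lognormal(
        rng, spec.age_median_above_offset, spec.age_sigma_log,
        0.0, spec.age_max - spec.age_offset, n,
    )
    weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, *spec.weight_bounds, size=n)
    scr = _truncated_normal(rng, spec.scr_mean, spec.scr_sd, *spec.scr_bounds, size=n)
    tdd = _truncated_lognormal(rng, spec.dose_median, spec.dose_sigma_log, 0.0, 1e9, n)
    tdd = np.clip(np.round(tdd / spec.dose_grid) * spec.dose_grid, *spec.dose_bounds)
    form = (rng.uniform(size=n) < spec.sustained_release_fraction).astype(int)
    crcl = cockcroft_gault(age, weight, scr, sex) if n else np.array([])

    frame = pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "WT": np.round(weight, 1),
            "AGE": np.round(age, 1),
            "SEX": sex,
            "SCR": np.round(scr, 1),
            "TDD": tdd,
            "FORM": form,
        }
    )
    frame["CRCL"] = np.round(
        cockcroft_gault(frame["AGE"], frame["WT"], frame["SCR"], frame["SEX"]), 1
    ) if n else crcl
    frame = frame[["ID", "WT", "AGE", "SEX", "SCR", "CRCL", "TDD", "FORM"]]
    return VirtualPopulation(frame=frame, spec=spec, seed=seed)


def generate_dataset(
    population: VirtualPopulation,
    model: PopulationModel | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
    lloq: float = 0.19,
) -> PKDataset:
    """Simulate a trough-only TDM dataset from ``model`` for a population.

    Each subject receives TDD/2 mg q12h; one or two pre-dose troughs are
    observed after >= ``design.min_doses`` administrations.  eta draws are
    lognormal per Pi = Ptv * exp(eta); residual error follows the model's
    residual form.  Observations below ``lloq`` are flagged BLQ (kept in
    the file; the estimator applies the <10% ignore rule).
    """
    model = model or final_lithium_model()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    covs = population.subject_covariates()
    n = len(covs)

    eta = np.zeros((n, 2))
    if model.omega2_cl > 0:
        eta[:, 0] = rng.normal(0.0, math.sqrt(model.omega2_cl), size=n)
    if model.omega2_v > 0:
        eta[:, 1] = rng.normal(0.0, math.sqrt(model.omega2_v), size=n)

    n_obs = 1 + (rng.uniform(size=n) < design.p_two_obs).astype(int)
    rows = []
    tau = design.interval_h
    for i, cov in enumerate(covs):
        dose = cov.total_daily_dose * tau / 24.0
        cl = model.typical_value("cl", cov) * math.exp(eta[i, 0])
        v = model.typical_value("v", cov) * math.exp(eta[i, 1])
        ke = cl / v
        m_counts = np.sort(
            rng.choice(
                np.arange(design.min_doses, design.max_doses + 1),
                size=n_obs[i],
                replace=False,
            )
        )
        base = {
            "ID": population.frame["ID"].iloc[i],
            "WT": cov.weight,
            "AGE": cov.age,
            "SEX": 1 if cov.sex == "male" else 0,
            "SCR": cov.serum_creatinine,
            "CRCL": cov.creatinine_clearance,
            "TDD": cov.total_daily_dose,
            "FORM": 1 if cov.dosage_form == "sustained_release" else 0,
        }
        for k in range(int(m_counts[-1])):
            rows.append({**base, "TIME": k * tau, "EVID": 1, "AMT": dose,
                         "DV": np.nan, "MDV": 1, "BLQ": 0})
        for m in m_counts:
            trough = float(
                _conc_profile(dose * MMOL_PER_MG, tau, float(m), tau, model.ka, ke, v)
            )
            sd = math.sqrt(float(model.residual.variance(trough)))
            y = trough + rng.normal(0.0, sd) if sd > 0 else trough
            rows.append({**base, "TIME": m * tau, "EVID": 0, "AMT": np.nan,
                         "DV": y, "MDV": 0, "BLQ": int(y < lloq)})

    frame = pd.DataFrame(rows, columns=[
        "ID", "TIME", "EVID", "AMT", "DV", "MDV", "BLQ",
        "WT", "AGE", "SEX", "SCR", "CRCL", "TDD", "FORM",
    ])
    # pre-dose troughs sort before the dose given at the same clock time
    frame = frame.sort_values(["ID", "TIME", "EVID"], kind="stable")
    frame = frame.reset_index(drop=True)
    dataset = PKDataset(frame, lloq=lloq)
    dataset.true_etas = eta  # generating etas, kept for calibration checks
    return dataset


_KNOWN_COVARIATES = ("wt", "age", "sex", "scr", "crcl", "tdd", "form")


def perturb_for_null(model: PopulationModel, covariate: str, parameter: str = "cl") -> PopulationModel:
    """Zero one covariate effect (or ``"all"``) in a generating model.

    A recognised covariate that is absent from the model returns the model
    unchanged (its effect is already zero); an unrecognised name is an error.
    """
    if covariate == "all":
        effects = tuple(
            replace(e, theta=0.0) if e.parameter == parameter else e
            for e in model.covariate_effects
        )
        return replace(model, covariate_effects=effects)
    if covariate not in _KNOWN_COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}")
    effects = tuple(
        replace(e, theta=0.0)
        if (e.parameter == parameter and e.covariate == covariate)
        else e
        for e in model.covariate_effects
    )
    return replace(model, covariate_effects=effects)
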