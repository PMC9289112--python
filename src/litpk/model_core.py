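"""Structural PK model for oral lithium and its covariate sub-model.

Lithium carbonate kinetics are described by a one-compartment disposition
model with first-order absorption and first-order (renal) elimination,
parameterised as apparent clearance CL/F (L/h) and apparent volume V/F (L).
Only trough samples are available in the therapeutic-drug-monitoring setting
this package targets, so the absorption rate constant Ka is a fixed constant
(0.293 1/h) rather than an estimated parameter.

Between-subject variability is lognormal, ``P_i = P_tv * exp(eta_i)`` with
``eta_i ~ N(0, omega^2)``.  Covariates act multiplicatively on the typical
value through power, linear, or categorical terms, each anchored at a frozen
reference value (600 mg/day total dose, 62 kg, 116 ml/min creatinine
clearance for the final lithium model).

Doses are milligrams of lithium carbonate; concentrations are mmol/L of
lithium ion.  One mg of Li2CO3 (MW 73.893 g/mol, two Li+ per formula unit)
is 0.0270662 mmol lithium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MMOL_PER_MG",
    "SubjectCovariates",
    "CovariateEffect",
    "ResidualModel",
    "PopulationModel",
    "IndividualParameters",
    "DosingRegimen",
    "cockcroft_gault",
    "apply_covariate_effect",
    "typical_clearance",
    "typical_volume",
    "individual_parameters",
    "concentration",
    "steady_state_trough",
    "final_lithium_model",
    "base_lithium_model",
]

#: mmol of lithium ion per mg of lithium carbonate (2 * 1000 / 73893).
MMOL_PER_MG = 0.0270662

#: Relative |ka - ke| threshold below which the flip-flop limit is used.
_KA_KE_RTOL = 1e-8


def cockcroft_gault(age, weight, scr, sex):
    """Creatinine clearance (ml/min) by the Cockcroft-Gault formula.

    ``CRCL = (140 - age) * weight / (0.818 * SCR) * k`` with serum
    creatinine in umol/L and k = 1 for males, 0.85 for females.

    Parameters may be scalars or arrays; ``sex`` is ``"male"``/``"female"``
    or a 0/1 numeric code with 1 = male.
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(weight <= 0) or np.any(scr <= 0):
        raise ValueError("weight and serum creatinine must be positive")
    if np.any(age < 0) or np.any(age > 140):
        raise ValueError("age must be in [0, 140]")
    k = _sex_factor(sex)
    out = (140.0 - age) * weight / (0.818 * scr) * k
    return out if out.ndim else float(out)


def _sex_factor(sex):
    if isinstance(sex, str):
        if sex not in ("male", "female"):
            raise ValueError(f"unknown sex {sex!r}")
        return 1.0 if sex == "male" else 0.85
    code = np.asarray(sex, dtype=float)  # 1 = male, 0 = female
    return np.where(code > 0.5, 1.0, 0.85)


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates entering the lithium clearance model.

    ``creatinine_clearance`` may be omitted, in which case it is derived
    from age/weight/serum creatinine/sex via :func:`cockcroft_gault`.
    """

    weight: float  # kg
    age: float  # years
    sex: str  # "male" | "female"
    serum_creatinine: float  # umol/L
    total_daily_dose: float  # mg lithium carbonate per day
    creatinine_clearance: float | None = None  # ml/min
    dosage_form: str = "sustained_release"  # "ordinary" | "sustained_release"

    def __post_init__(self):
        for name in ("weight", "age", "serum_creatinine", "total_daily_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.dosage_form not in ("ordinary", "sustained_release"):
            raise ValueError(f"unknown dosage form {self.dosage_form!r}")
        if self.creatinine_clearance is None:
            object.__setattr__(
                self,
                "creatinine_clearance",
                cockcroft_gault(self.age, self.weight, self.serum_creatinine, self.sex),
            )
        elif self.creatinine_clearance <= 0:
            raise ValueError("creatinine_clearance must be positive")

    def value(self, covariate: str) -> float:
        """Numeric value of a named covariate (sex: 1 = male, 0 = female)."""
        try:
            return {
                "wt": self.weight,
                "age": self.age,
                "sex": 1.0 if self.sex == "male" else 0.0,
                "scr": self.serum_creatinine,
                "crcl": self.creatinine_clearance,
                "tdd": self.total_daily_dose,
                "form": 1.0 if self.dosage_form == "sustained_release" else 0.0,
            }[covariate]
        except KeyError:
            raise KeyError(f"unknown covariate {covariate!r}") from None


_FORMS = ("power", "linear", "categorical")


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter.

    form ``power``:       P * (cov / reference) ** theta
    form ``linear``:      P * (1 + theta * cov / reference)
    form ``categorical``: P * (1 + theta * cov)   (cov coded 0/1)
    """

    parameter: str  # "cl" | "v"
    covariate: str  # e.g. "tdd", "wt", "crcl", "sex"
    form: str
    theta: float
    reference: float = 1.0

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form in ("power", "linear") and self.reference <= 0:
            raise ValueError("reference value must be positive")

    @property
    def name(self) -> str:
        return f"{self.parameter}_{self.covariate}"


def apply_covariate_effect(p_typical, cov_value, cov_median, theta, form):
    """Apply one covariate relationship to a typical parameter value."""
    if form == "power":
        if np.any(np.asarray(cov_value) <= 0) or cov_median <= 0:
            raise ValueError("power form requires positive covariate and reference")
        return p_typical * (np.asarray(cov_value, dtype=float) / cov_median) ** theta
    if form == "linear":
        if cov_median <= 0:
            raise ValueError("linear form requires a positive reference")
        return p_typical * (1.0 + theta * np.asarray(cov_value, dtype=float) / cov_median)
    if form == "categorical":
        return p_typical * (1.0 + theta * np.asarray(cov_value, dtype=float))
    raise ValueError(f"unknown covariate form {form!r}")


@dataclass(frozen=True)
class ResidualModel:
    """Residual (within-subject / assay) error model.

    additive:      y = f + eps2,                 var = sigma2_add
    proportional:  y = f * (1 + eps1),           var = sigma2_prop * f^2
    combined:      y = f * (1 + eps1) + eps2,    var = sigma2_add + sigma2_prop * f^2
    """

    form: str = "additive"
    sigma2_add: float = 0.0  # (mmol/L)^2
    sigma2_prop: float = 0.0  # dimensionless

    def __post_init__(self):
        if self.form not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual form {self.form!r}")
        if self.sigma2_add < 0 or self.sigma2_prop < 0:
            raise ValueError("residual variances must be non-negative")
        if self.form == "additive" and self.sigma2_prop != 0:
            raise ValueError("additive form must have sigma2_prop = 0")
        if self.form == "proportional" and self.sigma2_add != 0:
            raise ValueError("proportional form must have sigma2_add = 0")

    def variance(self, pred):
        """Residual variance at prediction ``pred`` (array-friendly)."""
        return self.sigma2_add + self.sigma2_prop * np.square(pred)

    @property
    def sigma_add(self) -> float:
        return math.sqrt(self.sigma2_add)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate structure, BSV variances and residual model."""

    theta_cl: float  # typical CL/F, L/h, at reference covariates
    theta_v: float  # typical V/F, L
    ka: float  # 1/h, fixed
    covariate_effects: tuple[CovariateEffect, ...] = ()
    omega2_cl: float = 0.0  # var of eta_CL (log scale)
    omega2_v: float = 0.0  # var of eta_V (log scale)
    residual: ResidualModel = field(default_factory=ResidualModel)

    def __post_init__(self):
        if min(self.theta_cl, self.theta_v, self.ka) <= 0:
            raise ValueError("theta_cl, theta_v and ka must be positive")
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("omega2 values must be non-negative")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    def effects_on(self, parameter: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.covariate_effects if e.parameter == parameter)

    def typical_value(self, parameter: str, cov: SubjectCovariates) -> float:
        base = {"cl": self.theta_cl, "v": self.theta_v}[parameter]
        for eff in self.effects_on(parameter):
            base = apply_covariate_effect(
                base, cov.value(eff.covariate), eff.reference, eff.theta, eff.form
            )
        return float(base)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        if any(
            e.parameter == effect.parameter and e.covariate == effect.covariate
            for e in self.covariate_effects
        ):
            raise ValueError(f"effect {effect.name} already present")
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, parameter: str, covariate: str) -> "PopulationModel":
        kept = tuple(
            e
            for e in self.covariate_effects
            if not (e.parameter == parameter and e.covariate == covariate)
        )
        if len(kept) == len(self.covariate_effects):
            raise ValueError(f"no effect {parameter}_{covariate} in model")
        return replace(self, covariate_effects=kept)

    @property
    def bsv_cl_percent(self) -> float:
        """Between-subject variability on CL reported as 100*sqrt(omega2)."""
        return 100.0 * math.sqrt(self.omega2_cl)

    @property
    def bsv_v_percent(self) -> float:
        return 100.0 * math.sqrt(self.omega2_v)


def final_lithium_model() -> PopulationModel:
    """The final lithium population model (covariates on CL, additive error).

    CL/F = 0.909 * (TDD/600)^0.354 * (WT/62)^0.33 * (CRCL/116)^0.186 L/h,
    V/F = 10.9 L, Ka = 0.293 1/h fixed, omega2_CL = 0.027 (16.4 %BSV),
    omega2_V = 0.162 (40.2 %BSV), additive residual SD 0.0218 mmol/L.
    """
    return PopulationModel(
        theta_cl=0.909,
        theta_v=10.9,
        ka=0.293,
        covariate_effects=(
            CovariateEffect("cl", "tdd", "power", 0.354, 600.0),
            CovariateEffect("cl", "wt", "power", 0.33, 62.0),
            CovariateEffect("cl", "crcl", "power", 0.186, 116.0),
        ),
        omega2_cl=0.027,
        omega2_v=0.162,
        residual=ResidualModel("additive", sigma2_add=0.0218**2),
    )


def base_lithium_model() -> PopulationModel:
    """Covariate-free base model (typical starting skeleton for estimation)."""
    return PopulationModel(
        theta_cl=1.0,
        theta_v=10.0,
        ka=0.293,
        omega2_cl=0.04,
        omega2_v=0.16,
        residual=ResidualModel("additive", sigma2_add=0.03**2),
    )


def typical_clearance(model: PopulationModel, cov: SubjectCovariates) -> float:
    """Typical CL/F (L/h) for a subject's covariates under ``model``."""
    return model.typical_value("cl", cov)


def typical_volume(model: PopulationModel, cov: SubjectCovariates) -> float:
    return model.typical_value("v", cov)


@dataclass(frozen=True)
class IndividualParameters:
    """Realised PK parameters of one subject."""

    cl: float  # L/h
    v: float  # L
    ka: float  # 1/h
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self):
        if min(self.cl, self.v, self.ka) <= 0:
            raise ValueError("cl, v and ka must be positive")

    @property
    def ke(self) -> float:
        return self.cl / self.v


def individual_parameters(
    model: PopulationModel,
    cov: SubjectCovariates,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """``P_i = P_tv * exp(eta_i)`` applied to CL and V; Ka copied from model."""
    return IndividualParameters(
        cl=model.typical_value("cl", cov) * math.exp(eta_cl),
        v=model.typical_value("v", cov) * math.exp(eta_v),
        ka=model.ka,
        eta_cl=eta_cl,
        eta_v=eta_v,
    )


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated equal oral doses of lithium carbonate at a fixed interval."""

    dose_mg: float  # mg lithium carbonate per administration
    interval_h: float  # h
    n_doses: float = math.inf  # count; inf = at steady state

    def __post_init__(self):
        if self.interval_h <= 0:
            raise ValueError("interval must be positive")
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.interval_h

    @property
    def dose_mmol(self) -> float:
        return self.dose_mg * MMOL_PER_MG


def _geometric_sum(k, tau, m, s):
    """``sum_{j=0}^{m-1} exp(-k (s + j tau))`` with m possibly infinite.

    All arguments broadcast; ``s`` is the time since the most recent dose,
    so every exponent is non-positive and the expression cannot overflow.
    """
    k = np.asarray(k, dtype=float)
    q = np.exp(-k * tau)
    head = np.exp(-k * s)
    with np.errstate(divide="ignore", invalid="ignore"):
        inf_sum = head / (1.0 - q)
        m_arr = np.asarray(m, dtype=float)
        fin_sum = head * np.where(np.isinf(m_arr), 1.0, -np.expm1(-k * tau * np.minimum(m_arr, 1e12))) / (1.0 - q)
        out = np.where(np.isinf(m_arr), inf_sum, fin_sum)
    # k*tau ~ 0 would divide by zero; callers guard k > 0 and tau > 0.
    return out


def _conc_profile(dose_mmol, tau, m, s, ka, ke, v):
    """Superposed one-compartment concentration (mmol/L), vectorised.

    ``m`` doses of ``dose_mmol`` each were given ``tau`` apart; ``s`` >= 0 is
    the time elapsed since the most recent of them.  ``m`` may be ``inf``
    (steady state).  Handles the removable ka == ke singularity by switching
    to the ``D ka t exp(-ka t) / V`` limit.
    """
    dose_mmol = np.asarray(dose_mmol, dtype=float)
    ka = np.asarray(ka, dtype=float)
    ke = np.asarray(ke, dtype=float)
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    tau = np.asarray(tau, dtype=float)
    m = np.asarray(m, dtype=float)

    ke_safe = np.maximum(ke, 1e-12)
    degenerate = np.abs(ka - ke_safe) < _KA_KE_RTOL * ka

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # regular branch: D ka / (V (ka-ke)) * (S(ke) - S(ka))
        denom = np.where(degenerate, 1.0, ka - ke_safe)
        regular = (
            dose_mmol
            * ka
            / (v * denom)
            * (_geometric_sum(ke_safe, tau, m, s) - _geometric_sum(ka, tau, m, s))
        )

        # flip-flop limit: sum_j D ka (s + j tau) exp(-ka (s + j tau)) / V
        q = np.exp(-ka * tau)
        head = np.exp(-ka * s)
        m_fin = np.where(np.isinf(m), 1e12, m)
        qm = q**m_fin
        sum0 = np.where(np.isinf(m), 1.0 / (1.0 - q), (1.0 - qm) / (1.0 - q))
        sum1 = np.where(
            np.isinf(m),
            q / (1.0 - q) ** 2,
            (q - m_fin * qm + (m_fin - 1.0) * qm * q) / (1.0 - q) ** 2,
        )
        limit = dose_mmol * ka * head * (s * sum0 + tau * sum1) / v

        out = np.where(degenerate, limit, regular)
    return np.maximum(out, 0.0)


def concentration(regimen: DosingRegimen, ind: IndividualParameters, t):
    """Lithium concentration (mmol/L) at time(s) ``t`` hours after the first dose.

    Doses are administered at 0, tau, 2*tau, ...; times before the first
    dose return 0.  Superposition of the closed-form one-compartment
    first-order absorption solution over all administered doses.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    tau = regimen.interval_h
    # number of doses already given at time t (dose at exactly t contributes 0)
    m = np.minimum(np.floor(t / tau) + 1, regimen.n_doses)
    s = t - (np.minimum(np.floor(t / tau), regimen.n_doses - 1)) * tau
    out = _conc_profile(regimen.dose_mmol, tau, m, s, ind.ka, ind.ke, ind.v)
    return out if out.ndim else float(out)


def steady_state_trough(regimen: DosingRegimen, ind: IndividualParameters) -> float:
    """Pre-dose concentration (mmol/L) at steady state under repeated dosing."""
    out = _conc_profile(
        regimen.dose_mmol, regimen.interval_h, math.inf, regimen.interval_h,
        ind.ka, ind.ke, ind.v,
    )
    return float(out)
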