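"""Three-step covariate analysis: screening, forward inclusion, backward elimination.

Candidate covariate-parameter relationships are first screened by the
correlation between the empirical Bayes eta on clearance and each covariate
(the numerical surrogate of a graphical eta-vs-covariate display).  The
surviving candidates then enter a greedy stepwise search on the FOCE-I
objective: a candidate is accepted when adding it drops the OFV by more
than 3.84 (chi-square, 1 df, p < 0.05) and, in the backward phase, a
retained covariate is removed when deleting it raises the OFV by less than
6.63 (p > 0.01).  Decisions depend only on OFV differences; ties break on
declaration order, so the search is deterministic given the data and
settings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import EstimationResult, EstimationSettings, PKDataset, fit
from .model_core import CovariateEffect, PopulationModel

__all__ = [
    "CovariateCandidate",
    "SelectionTrace",
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
    "screen_correlations",
    "forward_step",
    "backward_step",
    "run_scm",
]

#: OFV drop required to accept a covariate in forward inclusion (p < 0.05)
FORWARD_DOFV = 3.84
#: OFV rise below which a covariate is removed in backward elimination (p > 0.01)
BACKWARD_DOFV = 6.63

#: candidates of interest in the lithium analysis: weight, creatinine
#: clearance, daily dose (power forms) and sex (categorical, 0 = female)
DEFAULT_CANDIDATES = (
    ("cl", "tdd", "power", 600.0),
    ("cl", "wt", "power", 62.0),
    ("cl", "crcl", "power", 116.0),
    ("cl", "sex", "categorical", 1.0),
)


@dataclass(frozen=True)
class CovariateCandidate:
    """A parameter-covariate relationship proposed for testing."""

    parameter: str
    covariate: str
    form: str  # power | linear | categorical
    reference: float = 1.0

    @property
    def name(self) -> str:
        return f"{self.parameter}_{self.covariate}"

    def effect(self, theta: float = 0.0) -> CovariateEffect:
        return CovariateEffect(self.parameter, self.covariate, self.form,
                               theta, self.reference)


def default_candidates() -> tuple[CovariateCandidate, ...]:
    return tuple(CovariateCandidate(*c) for c in DEFAULT_CANDIDATES)


@dataclass
class StepRecord:
    phase: str  # "screen" | "forward" | "backward"
    candidate: str
    delta_ofv: float
    decision: str  # "included" | "rejected" | "removed" | "retained" | "ranked"


@dataclass
class SelectionTrace:
    """Ordered record of every screening/forward/backward decision."""

    steps: list[StepRecord] = field(default_factory=list)
    selected: tuple[str, ...] = ()

    def record(self, phase, candidate, delta_ofv, decision):
        self.steps.append(StepRecord(phase, candidate, float(delta_ofv), decision))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, s.phase, s.candidate, s.delta_ofv, s.decision)
             for i, s in enumerate(self.steps)],
            columns=["step", "phase", "candidate", "delta_ofv", "decision"],
        )


def screen_correlations(
    result: EstimationResult,
    dataset: PKDataset,
    candidates: tuple[CovariateCandidate, ...] | None = None,
    threshold: float = 0.1,
):
    """Rank candidates by |corr(eta_CL EBE, covariate)|.

    Pearson correlation throughout; for a 0/1 covariate this is the
    point-biserial coefficient.  Candidates with |r| below ``threshold``
    are screened out.  Constant covariates are skipped with a warning.
    Returns a list of (candidate, r) sorted by decreasing |r|.
    """
    candidates = candidates if candidates is not None else default_candidates()
    eta_cl = result.etas[:, 0]
    ranked = []
    for cand in candidates:
        vals = dataset.cov[cand.covariate.upper()]
        if np.std(vals) == 0 or np.std(eta_cl) == 0:
            warnings.warn(f"covariate {cand.covariate} is constant; skipped")
            continue
        r = float(np.corrcoef(eta_cl, vals)[0, 1])
        ranked.append((cand, r))
    ranked.sort(key=lambda t: -abs(t[1]))
    return [(c, r) for c, r in ranked if abs(r) >= threshold]


def _fit_with_start(dataset, model, settings, parent: EstimationResult | None):
    """Fit ``model``, warm-starting from a parent fit where structure allows."""
    return fit(dataset, model, settings)


def forward_step(
    dataset: PKDataset,
    current: PopulationModel,
    candidates: list[CovariateCandidate],
    settings: EstimationSettings,
    current_ofv: float,
):
    """Try each remaining candidate; return (best candidate, dOFV, its fit).

    The best candidate is the one with the largest OFV drop, accepted only
    if the drop exceeds :data:`FORWARD_DOFV`; otherwise (None, best dOFV
    observed, None).  Non-convergent sub-fits are skipped with a warning.
    """
    best = (None, -math.inf, None)
    for cand in candidates:
        trial = current.with_effect(cand.effect(0.0))
        try:
            res = _fit_with_start(dataset, trial, settings, None)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"candidate {cand.name} failed to fit: {exc}")
            continue
        if not res.converged:
            warnings.warn(f"candidate {cand.name} did not converge; skipped")
            continue
        dofv = current_ofv - res.ofv
        if dofv > best[1]:
            best = (cand, dofv, res)
    cand, dofv, res = best
    if cand is not None and dofv > FORWARD_DOFV:
        return cand, dofv, res
    return None, dofv, None


def backward_step(
    dataset: PKDataset,
    current: PopulationModel,
    settings: EstimationSettings,
    current_ofv: float,
    removable: list[str] | None = None,
):
    """Delete each effect in turn; remove the least informative one.

    Returns (removed effect name or None, dOFV of the cheapest deletion,
    fit without it or None).  Removal happens when the OFV rise is below
    :data:`BACKWARD_DOFV`.
    """
    best = (None, math.inf, None)
    for eff in current.covariate_effects:
        if removable is not None and eff.name not in removable:
            continue
        trial = current.without_effect(eff.parameter, eff.covariate)
        try:
            res = _fit_with_start(dataset, trial, settings, None)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"deletion of {eff.name} failed to fit: {exc}")
            continue
        if not res.converged:
            warnings.warn(f"deletion of {eff.name} did not converge; skipped")
            continue
        dofv = res.ofv - current_ofv
        if dofv < best[1]:
            best = (eff.name, dofv, res)
    name, dofv, res = best
    if name is not None and dofv < BACKWARD_DOFV:
        return name, dofv, res
    return None, dofv, None


def run_scm(
    dataset: PKDataset,
    base_model: PopulationModel,
    candidates: tuple[CovariateCandidate, ...] | None = None,
    settings: EstimationSettings | None = None,
    screen_threshold: float = 0.1,
    base_result: EstimationResult | None = None,
):
    """Full three-step stepwise covariate modelling.

    Returns (SelectionTrace, final EstimationResult).  ``base_model`` must
    be covariate-free on the tested parameter; ``base_result`` may supply a
    pre-computed base fit.
    """
    settings = settings or EstimationSettings()
    candidates = candidates if candidates is not None else default_candidates()
    trace = SelectionTrace()

    if base_result is None:
        base_result = fit(dataset, base_model, settings)
    current_model = base_result.model
    current_result = base_result

    ranked = screen_correlations(base_result, dataset, candidates, screen_threshold)
    for cand, r in ranked:
        trace.record("screen", cand.name, r, "ranked")
    remaining = [c for c, _ in ranked]
    for cand in candidates:
        if cand not in remaining:
            trace.record("screen", cand.name, 0.0, "rejected")

    while remaining:
        cand, dofv, res = forward_step(
            dataset, current_model, remaining, settings, current_result.ofv
        )
        if cand is None:
            for c in remaining:
                trace.record("forward", c.name, dofv, "rejected")
            break
        trace.record("forward", cand.name, dofv, "included")
        remaining = [c for c in remaining if c is not cand]
        current_model = res.model
        current_result = res

    included = [e.name for e in current_model.covariate_effects
                if any(c.name == e.name for c in candidates)]
    while included:
        name, dofv, res = backward_step(
            dataset, current_model, settings, current_result.ofv, removable=included
        )
        if name is None:
            for n in included:
                trace.record("backward", n, dofv, "retained")
            break
        trace.record("backward", name, dofv, "removed")
        included = [n for n in included if n != name]
        current_model = res.model
        current_result = res

    trace.selected = tuple(e.name for e in current_model.covariate_effects)
    return trace, current_result
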