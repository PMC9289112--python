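"""Shared fixtures: the default synthetic study and its fitted model.

The expensive session fixtures (a 268-subject study and its FOCE-I fit)
are shared across estimation, evaluation and acceptance tests.
"""

import pytest

from litpk.estimation import EstimationSettings, fit
from litpk.model_core import (
    CovariateEffect,
    PopulationModel,
    ResidualModel,
    base_lithium_model,
    final_lithium_model,
)
from litpk.synthetic_data import PopulationSpec, generate_dataset, generate_population

#: canonical seeds of the default synthetic study used across the suite
STUDY_POP_SEED = 1
STUDY_OBS_SEED = 2


def final_model_skeleton():
    """Final-model structure with generic initial values (truth not supplied)."""
    return PopulationModel(
        theta_cl=1.0,
        theta_v=8.0,
        ka=0.293,
        covariate_effects=(
            CovariateEffect("cl", "tdd", "power", 0.1, 600.0),
            CovariateEffect("cl", "wt", "power", 0.1, 62.0),
            CovariateEffect("cl", "crcl", "power", 0.1, 116.0),
        ),
        omega2_cl=0.05,
        omega2_v=0.1,
        residual=ResidualModel("additive", sigma2_add=0.03**2),
    )


@pytest.fixture(scope="session")
def study():
    """Default 268-subject synthetic study (Table-1-like covariates,
    final-model generating parameters)."""
    pop = generate_population(PopulationSpec(), seed=STUDY_POP_SEED)
    return generate_dataset(pop, final_lithium_model(), seed=STUDY_OBS_SEED)


@pytest.fixture(scope="session")
def study_fit(study):
    """FOCE-I fit of the matching skeleton to the default study."""
    return fit(study, final_model_skeleton(), EstimationSettings())


@pytest.fixture(scope="session")
def base_fit(study):
    """Covariate-free base-model fit of the default study (for screening)."""
    return fit(
        study, base_lithium_model(), EstimationSettings(compute_uncertainty=False)
    )


@pytest.fixture(scope="session")
def small_study():
    """A 40-subject study for cheaper fits in unit tests."""
    pop = generate_population(PopulationSpec(n_subjects=40), seed=7)
    return generate_dataset(pop, final_lithium_model(), seed=8)
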