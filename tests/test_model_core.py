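"""Structural model: Cockcroft-Gault, covariate algebra, concentration curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from litpk.model_core import (
    CovariateEffect,
    DosingRegimen,
    IndividualParameters,
    PopulationModel,
    ResidualModel,
    SubjectCovariates,
    apply_covariate_effect,
    cockcroft_gault,
    concentration,
    final_lithium_model,
    individual_parameters,
    steady_state_trough,
    typical_clearance,
)


def _cov(**kw):
    base = dict(weight=62.0, age=40.0, sex="male", serum_creatinine=62.0,
                total_daily_dose=600.0, creatinine_clearance=116.0)
    base.update(kw)
    return SubjectCovariates(**base)


class TestCockcroftGault:
    def test_reference_male(self):
        assert cockcroft_gault(40, 62, 62, "male") == pytest.approx(122.25, abs=0.005)

    def test_female_factor(self):
        male = cockcroft_gault(40, 62, 62, "male")
        assert cockcroft_gault(40, 62, 62, "female") == pytest.approx(0.85 * male)

    def test_zero_numerator_boundary(self):
        assert cockcroft_gault(140, 70, 80, "male") == 0.0

    @pytest.mark.parametrize("bad", [dict(weight=-1), dict(scr=0)])
    def test_invalid_inputs(self, bad):
        kw = dict(age=40, weight=70, scr=80, sex="male")
        kw.update(bad)
        with pytest.raises(ValueError):
            cockcroft_gault(kw["age"], kw["weight"], kw["scr"], kw["sex"])

    def test_vectorised(self):
        out = cockcroft_gault(np.array([40.0, 40.0]), 62.0, 62.0, np.array([1, 0]))
        assert out[1] == pytest.approx(0.85 * out[0])


class TestTypicalClearance:
    def test_reference_covariates_give_theta(self):
        assert typical_clearance(final_lithium_model(), _cov()) == pytest.approx(0.909)

    def test_heavy_patient(self):
        cl = typical_clearance(final_lithium_model(), _cov(weight=100.0))
        assert round(cl, 2) == 1.06

    def test_renal_impairment_percent_drop(self):
        m = final_lithium_model()
        lo = typical_clearance(m, _cov(creatinine_clearance=30.0))
        hi = typical_clearance(m, _cov(creatinine_clearance=120.0))
        assert round(100 * (1 - lo / hi)) == 23

    def test_rejects_nonpositive_covariate(self):
        with pytest.raises(ValueError):
            SubjectCovariates(weight=-5, age=40, sex="male", serum_creatinine=62,
                              total_daily_dose=600)

    def test_effect_order_independent(self):
        m = final_lithium_model()
        perm = PopulationModel(
            theta_cl=m.theta_cl, theta_v=m.theta_v, ka=m.ka,
            covariate_effects=m.covariate_effects[::-1],
            omega2_cl=m.omega2_cl, omega2_v=m.omega2_v, residual=m.residual,
        )
        cov = _cov(weight=80.0, total_daily_dose=900.0, creatinine_clearance=75.0)
        assert typical_clearance(m, cov) == pytest.approx(typical_clearance(perm, cov))


class TestApplyCovariateEffect:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.909, 62.0, 62.0, 0.354, "power"), 0.909),  # identity at reference
            ((0.909, 0.0, 1.0, 0.5, "categorical"), 0.909),  # reference category
            ((0.909, 750.0, 600.0, 0.354, "power"), 0.9837),
            ((2.0, 50.0, 100.0, 0.2, "linear"), 2.0 * 1.1),
        ],
    )
    def test_forms(self, args, expected):
        assert apply_covariate_effect(*args) == pytest.approx(expected, abs=1e-4)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            apply_covariate_effect(1.0, 1.0, 1.0, 0.1, "exponential")


class TestIndividualParameters:
    def test_reference_subject(self):
        ind = individual_parameters(final_lithium_model(), _cov())
        assert ind.cl == pytest.approx(0.909)
        assert ind.v == pytest.approx(10.9)
        assert ind.ka == pytest.approx(0.293)

    def test_eta_doubles_clearance(self):
        m = final_lithium_model()
        ind = individual_parameters(m, _cov(), eta_cl=math.log(2.0))
        assert ind.cl == pytest.approx(2 * 0.909)

    def test_bsv_magnitude_monte_carlo(self):
        m = final_lithium_model()
        rng = np.random.default_rng(3)
        etas = rng.normal(0, math.sqrt(0.027), size=20000)
        cls = [individual_parameters(m, _cov(), eta_cl=e).cl for e in etas[:2000]]
        sd_log = np.std(np.log(np.array(cls) / 0.909))
        assert sd_log == pytest.approx(0.164, abs=0.01)


@st.composite
def pk_instances(draw):
    cl = draw(st.floats(0.2, 3.0))
    v = draw(st.floats(5.0, 30.0))
    ka = draw(st.floats(0.1, 1.5))
    dose = draw(st.floats(100.0, 800.0))
    tau = draw(st.floats(6.0, 24.0))
    n_doses = draw(st.integers(1, 6))
    t = draw(st.floats(0.5, 1.0)) * n_doses * tau
    return cl, v, ka, dose, tau, n_doses, t


class TestConcentration:
    def test_zero_before_first_dose(self):
        ind = IndividualParameters(cl=0.9, v=10.9, ka=0.293)
        assert concentration(DosingRegimen(300, 12), ind, 0.0) == 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(pk_instances())
    def test_matches_ode_oracle(self, inst):
        cl, v, ka, dose, tau, n_doses, t = inst
        ind = IndividualParameters(cl=cl, v=v, ka=ka)
        reg = DosingRegimen(dose, tau, n_doses)
        ours = concentration(reg, ind, t)
        oracle = helpers.ode_concentration(
            dose, [k * tau for k in range(n_doses)], cl, v, ka, t
        )
        assert ours == pytest.approx(oracle, rel=1e-6, abs=1e-12)

    def test_flip_flop_limit_is_continuous(self):
        v, ka = 10.9, 0.293
        reg = DosingRegimen(375, 12, 3)
        exact_limit = concentration(reg, IndividualParameters(cl=ka * v, v=v, ka=ka), 30.0)
        nearby = concentration(
            reg, IndividualParameters(cl=ka * v * (1 + 1e-7), v=v, ka=ka), 30.0
        )
        assert exact_limit == pytest.approx(nearby, rel=1e-5)

    def test_superposition_reaches_steady_state(self):
        ind = individual_parameters(final_lithium_model(), _cov())
        reg_inf = DosingRegimen(300, 12)
        # >= 10 half-lives of repeated dosing (t_half ~ 8.3 h)
        n = 20
        finite = concentration(DosingRegimen(300, 12, n), ind, n * 12.0)
        ss = steady_state_trough(reg_inf, ind)
        assert abs(finite - ss) / ss < 1e-3


class TestSteadyStateTrough:
    def test_printed_example(self):
        m = final_lithium_model()
        cov = _cov(weight=100.0, total_daily_dose=750.0, creatinine_clearance=120.0)
        ind = individual_parameters(m, cov)
        assert steady_state_trough(DosingRegimen(375, 12), ind) == pytest.approx(
            0.521, abs=5e-4
        )

    def test_washout_limit(self):
        # as clearance grows the trough vanishes like 1/CL (absorption-limited)
        t1 = steady_state_trough(DosingRegimen(300, 12),
                                 IndividualParameters(cl=500.0, v=10.0, ka=0.293))
        t2 = steady_state_trough(DosingRegimen(300, 12),
                                 IndividualParameters(cl=5000.0, v=10.0, ka=0.293))
        assert t1 < 1e-3
        assert t2 < t1 / 9

    def test_monotone_decreasing_in_clearance(self):
        troughs = [
            steady_state_trough(
                DosingRegimen(300, 12), IndividualParameters(cl=cl, v=10.9, ka=0.293)
            )
            for cl in np.linspace(0.3, 3.0, 10)
        ]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))

    def test_trough_sublinear_in_daily_dose(self):
        # TDD exponent 0.354 < 1 on CL: doubling the dose less than doubles
        # the trough, but still increases it
        m = final_lithium_model()
        doses = np.array([300.0, 600.0, 1200.0])
        troughs = []
        for dd in doses:
            cov = _cov(total_daily_dose=dd)
            ind = individual_parameters(m, cov)
            troughs.append(steady_state_trough(DosingRegimen(dd / 2, 12), ind))
        assert troughs[0] < troughs[1] < troughs[2]
        assert troughs[1] / troughs[0] < 2.0
        assert troughs[2] / troughs[1] < 2.0


class TestDomainTypes:
    def test_crcl_derived_when_absent(self):
        cov = SubjectCovariates(weight=62, age=40, sex="male", serum_creatinine=62,
                                total_daily_dose=600)
        assert cov.creatinine_clearance == pytest.approx(122.25, abs=0.005)

    def test_residual_model_consistency(self):
        with pytest.raises(ValueError):
            ResidualModel("additive", sigma2_add=0.01, sigma2_prop=0.02)
        with pytest.raises(ValueError):
            ResidualModel("combined", sigma2_add=-1.0)

    def test_regimen_daily_dose(self):
        assert DosingRegimen(375, 12).daily_dose_mg == pytest.approx(750.0)

    def test_duplicate_effect_rejected(self):
        m = final_lithium_model()
        with pytest.raises(ValueError):
            m.with_effect(CovariateEffect("cl", "tdd", "power", 0.1, 600.0))
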