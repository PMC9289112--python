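"""FOCE-I estimation: inner problem, objective, diagnostics, uncertainty."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares, minimize_scalar

import helpers
from litpk.estimation import (
    EstimationSettings,
    PKDataset,
    conditional_etas,
    cwres,
    fit,
    foce_objective,
    shrinkage,
    standard_errors,
)
from litpk.model_core import (
    PopulationModel,
    ResidualModel,
    final_lithium_model,
)
from litpk.synthetic_data import (
    PopulationSpec,
    StudyDesign,
    generate_dataset,
    generate_population,
)
from conftest import final_model_skeleton

FAST = EstimationSettings(compute_uncertainty=False)


def _toy_frame(dv_rows, dose_mg=300.0, tau=12.0, n_doses=20, **cov):
    """One-subject frame with regular q12h dosing and given (time, DV) rows."""
    base = dict(ID=1, WT=62.0, AGE=40.0, SEX=1, SCR=62.0, CRCL=116.0,
                TDD=2 * dose_mg, FORM=1)
    base.update(cov)
    rows = []
    for k in range(n_doses):
        rows.append({**base, "TIME": k * tau, "EVID": 1, "AMT": dose_mg,
                     "DV": np.nan, "MDV": 1, "BLQ": 0})
    for t, dv in dv_rows:
        rows.append({**base, "TIME": t, "EVID": 0, "AMT": np.nan,
                     "DV": dv, "MDV": 0, "BLQ": 0})
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    return frame.reset_index(drop=True)


class TestPKDatasetValidation:
    def test_observation_before_any_dose_rejected(self):
        frame = _toy_frame([(5.0, 0.5)])
        frame.loc[frame["EVID"] == 0, "TIME"] = -1.0
        with pytest.raises(ValueError):
            PKDataset(frame)

    def test_decreasing_times_rejected(self):
        frame = _toy_frame([(100.0, 0.5)])
        frame.loc[3, "TIME"] = 1000.0
        with pytest.raises(ValueError):
            PKDataset(frame.reset_index(drop=True))

    def test_nonpositive_unflagged_dv_rejected(self):
        with pytest.raises(ValueError):
            PKDataset(_toy_frame([(100.0, -0.2)]))

    def test_blq_fraction_and_counts(self, study):
        assert study.n_subjects == 268
        assert study.blq_fraction < 0.10


class TestConditionalEtas:
    def test_single_observation_matches_grid_oracle(self):
        model = replace(final_lithium_model(), omega2_v=0.0)
        ds = PKDataset(_toy_frame([(20 * 12.0, 0.61)]))
        etas, hess = conditional_etas(ds, model)

        cov = ds.subject_covariates()[0]
        cl_typ = model.typical_value("cl", cov)
        v = model.typical_value("v", cov)
        sig2 = model.residual.sigma2_add
        dose_times = [k * 12.0 for k in range(20)]

        def deviance(eta):
            f = helpers.explicit_superposition(300.0, dose_times, cl_typ * math.exp(eta),
                                               v, model.ka, 240.0)
            return (0.61 - f) ** 2 / sig2 + math.log(sig2) + eta**2 / model.omega2_cl

        r = minimize_scalar(deviance, bounds=(-2, 2), method="bounded",
                            options={"xatol": 1e-10})
        assert etas[0, 0] == pytest.approx(r.x, abs=1e-6)
        assert hess[0, 0, 0] > 0

    def test_symmetric_data_gives_near_zero_eta(self):
        model = replace(final_lithium_model(), omega2_v=0.0)
        # observation exactly at the typical prediction -> eta* ~ 0
        ds0 = PKDataset(_toy_frame([(20 * 12.0, 0.5)]))
        covs = ds0.subject_covariates()[0]
        typical = helpers.explicit_superposition(
            300.0, [k * 12.0 for k in range(20)],
            model.typical_value("cl", covs), model.typical_value("v", covs),
            model.ka, 240.0,
        )
        ds = PKDataset(_toy_frame([(20 * 12.0, typical)]))
        etas, _ = conditional_etas(ds, model)
        assert abs(etas[0, 0]) < 1e-6

    def test_small_omega_shrinks_eta_toward_zero(self):
        ds = PKDataset(_toy_frame([(20 * 12.0, 0.61)]))
        big = replace(final_lithium_model(), omega2_v=0.0, omega2_cl=0.1)
        tiny = replace(final_lithium_model(), omega2_v=0.0, omega2_cl=1e-6)
        eta_big, _ = conditional_etas(ds, big)
        eta_tiny, _ = conditional_etas(ds, tiny)
        assert abs(eta_tiny[0, 0]) < 1e-2 * abs(eta_big[0, 0])


class TestFoceObjective:
    def test_no_random_effects_reduces_to_gaussian_m2ll(self):
        model = replace(final_lithium_model(), omega2_cl=0.0, omega2_v=0.0)
        pop = generate_population(PopulationSpec(n_subjects=12), seed=21)
        ds = generate_dataset(pop, model, seed=22)
        ofv = foce_objective(ds, model)

        covs = ds.subject_covariates()
        sig2 = model.residual.sigma2_add
        expected = 0.0
        amt, tau, m, s = ds.sched
        for j, y in enumerate(ds.y):
            i = ds.obs_subject[j]
            cl = model.typical_value("cl", covs[i])
            v = model.typical_value("v", covs[i])
            dose_times = [s[j] + k * tau[j] for k in range(int(m[j]))]
            # explicit per-dose sum evaluated directly at time-since-dose grid
            f = sum(
                amt[j] * helpers.MMOL_PER_MG * model.ka
                / (v * (model.ka - cl / v))
                * (math.exp(-(cl / v) * td) - math.exp(-model.ka * td))
                for td in dose_times
            )
            expected += (y - f) ** 2 / sig2 + math.log(sig2) + math.log(2 * math.pi)
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_matches_quadrature_oracle_and_gap_monotone_in_omega(self):
        pop = generate_population(PopulationSpec(n_subjects=5), seed=11)
        gaps = []
        for om_sd in (0.05, 0.02, 0.01):
            model = replace(final_lithium_model(), omega2_cl=om_sd**2, omega2_v=0.0)
            ds = generate_dataset(pop, model, seed=12)
            gap = abs(foce_objective(ds, model) - helpers.agq_minus2loglik(ds, model))
            gaps.append(gap)
        assert gaps[0] < 0.1
        assert gaps[0] > gaps[1] > gaps[2]

    def test_duplicating_subjects_doubles_ofv(self, small_study):
        model = final_lithium_model()
        single = foce_objective(small_study, model)
        doubled_frame = []
        n = small_study.frame["ID"].max()
        for shift in (0, n):
            block = small_study.frame.copy()
            block["ID"] = block["ID"] + shift
            doubled_frame.append(block)
        doubled = PKDataset(pd.concat(doubled_frame, ignore_index=True))
        assert foce_objective(doubled, model) == pytest.approx(2 * single, rel=1e-9)


class TestFit:
    def test_deterministic_ofv_bit_for_bit(self, small_study):
        r1 = fit(small_study, final_model_skeleton(), FAST)
        r2 = fit(small_study, final_model_skeleton(), FAST)
        assert r1.ofv == r2.ofv
        assert np.array_equal(r1.etas, r2.etas)

    def test_degenerate_fit_equals_weighted_least_squares(self, small_study):
        # omega = 0: FOCE-I collapses to (iteratively profiled) least squares
        skel = PopulationModel(
            theta_cl=1.0, theta_v=8.0, ka=0.293,
            omega2_cl=0.0, omega2_v=0.0,
            residual=ResidualModel("additive", sigma2_add=0.05**2),
        )
        res = fit(small_study, skel, FAST)

        covs = small_study.subject_covariates()
        amt, tau, m, s = small_study.sched
        keep = ~small_study.blq
        y = small_study.y[keep]

        def resid(x):
            cl, v = math.exp(x[0]), math.exp(x[1])
            out = []
            for j in np.flatnonzero(keep):
                ke = cl / v
                f = sum(
                    amt[j] * helpers.MMOL_PER_MG * 0.293 / (v * (0.293 - ke))
                    * (math.exp(-ke * (s[j] + k * tau[j]))
                       - math.exp(-0.293 * (s[j] + k * tau[j])))
                    for k in range(int(m[j]))
                )
                out.append(small_study.y[j] - f)
            return np.array(out)

        # trough-only data leaves a flat CL-V ridge, so compare the attained
        # objective rather than the (non-unique) coordinates
        best_ls = min(
            0.5 * np.sum(
                least_squares(resid, x0=[c0, v0], xtol=1e-14, ftol=1e-14).fun ** 2
            )
            for c0 in (-0.2, 0.0, 0.2)
            for v0 in (math.log(5.0), math.log(8.0), math.log(15.0))
        )
        ssr_fit = float(np.sum(resid([
            math.log(res.model.theta_cl), math.log(res.model.theta_v)
        ]) ** 2))
        assert ssr_fit <= 2 * best_ls * (1 + 1e-6)
        # profiled additive variance equals SSR / n
        n = len(y)
        assert res.model.residual.sigma2_add == pytest.approx(ssr_fit / n, rel=1e-4)
        assert res.ofv == pytest.approx(
            n * math.log(ssr_fit / n) + n + n * math.log(2 * math.pi), rel=1e-6
        )

    def test_recovers_generating_parameters(self, study_fit):
        m = study_fit.model
        assert study_fit.converged
        assert m.theta_cl == pytest.approx(0.909, rel=0.10)
        assert 6.0 < m.theta_v < 20.0
        assert m.residual.sigma_add == pytest.approx(0.0218, rel=0.25)


class TestShrinkageAndResiduals:
    def test_sparser_design_has_higher_eta_shrinkage(self):
        model = final_lithium_model()
        pop = generate_population(PopulationSpec(n_subjects=60), seed=31)
        rich = generate_dataset(pop, model, StudyDesign(p_two_obs=1.0), seed=32)
        sparse = generate_dataset(pop, model, StudyDesign(p_two_obs=0.0), seed=32)
        shr_rich, _ = shrinkage(rich, model)
        shr_sparse, _ = shrinkage(sparse, model)
        assert shr_sparse["cl"] > shr_rich["cl"]

    def test_cwres_reduces_to_wres_without_random_effects(self):
        model = replace(final_lithium_model(), omega2_cl=0.0, omega2_v=0.0)
        pop = generate_population(PopulationSpec(n_subjects=15), seed=41)
        ds = generate_dataset(pop, model, seed=42)
        cw = cwres(ds, model)
        etas, _ = conditional_etas(ds, model)
        # PRED from a zero-eta evaluation; residual scaled by sigma
        from litpk.estimation import _Problem

        prob = _Problem(ds, model, EstimationSettings())
        p = prob.spec.unpack(prob.spec.pack(model))
        cl_typ, v_typ = prob.typical_params(p)
        pred = prob.predict(cl_typ, v_typ)
        manual = (prob.y - pred) / math.sqrt(model.residual.sigma2_add)
        np.testing.assert_allclose(cw, manual, rtol=1e-9)

    def test_cwres_calibrated_on_self_simulated_study(self, study_fit):
        cw = study_fit.cwres
        assert -0.1 < cw.mean() < 0.1
        assert 0.9 < cw.std() < 1.1
        assert np.mean(np.abs(cw) <= 2.0) >= 0.90

    def test_shrinkage_bounds(self, study_fit):
        for v in study_fit.eta_shrinkage.values():
            assert 0.0 <= v <= 100.0


class TestStandardErrors:
    def test_se_matches_fisher_information_oracle(self):
        # omega = 0, additive error, no covariates, and a rich two-timepoint
        # design (2 h and 12 h post dose) so CL and V are separately
        # identified: the inverse-Hessian SE of log CL must match the
        # expected-information (J' J / sigma^2) oracle built from
        # prediction sensitivities
        model = replace(final_lithium_model(), omega2_cl=0.0, omega2_v=0.0,
                        covariate_effects=())
        rng = np.random.default_rng(53)
        sigma = 0.0218
        dose_times = [k * 12.0 for k in range(20)]
        blocks = []
        for sid in range(1, 31):
            dvs = []
            for tad in (2.0, 12.0):
                t = 19 * 12.0 + tad
                f = helpers.explicit_superposition(300.0, dose_times, 0.909, 10.9,
                                                   0.293, t)
                dvs.append((t, f + rng.normal(0, sigma)))
            block = _toy_frame(dvs)
            block["ID"] = sid
            blocks.append(block)
        ds = PKDataset(pd.concat(blocks, ignore_index=True))

        rse, cov, cond = standard_errors(ds, model)
        se_logcl = rse["theta_cl"] / 100.0

        from litpk.estimation import _Problem

        prob = _Problem(ds, model, EstimationSettings())
        p = prob.spec.unpack(prob.spec.pack(model))
        cl_typ, v_typ = prob.typical_params(p)
        h = 1e-6
        dfdx = (prob.predict(cl_typ * math.exp(h), v_typ)
                - prob.predict(cl_typ * math.exp(-h), v_typ)) / (2 * h)
        dfdv = (prob.predict(cl_typ, v_typ * math.exp(h))
                - prob.predict(cl_typ, v_typ * math.exp(-h))) / (2 * h)
        J = np.stack([dfdx, dfdv], axis=1)
        info = J.T @ J / model.residual.sigma2_add  # sigma2 orthogonal to means
        se_oracle = math.sqrt(np.linalg.inv(info)[0, 0])
        assert se_logcl == pytest.approx(se_oracle, rel=0.10)

    def test_duplicating_data_shrinks_se_by_sqrt2(self, small_study):
        model = final_lithium_model()
        rse1, _, _ = standard_errors(small_study, model)
        blocks = []
        n = small_study.frame["ID"].max()
        for shift in (0, n):
            b = small_study.frame.copy()
            b["ID"] = b["ID"] + shift
            blocks.append(b)
        doubled = PKDataset(pd.concat(blocks, ignore_index=True))
        rse2, _, _ = standard_errors(doubled, model)
        assert rse2["theta_cl"] == pytest.approx(rse1["theta_cl"] / math.sqrt(2), rel=0.05)

    def test_condition_number_at_least_one(self, study_fit):
        assert study_fit.condition_number >= 1.0


class TestBLQPolicy:
    def test_excessive_blq_fraction_rejected(self):
        model = final_lithium_model()
        pop = generate_population(PopulationSpec(n_subjects=20), seed=61)
        ds = generate_dataset(pop, model, seed=62)
        frame = ds.frame.copy()
        obs = frame["EVID"] == 0
        frame.loc[obs, "BLQ"] = 1  # flag everything
        bad = PKDataset(frame)
        with pytest.raises(ValueError, match="LLOQ"):
            foce_objective(bad, model)
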