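"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
closed-form prediction or FOCE code paths: concentrations come from
numerical ODE integration or explicit per-dose loops, and marginal
likelihoods from adaptive Gauss-Hermite quadrature.
"""

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar
from numpy.polynomial.hermite import hermgauss

MMOL_PER_MG = 0.0270662


def ode_concentration(dose_mg_each, dose_times, cl, v, ka, t_eval):
    """Concentration (mmol/L) by integrating the gut/central ODE system.

    Doses (mg lithium carbonate) enter the gut compartment as boluses at
    ``dose_times``; the central compartment eliminates at ke = cl/v.
    """
    ke = cl / v
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    events = sorted(set(float(td) for td in dose_times))
    out = np.zeros(len(t_eval))
    state = np.array([0.0, 0.0])  # gut, central (mmol)
    t_now = 0.0
    checkpoints = sorted(set(events) | set(t_eval.tolist()))

    def rhs(t, yv):
        return [-ka * yv[0], ka * yv[0] - ke * yv[1]]

    for tc in checkpoints:
        if tc > t_now:
            sol = solve_ivp(rhs, (t_now, tc), state, rtol=1e-11, atol=1e-13,
                            dense_output=False)
            state = sol.y[:, -1]
            t_now = tc
        if tc in events:
            state = state + np.array([dose_mg_each * MMOL_PER_MG, 0.0])
        for i, te in enumerate(t_eval):
            if math.isclose(te, tc, abs_tol=1e-12):
                out[i] = state[1] / v
    return out if len(out) > 1 else float(out[0])


def explicit_superposition(dose_mg_each, dose_times, cl, v, ka, t):
    """Per-dose closed-form sum written as an explicit Python loop."""
    ke = cl / v
    c = 0.0
    for td in dose_times:
        if td >= t:
            continue
        dt = t - td
        c += (dose_mg_each * MMOL_PER_MG * ka / (v * (ka - ke))
              * (math.exp(-ke * dt) - math.exp(-ka * dt)))
    return c


def agq_minus2loglik(dataset, model, n_nodes=32):
    """-2 log marginal likelihood by 1-D adaptive Gauss-Hermite quadrature.

    Valid for models with a single random effect (eta on CL, omega2_v = 0)
    and additive residual error; predictions use the explicit per-dose loop
    above, independent of the package's vectorised predictor.
    """
    assert model.omega2_v == 0.0 and model.residual.form == "additive"
    z, wq = hermgauss(n_nodes)
    sig2 = model.residual.sigma2_add
    om2 = model.omega2_cl
    covs = dataset.subject_covariates()
    total = 0.0
    frame = dataset.frame
    for i, sid in enumerate(dataset.subject_ids):
        block = frame[frame["ID"] == sid]
        dose_rows = block[block["EVID"] == 1]
        dose_times = dose_rows["TIME"].to_numpy(dtype=float)
        dose_amt = float(dose_rows["AMT"].iloc[0])
        obs = block[(block["EVID"] == 0) & (block["MDV"] == 0) & (block["BLQ"] == 0)]
        y = obs["DV"].to_numpy(dtype=float)
        t_obs = obs["TIME"].to_numpy(dtype=float)
        cl_typ = model.typical_value("cl", covs[i])
        v = model.typical_value("v", covs[i])

        def neg_log_integrand(eta):
            cl = cl_typ * math.exp(eta)
            ll = 0.0
            for yy, tt in zip(y, t_obs):
                f = explicit_superposition(dose_amt, dose_times, cl, v, model.ka, tt)
                ll += -0.5 * ((yy - f) ** 2 / sig2 + math.log(2 * math.pi * sig2))
            lp = -0.5 * (eta**2 / om2 + math.log(2 * math.pi * om2))
            return -(ll + lp)

        r = minimize_scalar(neg_log_integrand, bounds=(-2, 2), method="bounded",
                            options={"xatol": 1e-12})
        mode = r.x
        h = 1e-4
        curv = (neg_log_integrand(mode + h) - 2 * neg_log_integrand(mode)
                + neg_log_integrand(mode - h)) / h**2
        scale = math.sqrt(2.0 / curv)
        vals = np.array([neg_log_integrand(mode + scale * zi) for zi in z])
        logterms = np.log(wq) + z**2 - vals
        mx = logterms.max()
        integral = math.exp(mx) * np.sum(np.exp(logterms - mx)) * scale
        total += -2.0 * math.log(integral)
    return total
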