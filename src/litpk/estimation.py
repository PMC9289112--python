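"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's trough concentrations is
approximated by linearising the structural model about the subject's
conditional (empirical Bayes) random-effect estimate eta*:

    OFV = sum_i [ log|V_i| + r_i' V_i^-1 r_i + n_i log 2 pi ]

with G_i = df/deta at eta*_i, V_i = G_i Omega G_i' + Sigma_i(eta*_i),
r_i = y_i - f_i(eta*_i) + G_i eta*_i, and the residual variance Sigma
evaluated at eta*_i (the "interaction"; with a purely additive residual
Sigma is constant and FOCE-I coincides with FOCE).

eta*_i minimises the penalised conditional deviance

    sum_j [ (y_j - f_j(eta))^2 / sigma_j^2(eta) + log sigma_j^2(eta) ]
    + eta' Omega^-1 eta

solved here by a damped Gauss-Newton iteration vectorised across subjects.
Fixed effects and variances are optimised on the log scale (covariate
coefficients untransformed) with a quasi-Newton outer optimiser and
finite-difference gradients, so a fit is deterministic given the data and
settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import (
    MMOL_PER_MG,
    PopulationModel,
    SubjectCovariates,
    _conc_profile,
)

__all__ = [
    "PKDataset",
    "EstimationSettings",
    "EstimationResult",
    "fit",
    "foce_objective",
    "conditional_etas",
    "cwres",
    "shrinkage",
    "standard_errors",
    "DIALECT_COLUMNS",
]

DIALECT_COLUMNS = (
    "ID", "TIME", "EVID", "AMT", "DV", "MDV", "BLQ",
    "WT", "AGE", "SEX", "SCR", "CRCL", "TDD", "FORM",
)

_COV_COLUMNS = ("WT", "AGE", "SEX", "SCR", "CRCL", "TDD", "FORM")

#: maximum tolerated fraction of below-LLOQ samples (they are then ignored)
BLQ_MAX_FRACTION = 0.10


class PKDataset:
    """A rectangular dosing/observation dataset with per-subject covariates.

    Rows follow the conventional pharmacometric dialect: ``EVID`` 1 marks a
    dose (``AMT`` mg lithium carbonate), ``EVID`` 0 an observation (``DV``
    mmol/L), ``MDV`` 1 a missing observation, ``BLQ`` 1 a sample below the
    assay's lower limit of quantification.  Covariates are constant within
    subject.  Subject blocks must be contiguous and time-sorted.
    """

    def __init__(self, frame: pd.DataFrame, lloq: float = 0.19):
        missing = [c for c in DIALECT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        frame = frame.loc[:, list(DIALECT_COLUMNS)].reset_index(drop=True)
        self.frame = frame
        self.lloq = float(lloq)
        self._validate()
        self._build_design()

    # -- construction ---------------------------------------------------
    def _validate(self):
        f = self.frame
        if len(f) == 0:
            raise ValueError("empty dataset")
        ids = f["ID"].to_numpy()
        first_pos = {}
        for pos, sid in enumerate(ids):
            if sid in first_pos and ids[pos - 1] != sid:
                raise ValueError(f"subject {sid} rows are not contiguous")
            first_pos.setdefault(sid, pos)
        if np.any(f["TIME"].to_numpy() < 0):
            raise ValueError("negative times")
        for sid, block in f.groupby("ID", sort=False):
            t = block["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times decrease within subject {sid}")
            evid = block["EVID"].to_numpy()
            obs = np.flatnonzero((evid == 0) & (block["MDV"].to_numpy() == 0))
            doses = np.flatnonzero(evid == 1)
            if len(obs) and (len(doses) == 0 or t[doses[0]] > t[obs[0]]):
                raise ValueError(f"subject {sid} has an observation before any dose")
            dv = block["DV"].to_numpy(dtype=float)
            bad = obs[(~(dv[obs] > 0)) & (block["BLQ"].to_numpy()[obs] == 0)]
            if len(bad):
                raise ValueError(f"non-positive unflagged DV for subject {sid}")

    def _build_design(self):
        f = self.frame
        self.subject_ids = pd.unique(f["ID"])
        self.n_subjects = len(self.subject_ids)
        sid_to_idx = {sid: i for i, sid in enumerate(self.subject_ids)}

        cov_rows = f.groupby("ID", sort=False).first().reset_index()
        self.cov_frame = cov_rows[["ID", *list(_COV_COLUMNS)]]
        self.cov = {c: self.cov_frame[c].to_numpy(dtype=float) for c in _COV_COLUMNS}

        obs_mask = (f["EVID"] == 0) & (f["MDV"] == 0)
        self.obs = f.loc[obs_mask]
        self.obs_index = self.obs.index.to_numpy()
        self.y = self.obs["DV"].to_numpy(dtype=float)
        self.obs_subject = np.array([sid_to_idx[s] for s in self.obs["ID"]], dtype=int)
        self.blq = self.obs["BLQ"].to_numpy(dtype=int) > 0

        # per-observation dosing schedule; fast path when each subject's
        # dosing is a uniform amount/interval sequence (geometric closed form)
        amt = np.empty(len(self.y))
        tau = np.empty(len(self.y))
        mdoses = np.empty(len(self.y))
        slast = np.empty(len(self.y))
        regular = True
        pairs_amt, pairs_dt, pairs_obs = [], [], []
        obs_positions = np.flatnonzero(obs_mask.to_numpy())
        times = f["TIME"].to_numpy(dtype=float)
        evid = f["EVID"].to_numpy()
        amts = f["AMT"].to_numpy(dtype=float)
        start = 0
        obs_ptr = 0
        for sid in self.subject_ids:
            stop = start
            while stop < len(f) and f["ID"].iat[stop] == sid:
                stop += 1
            didx = [i for i in range(start, stop) if evid[i] == 1]
            dt_times = times[didx]
            dt_amts = amts[didx]
            sub_regular = (
                len(didx) > 0
                and np.allclose(dt_amts, dt_amts[0], rtol=1e-9, atol=1e-9)
                and (
                    len(didx) == 1
                    or np.allclose(np.diff(dt_times), dt_times[1] - dt_times[0],
                                   rtol=1e-9, atol=1e-9)
                )
            )
            for i in range(start, stop):
                if not (evid[i] == 0 and f["MDV"].iat[i] == 0):
                    continue
                before = dt_times < times[i] - 1e-12
                m = int(before.sum())
                if m == 0:
                    raise ValueError(f"observation before first dose, subject {sid}")
                if sub_regular:
                    amt[obs_ptr] = dt_amts[0]
                    tau[obs_ptr] = dt_times[1] - dt_times[0] if len(didx) > 1 else 1.0
                    mdoses[obs_ptr] = m
                    slast[obs_ptr] = times[i] - dt_times[m - 1]
                else:
                    regular = False
                pairs_amt.append(dt_amts[before])
                pairs_dt.append(times[i] - dt_times[before])
                pairs_obs.append(np.full(m, obs_ptr))
                obs_ptr += 1
            if not sub_regular:
                regular = False
            start = stop
        self.regular = regular
        if regular:
            self.sched = (amt, tau, mdoses, slast)
        self.pairs = (
            np.concatenate(pairs_amt) if pairs_amt else np.array([]),
            np.concatenate(pairs_dt) if pairs_dt else np.array([]),
            np.concatenate(pairs_obs).astype(int) if pairs_obs else np.array([], int),
        )

    # -- views ----------------------------------------------------------
    @property
    def n_observations(self) -> int:
        return len(self.y)

    @property
    def blq_fraction(self) -> float:
        return float(self.blq.mean()) if len(self.y) else 0.0

    def subject_covariates(self) -> list[SubjectCovariates]:
        out = []
        for row in self.cov_frame.itertuples():
            out.append(
                SubjectCovariates(
                    weight=row.WT, age=row.AGE,
                    sex="male" if row.SEX == 1 else "female",
                    serum_creatinine=row.SCR, total_daily_dose=row.TDD,
                    creatinine_clearance=row.CRCL,
                    dosage_form="sustained_release" if row.FORM == 1 else "ordinary",
                )
            )
        return out

    def resample_subjects(self, rng: np.random.Generator) -> "PKDataset":
        """Nonparametric bootstrap replicate: subjects drawn with replacement."""
        picks = rng.integers(0, self.n_subjects, size=self.n_subjects)
        blocks = []
        for new_id, k in enumerate(picks, start=1):
            sid = self.subject_ids[k]
            block = self.frame[self.frame["ID"] == sid].copy()
            block["ID"] = new_id
            blocks.append(block)
        return PKDataset(pd.concat(blocks, ignore_index=True), lloq=self.lloq)


@dataclass(frozen=True)
class EstimationSettings:
    """Optimiser controls; defaults give a deterministic, reasonably tight fit."""

    inner_tol: float = 1e-10  # absolute tolerance on the penalised deviance
    inner_max_iter: int = 60
    outer_tol: float = 1e-8  # L-BFGS-B ftol (relative OFV change)
    outer_gtol: float = 1e-4
    outer_max_iter: int = 500
    fd_rel_step: float = 3e-5  # outer finite-difference gradient step
    hessian_rel_step: float = 5e-3  # standard-error Hessian step
    eta_fd_step: float = 1e-4  # step for df/deta central differences
    compute_uncertainty: bool = True
    seed: int | None = None


# ---------------------------------------------------------------------------
# parameter packing


class _ParamSpec:
    """Maps between a PopulationModel and the transformed outer vector."""

    def __init__(self, skeleton: PopulationModel):
        self.skeleton = skeleton
        self.names: list[str] = ["theta_cl", "theta_v"]
        self.effects = skeleton.covariate_effects
        for e in self.effects:
            self.names.append(f"beta_{e.name}")
        self.est_omega_cl = skeleton.omega2_cl > 0
        self.est_omega_v = skeleton.omega2_v > 0
        if self.est_omega_cl:
            self.names.append("omega2_cl")
        if self.est_omega_v:
            self.names.append("omega2_v")
        # a variance of exactly 0 in the skeleton is structurally absent
        form = skeleton.residual.form
        self.est_sig_add = (form in ("additive", "combined")
                            and skeleton.residual.sigma2_add > 0)
        self.est_sig_prop = (form in ("proportional", "combined")
                             and skeleton.residual.sigma2_prop > 0)
        if self.est_sig_add:
            self.names.append("sigma2_add")
        if self.est_sig_prop:
            self.names.append("sigma2_prop")
        self.n = len(self.names)

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = [math.log(model.theta_cl), math.log(model.theta_v)]
        for e in model.covariate_effects:
            x.append(e.theta)
        if self.est_omega_cl:
            x.append(math.log(model.omega2_cl))
        if self.est_omega_v:
            x.append(math.log(model.omega2_v))
        if self.est_sig_add:
            x.append(math.log(model.residual.sigma2_add))
        if self.est_sig_prop:
            x.append(math.log(model.residual.sigma2_prop))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> dict:
        i = 0
        p = {"theta_cl": math.exp(x[0]), "theta_v": math.exp(x[1])}
        i = 2
        betas = []
        for e in self.effects:
            p[f"beta_{e.name}"] = x[i]
            betas.append(x[i])
            i += 1
        p["_betas"] = np.array(betas)
        # floor guards exp() underflow during extreme optimizer excursions
        p["omega2_cl"] = (max(math.exp(x[i]), 1e-290) if self.est_omega_cl
                          else self.skeleton.omega2_cl)
        i += self.est_omega_cl
        p["omega2_v"] = (max(math.exp(x[i]), 1e-290) if self.est_omega_v
                         else self.skeleton.omega2_v)
        i += self.est_omega_v
        p["sigma2_add"] = (math.exp(x[i]) if self.est_sig_add
                           else self.skeleton.residual.sigma2_add)
        i += self.est_sig_add
        p["sigma2_prop"] = (math.exp(x[i]) if self.est_sig_prop
                            else self.skeleton.residual.sigma2_prop)
        return p

    def to_model(self, p: dict) -> PopulationModel:
        effects = tuple(
            replace(e, theta=p[f"beta_{e.name}"]) for e in self.effects
        )
        residual = replace(
            self.skeleton.residual,
            sigma2_add=p["sigma2_add"] if self.est_sig_add else self.skeleton.residual.sigma2_add,
            sigma2_prop=p["sigma2_prop"] if self.est_sig_prop else self.skeleton.residual.sigma2_prop,
        )
        return replace(
            self.skeleton,
            theta_cl=p["theta_cl"],
            theta_v=p["theta_v"],
            covariate_effects=effects,
            omega2_cl=p["omega2_cl"],
            omega2_v=p["omega2_v"],
            residual=residual,
        )

    def report_scale(self, names_x: Sequence[str], x: np.ndarray, se_x: np.ndarray):
        """Natural-scale estimates and RSE% by the delta method."""
        est, rse = {}, {}
        for name, xi, sei in zip(names_x, x, se_x):
            if name.startswith("beta_"):
                est[name] = xi
                rse[name] = 100.0 * sei / abs(xi) if xi != 0 else math.inf
            elif name.startswith("omega2"):
                # reported as %BSV = 100 sqrt(omega2)
                key = name.replace("omega2", "bsv") + "_percent"
                est[key] = 100.0 * math.sqrt(math.exp(xi))
                rse[key] = 100.0 * sei / 2.0
            elif name.startswith("sigma2"):
                key = name.replace("sigma2", "sigma")
                est[key] = math.sqrt(math.exp(xi))
                rse[key] = 100.0 * sei / 2.0
            else:
                est[name] = math.exp(xi)
                rse[name] = 100.0 * sei
        return est, rse


# ---------------------------------------------------------------------------
# FOCE machinery


class _Problem:
    """Vectorised FOCE-I objective for one dataset and model skeleton."""

    def __init__(self, dataset: PKDataset, skeleton: PopulationModel,
                 settings: EstimationSettings):
        if dataset.blq_fraction >= BLQ_MAX_FRACTION:
            raise ValueError(
                f"{100 * dataset.blq_fraction:.1f}% of observations are below the "
                f"LLOQ; the ignore-BLQ rule only applies below "
                f"{100 * BLQ_MAX_FRACTION:.0f}%"
            )
        self.ds = dataset
        self.skel = skeleton
        self.settings = settings
        self.spec = _ParamSpec(skeleton)

        keep = ~dataset.blq
        self.keep = keep
        self.y = dataset.y[keep]
        self.subj = dataset.obs_subject[keep]
        self.n_subj = dataset.n_subjects
        self.nobs_per_subj = np.bincount(self.subj, minlength=self.n_subj)
        if dataset.regular:
            amt, tau, m, s = dataset.sched
            self.sched = (amt[keep] * MMOL_PER_MG, tau[keep], m[keep], s[keep])
            self.pairs = None
        else:
            pamt, pdt, pobs = dataset.pairs
            sel = keep[pobs]
            reindex = np.cumsum(keep) - 1
            self.pairs = (pamt[sel] * MMOL_PER_MG, pdt[sel], reindex[pobs[sel]])
            self.sched = None

        # per-subject covariate design for each effect
        self._eff_cov = {}
        for e in skeleton.covariate_effects:
            vals = dataset.cov[e.covariate.upper()]
            if e.form == "power":
                self._eff_cov[e.name] = np.log(vals / e.reference)
            elif e.form == "linear":
                self._eff_cov[e.name] = vals / e.reference
            else:
                self._eff_cov[e.name] = vals.astype(float)

        # active etas: 0 -> eta_cl, 1 -> eta_v
        self.eta_active = []
        if skeleton.omega2_cl > 0:
            self.eta_active.append(0)
        if skeleton.omega2_v > 0:
            self.eta_active.append(1)
        self.k = len(self.eta_active)
        self.eta_warm = np.zeros((self.n_subj, self.k))

        # grouping of subjects by observation count (for batched V_i algebra)
        order = np.argsort(self.subj, kind="stable")
        if not np.array_equal(order, np.arange(len(self.subj))):
            raise ValueError("observations are not grouped by subject")
        self.obs_offsets = np.concatenate([[0], np.cumsum(self.nobs_per_subj)])
        self.groups = {}
        for n in np.unique(self.nobs_per_subj):
            if n == 0:
                continue
            subj_idx = np.flatnonzero(self.nobs_per_subj == n)
            obs_idx = (self.obs_offsets[subj_idx][:, None] + np.arange(n)[None, :])
            self.groups[int(n)] = (subj_idx, obs_idx)

        self.n_calls = 0

    # -- structural predictions -----------------------------------------
    def typical_params(self, p: dict):
        """(cl_typ, v_typ) per subject; None on an invalid covariate factor."""
        log_cl = np.full(self.n_subj, math.log(p["theta_cl"]))
        log_v = np.full(self.n_subj, math.log(p["theta_v"]))
        for e, beta in zip(self.spec.effects, p["_betas"]):
            cov = self._eff_cov[e.name]
            if e.form == "power":
                fac_log = beta * cov
            else:
                fac = 1.0 + beta * cov
                if np.any(fac <= 0):
                    return None, None
                fac_log = np.log(fac)
            if e.parameter == "cl":
                log_cl = log_cl + fac_log
            else:
                log_v = log_v + fac_log
        return np.exp(log_cl), np.exp(log_v)

    def predict(self, cl_subj, v_subj):
        """Per-observation concentration given subject-level CL and V."""
        ke = cl_subj / v_subj
        if self.sched is not None:
            amt, tau, m, s = self.sched
            return _conc_profile(amt, tau, m, s, self.skel.ka,
                                 ke[self.subj], v_subj[self.subj])
        pamt, pdt, pobs = self.pairs
        terms = _conc_profile(pamt, 1.0, 1.0, pdt, self.skel.ka,
                              ke[self.subj][pobs], v_subj[self.subj][pobs])
        return np.bincount(pobs, weights=terms, minlength=len(self.y))

    def _f_eta(self, cl_typ, v_typ, eta):
        cl = cl_typ.copy()
        v = v_typ.copy()
        for d, which in enumerate(self.eta_active):
            if which == 0:
                cl = cl_typ * np.exp(eta[:, d])
            else:
                v = v_typ * np.exp(eta[:, d])
        return self.predict(cl, v)

    # -- inner problem ---------------------------------------------------
    def _deviance(self, f, eta, p):
        w = p["sigma2_add"] + p["sigma2_prop"] * f * f
        w = np.maximum(w, 1e-300)
        r = self.y - f
        per_obs = r * r / w + np.log(w)
        dev = np.bincount(self.subj, weights=per_obs, minlength=self.n_subj)
        for d, which in enumerate(self.eta_active):
            om = p["omega2_cl"] if which == 0 else p["omega2_v"]
            dev = dev + eta[:, d] ** 2 / om
        return dev

    def inner_solve(self, p: dict, cl_typ, v_typ, eta0=None):
        """Damped Gauss-Newton minimisation of the penalised deviance."""
        k = self.k
        if k == 0:
            return np.zeros((self.n_subj, 0))
        eta = (eta0 if eta0 is not None else self.eta_warm).copy()
        h = self.settings.eta_fd_step
        omega = np.array(
            [p["omega2_cl"] if w == 0 else p["omega2_v"] for w in self.eta_active]
        )
        f = self._f_eta(cl_typ, v_typ, eta)
        dev = self._deviance(f, eta, p)
        for _ in range(self.settings.inner_max_iter):
            # central-difference sensitivities df/deta
            G = np.empty((len(self.y), k))
            for d in range(k):
                ep = eta.copy(); ep[:, d] += h
                em = eta.copy(); em[:, d] -= h
                G[:, d] = (self._f_eta(cl_typ, v_typ, ep)
                           - self._f_eta(cl_typ, v_typ, em)) / (2 * h)
            w = np.maximum(p["sigma2_add"] + p["sigma2_prop"] * f * f, 1e-300)
            r = self.y - f
            dw_fac = 2.0 * p["sigma2_prop"] * f  # d w / d f
            grad = np.empty((self.n_subj, k))
            H = np.empty((self.n_subj, k, k))
            for d in range(k):
                gobs = (-2.0 * r * G[:, d] / w
                        + (1.0 / w - r * r / (w * w)) * dw_fac * G[:, d])
                grad[:, d] = (np.bincount(self.subj, weights=gobs,
                                          minlength=self.n_subj)
                              + 2.0 * eta[:, d] / omega[d])
                for d2 in range(d, k):
                    hobs = 2.0 * G[:, d] * G[:, d2] / w
                    Hdd = np.bincount(self.subj, weights=hobs,
                                      minlength=self.n_subj)
                    if d2 == d:
                        Hdd = Hdd + 2.0 / omega[d]
                    H[:, d, d2] = Hdd
                    H[:, d2, d] = Hdd
            # Newton step (k <= 2: explicit solve with ridge fallback)
            step = self._solve_small(H, -grad)
            alpha = np.ones(self.n_subj)
            new_eta = eta + alpha[:, None] * step
            new_f = self._f_eta(cl_typ, v_typ, new_eta)
            new_dev = self._deviance(new_f, new_eta, p)
            for _ in range(15):
                worse = new_dev > dev + 1e-12
                if not np.any(worse):
                    break
                alpha = np.where(worse, alpha * 0.5, alpha)
                new_eta = eta + alpha[:, None] * step
                new_f = self._f_eta(cl_typ, v_typ, new_eta)
                new_dev = self._deviance(new_f, new_eta, p)
            improved = new_dev <= dev + 1e-12
            change = np.where(improved, dev - new_dev, 0.0)
            eta = np.where(improved[:, None], new_eta, eta)
            f = self._f_eta(cl_typ, v_typ, eta)
            dev = np.minimum(dev, new_dev)
            if np.max(change) < self.settings.inner_tol * (1.0 + np.abs(dev).max()):
                break
        return eta

    @staticmethod
    def _solve_small(H, b):
        k = b.shape[1]
        if k == 1:
            return b / np.maximum(H[:, 0, 0], 1e-12)[:, None]
        a, bb, c, d = H[:, 0, 0], H[:, 0, 1], H[:, 1, 0], H[:, 1, 1]
        det = a * d - bb * c
        ridge = det < 1e-12 * np.maximum(a * d, 1e-12)
        lam = np.where(ridge, 1e-8 + 1e-3 * (np.abs(a) + np.abs(d)), 0.0)
        a = a + lam
        d = d + lam
        det = a * d - bb * c
        x0 = (d * b[:, 0] - bb * b[:, 1]) / det
        x1 = (-c * b[:, 0] + a * b[:, 1]) / det
        return np.stack([x0, x1], axis=1)

    # -- FOCE linearisation and OFV --------------------------------------
    def linearize(self, p: dict, cl_typ, v_typ, eta):
        h = self.settings.eta_fd_step
        f = self._f_eta(cl_typ, v_typ, eta)
        G = np.empty((len(self.y), self.k))
        for d in range(self.k):
            ep = eta.copy(); ep[:, d] += h
            em = eta.copy(); em[:, d] -= h
            G[:, d] = (self._f_eta(cl_typ, v_typ, ep)
                       - self._f_eta(cl_typ, v_typ, em)) / (2 * h)
        w = np.maximum(p["sigma2_add"] + p["sigma2_prop"] * f * f, 1e-300)
        return f, G, w

    def ofv_terms(self, p: dict, f, G, w, eta):
        """Per-subject FOCE-I -2 log likelihood contributions."""
        omega = np.array(
            [p["omega2_cl"] if which == 0 else p["omega2_v"]
             for which in self.eta_active]
        )
        resid = self.y - f
        geta = G @ eta.T if self.k else np.zeros((len(self.y), self.n_subj))
        out = np.zeros(self.n_subj)
        for n, (subj_idx, obs_idx) in self.groups.items():
            Gb = G[obs_idx]  # (ns, n, k)
            wb = w[obs_idx]
            rb = resid[obs_idx]
            if self.k:
                rb = rb + np.einsum("snk,sk->sn", Gb, eta[subj_idx])
                V = np.einsum("snk,k,smk->snm", Gb, omega, Gb)
            else:
                V = np.zeros((len(subj_idx), n, n))
            V[:, np.arange(n), np.arange(n)] += wb
            sign, logdet = np.linalg.slogdet(V)
            sol = np.linalg.solve(V, rb[..., None])[..., 0]
            quad = np.einsum("sn,sn->s", rb, sol)
            out[subj_idx] = logdet + quad + n * math.log(2 * math.pi)
        return out

    def objective(self, x: np.ndarray) -> float:
        self.n_calls += 1
        p = self.spec.unpack(x)
        cl_typ, v_typ = self.typical_params(p)
        if cl_typ is None or not np.all(np.isfinite(cl_typ)):
            return 1e12
        try:
            eta = self.inner_solve(p, cl_typ, v_typ)
            self.eta_warm = eta
            f, G, w = self.linearize(p, cl_typ, v_typ, eta)
            terms = self.ofv_terms(p, f, G, w, eta)
        except np.linalg.LinAlgError:
            return 1e12
        if not np.all(np.isfinite(terms)):
            return 1e12
        self._last = (p, cl_typ, v_typ, eta, f, G, w)
        return float(terms.sum())

    # -- diagnostics ------------------------------------------------------
    def outputs(self, p, cl_typ, v_typ, eta):
        """PRED, IPRED, CWRES, IWRES aligned with the included observations."""
        pred = self._f_eta(cl_typ, v_typ, np.zeros_like(eta))
        ipred = self._f_eta(cl_typ, v_typ, eta)
        f, G, w = self.linearize(p, cl_typ, v_typ, eta)
        omega = np.array(
            [p["omega2_cl"] if which == 0 else p["omega2_v"]
             for which in self.eta_active]
        )
        resid = self.y - f
        cw = np.empty(len(self.y))
        for n, (subj_idx, obs_idx) in self.groups.items():
            Gb = G[obs_idx]
            wb = w[obs_idx]
            rb = resid[obs_idx]
            if self.k:
                rb = rb + np.einsum("snk,sk->sn", Gb, eta[subj_idx])
                V = np.einsum("snk,k,smk->snm", Gb, omega, Gb)
            else:
                V = np.zeros((len(subj_idx), n, n))
            V[:, np.arange(n), np.arange(n)] += wb
            lam, Q = np.linalg.eigh(V)
            if np.any(lam <= 0):
                raise np.linalg.LinAlgError("singular FOCE covariance block")
            inv_sqrt = np.einsum("snk,sk,smk->snm", Q, 1.0 / np.sqrt(lam), Q)
            cw[obs_idx.ravel()] = np.einsum("snm,sm->sn", inv_sqrt, rb).ravel()
        iw = (self.y - ipred) / np.sqrt(
            np.maximum(p["sigma2_add"] + p["sigma2_prop"] * ipred**2, 1e-300)
        )
        return pred, ipred, cw, iw


# ---------------------------------------------------------------------------
# result container and public entry points


@dataclass
class EstimationResult:
    """Estimates, diagnostics and uncertainty of one FOCE-I fit."""

    model: PopulationModel
    ofv: float
    params: dict
    converged: bool
    message: str
    etas: np.ndarray  # (n_subjects, 2): eta_cl, eta_v (0 where inactive)
    eta_shrinkage: dict  # percent, keys "cl"/"v" where estimated
    epsilon_shrinkage: float  # percent
    pred: np.ndarray
    ipred: np.ndarray
    cwres: np.ndarray
    iwres: np.ndarray
    obs_index: np.ndarray  # rows of dataset.frame for the included observations
    n_obs: int
    n_subjects: int
    n_function_evals: int
    rse_percent: dict | None = None
    covariance: np.ndarray | None = None
    correlation: np.ndarray | None = None
    condition_number: float | None = None
    x_names: tuple = ()
    x_hat: np.ndarray | None = None

    def param_table(self) -> pd.DataFrame:
        rows = []
        est, _ = _report_estimates(self)
        for name, value in est.items():
            rse = (self.rse_percent or {}).get(name)
            rows.append((name, value, rse))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "rse_percent"])


def _report_estimates(result: EstimationResult) -> tuple[dict, dict]:
    m = result.model
    est = {"theta_cl": m.theta_cl, "theta_v": m.theta_v}
    for e in m.covariate_effects:
        est[f"beta_{e.name}"] = e.theta
    if m.omega2_cl > 0:
        est["bsv_cl_percent"] = m.bsv_cl_percent
    if m.omega2_v > 0:
        est["bsv_v_percent"] = m.bsv_v_percent
    if m.residual.form in ("additive", "combined"):
        est["sigma_add"] = math.sqrt(m.residual.sigma2_add)
    if m.residual.form in ("proportional", "combined"):
        est["sigma_prop"] = math.sqrt(m.residual.sigma2_prop)
    return est, {}


def _fd_gradient(fun, x, rel_step):
    g = np.empty(len(x))
    for i in range(len(x)):
        h = rel_step * max(abs(x[i]), 0.1)
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _fd_hessian(fun, x, rel_step):
    n = len(x)
    h = np.array([rel_step * max(abs(xi), 0.1) for xi in x])
    H = np.empty((n, n))
    f0 = fun(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        fp[i] = fun(xp)
        fm[i] = fun(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                fun(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fun(xmm)
            ) / (2 * h[i] * h[j])
    return H


def fit(
    dataset: PKDataset,
    skeleton: PopulationModel,
    settings: EstimationSettings | None = None,
    x0: np.ndarray | None = None,
) -> EstimationResult:
    """Estimate a population model from a dataset by FOCE-I.

    ``skeleton`` supplies both the model structure (which covariate effects,
    which variances are present -- a variance of exactly 0 is structurally
    absent and its eta is fixed at 0) and the initial estimates.  The fit is
    deterministic given the data and settings.
    """
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, skeleton, settings)
    x_start = prob.spec.pack(skeleton) if x0 is None else np.asarray(x0, float)

    cache = {}

    def obj(x):
        key = x.tobytes()
        if key not in cache:
            if len(cache) > 4:
                cache.clear()
            cache[key] = prob.objective(x)
        return cache[key]

    def jac(x):
        return _fd_gradient(obj, x, settings.fd_rel_step)

    res = optimize.minimize(
        obj, x_start, jac=jac, method="L-BFGS-B",
        options={
            "maxiter": settings.outer_max_iter,
            "ftol": settings.outer_tol,
            "gtol": settings.outer_gtol,
        },
    )
    ofv = prob.objective(res.x)  # refresh cached state at the solution
    p, cl_typ, v_typ, eta, f, G, w = prob._last
    model_hat = prob.spec.to_model(p)

    etas_full = np.zeros((prob.n_subj, 2))
    for d, which in enumerate(prob.eta_active):
        etas_full[:, which] = eta[:, d]

    pred, ipred, cw, iw = prob.outputs(p, cl_typ, v_typ, eta)

    eta_shr = {}
    for d, which in enumerate(prob.eta_active):
        om = p["omega2_cl"] if which == 0 else p["omega2_v"]
        name = "cl" if which == 0 else "v"
        sd = float(np.std(eta[:, d], ddof=1)) if prob.n_subj > 1 else 0.0
        eta_shr[name] = 100.0 * (1.0 - sd / math.sqrt(om))
    eps_shr = 100.0 * (1.0 - float(np.std(iw, ddof=1))) if len(iw) > 1 else math.nan

    result = EstimationResult(
        model=model_hat,
        ofv=ofv,
        params={k: v for k, v in p.items() if not k.startswith("_")},
        converged=bool(res.success),
        message=str(res.message),
        etas=etas_full,
        eta_shrinkage=eta_shr,
        epsilon_shrinkage=eps_shr,
        pred=pred,
        ipred=ipred,
        cwres=cw,
        iwres=iw,
        obs_index=dataset.obs_index[prob.keep],
        n_obs=len(prob.y),
        n_subjects=prob.n_subj,
        n_function_evals=prob.n_calls,
        x_names=tuple(prob.spec.names),
        x_hat=res.x.copy(),
    )

    if settings.compute_uncertainty:
        try:
            H = _fd_hessian(prob.objective, res.x, settings.hessian_rel_step)
            cov = 2.0 * np.linalg.inv(H)
            dg = np.diag(cov)
            if np.any(~np.isfinite(dg)) or np.any(dg <= 0):
                raise np.linalg.LinAlgError("non-positive-definite Hessian")
            se_x = np.sqrt(dg)
            d = np.sqrt(dg)
            corr = cov / np.outer(d, d)
            lam = np.linalg.eigvalsh(corr)
            result.covariance = cov
            result.correlation = corr
            result.condition_number = float(lam.max() / lam.min()) if lam.min() > 0 else math.inf
            _, rse = prob.spec.report_scale(prob.spec.names, res.x, se_x)
            result.rse_percent = rse
        except np.linalg.LinAlgError:
            result.rse_percent = None
    return result


def foce_objective(
    dataset: PKDataset,
    model: PopulationModel,
    settings: EstimationSettings | None = None,
) -> float:
    """FOCE-I objective function value of ``model`` on ``dataset`` (no fitting)."""
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    return prob.objective(prob.spec.pack(model))


def conditional_etas(
    dataset: PKDataset,
    model: PopulationModel,
    settings: EstimationSettings | None = None,
):
    """Empirical Bayes etas (n_subjects x 2) and inner curvature per subject."""
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    p = prob.spec.unpack(prob.spec.pack(model))
    cl_typ, v_typ = prob.typical_params(p)
    eta = prob.inner_solve(p, cl_typ, v_typ)
    etas_full = np.zeros((prob.n_subj, 2))
    for d, which in enumerate(prob.eta_active):
        etas_full[:, which] = eta[:, d]
    # curvature: Gauss-Newton Hessian of the penalised deviance at eta*
    f, G, w = prob.linearize(p, cl_typ, v_typ, eta)
    omega = np.array(
        [p["omega2_cl"] if which == 0 else p["omega2_v"]
         for which in prob.eta_active]
    )
    hess = np.zeros((prob.n_subj, prob.k, prob.k))
    for d in range(prob.k):
        for d2 in range(prob.k):
            hb = np.bincount(prob.subj, weights=2.0 * G[:, d] * G[:, d2] / w,
                             minlength=prob.n_subj)
            hess[:, d, d2] = hb
        hess[:, d, d] += 2.0 / omega[d]
    return etas_full, hess


def cwres(dataset: PKDataset, model: PopulationModel,
          settings: EstimationSettings | None = None) -> np.ndarray:
    """Conditional weighted residuals of ``model`` on ``dataset``."""
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    p = prob.spec.unpack(prob.spec.pack(model))
    cl_typ, v_typ = prob.typical_params(p)
    eta = prob.inner_solve(p, cl_typ, v_typ)
    _, _, cw, _ = prob.outputs(p, cl_typ, v_typ, eta)
    return cw


def shrinkage(dataset: PKDataset, model: PopulationModel,
              settings: EstimationSettings | None = None):
    """(eta shrinkage dict in percent, epsilon shrinkage in percent)."""
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    p = prob.spec.unpack(prob.spec.pack(model))
    cl_typ, v_typ = prob.typical_params(p)
    eta = prob.inner_solve(p, cl_typ, v_typ)
    _, _, _, iw = prob.outputs(p, cl_typ, v_typ, eta)
    out = {}
    for d, which in enumerate(prob.eta_active):
        om = p["omega2_cl"] if which == 0 else p["omega2_v"]
        sd = float(np.std(eta[:, d], ddof=1)) if prob.n_subj > 1 else 0.0
        out["cl" if which == 0 else "v"] = 100.0 * (1.0 - sd / math.sqrt(om))
    eps = 100.0 * (1.0 - float(np.std(iw, ddof=1))) if len(iw) > 1 else math.nan
    return out, eps


def standard_errors(dataset: PKDataset, model: PopulationModel,
                    settings: EstimationSettings | None = None):
    """(RSE% dict, covariance of the transformed estimates, condition number).

    The covariance is the inverse of one-half the finite-difference Hessian
    of the OFV; the condition number is the eigenvalue ratio of the implied
    correlation matrix.
    """
    settings = settings or EstimationSettings()
    prob = _Problem(dataset, model, settings)
    x = prob.spec.pack(model)
    H = _fd_hessian(prob.objective, x, settings.hessian_rel_step)
    cov = 2.0 * np.linalg.inv(H)
    if np.any(np.diag(cov) <= 0):
        return None, None, None
    se_x = np.sqrt(np.diag(cov))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    lam = np.linalg.eigvalsh(corr)
    cond = float(lam.max() / lam.min()) if lam.min() > 0 else math.inf
    _, rse = prob.spec.report_scale(prob.spec.names, x, se_x)
    return rse, cov, cond
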