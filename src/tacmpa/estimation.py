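"""Nonlinear mixed-effects estimation (FOCE-I and Laplace).

The marginal likelihood of each subject's data is approximated either by the
first-order-conditional expansion with eta-residual interaction (FOCE-I) or
by the full second-order Laplace approximation, both evaluated at the
subject's empirical-Bayes mode eta_hat.  The objective function value (OFV)
follows the pharmacometric convention of dropping all 2*pi constants, so
differences between nested models are likelihood-ratio statistics.

Below-LLOQ (BLQ) records are handled by one of three strategies: ``omit``
(dropped), ``replace-with-ipred`` (DV replaced by the individual prediction
at the current empirical-Bayes eta, refreshed at every objective
evaluation), or ``M3`` (censored-likelihood contribution Phi(LLOQ)).
The standard routing rule is FOCE-I + omit when fewer than 10% of an
analyte's observations are BLQ, and Laplace + replace-with-ipred otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess3

from .dataset import TrialDataset
from .models import (IntegratedModelSpec, ResidualModel, _tac_closed_form,
                     apply_etas, predict_profiles)
from .scm import CovariateCandidate, covariate_multiplier

_TAC_THETAS = ("cl_tac", "v2", "ka_tac", "k23", "k32", "tlag", "cyp3a5_fold")
_MPA_THETAS = ("cl_mpa", "v5", "ka_mpa", "k56", "k65", "ehc_frac", "k70",
               "v7", "k84", "mtime1")
_TAC_ETAS = ("cl_tac", "v2", "ka_tac")
_MPA_ETAS = ("cl_mpa", "v5", "ka_mpa", "ehc_frac")


@dataclass
class EstimationSettings:
    method: str = "FOCE-I"            # "FOCE-I" | "Laplace"
    blq_strategy: str = "omit"        # "omit" | "replace-with-ipred" | "M3"
    inner_tol: float = 1e-7
    outer_tol: float = 1e-7
    max_iter: int = 300
    seed: int | None = None
    fixed: frozenset = frozenset()    # parameter names held at their initial values

    def __post_init__(self):
        if self.method not in ("FOCE-I", "Laplace"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.blq_strategy not in ("omit", "replace-with-ipred", "M3"):
            raise ValueError(f"unknown BLQ strategy {self.blq_strategy!r}")
        if self.inner_tol <= 0 or self.outer_tol <= 0:
            raise ValueError("tolerances must be > 0")
        self.fixed = frozenset(self.fixed)


@dataclass
class SubjectData:
    """One subject's observations (possibly several periods), fitting-ready."""

    subject_id: str
    is_expresser: bool
    covariates: dict[str, float]
    periods: list[dict]  # each: dose_tac, dose_mmf, times, analytes, dv, blq, lloq

    def n_obs(self) -> int:
        return sum(len(p["dv"]) for p in self.periods)


@dataclass
class FitResult:
    theta: dict[str, float]
    omega2: dict[str, float]
    sigma: dict[str, ResidualModel]
    ofv: float
    etas: dict[str, dict[str, float]]
    converged: bool
    trace: list[tuple[int, float]]
    spec: IntegratedModelSpec
    n_obs: int = 0
    message: str = ""


def route_estimation_method(blq_fractions: dict[str, float]) -> dict[str, EstimationSettings]:
    """Per-analyte method routing from observed BLQ fractions.

    Strictly fewer than 10% BLQ -> FOCE-I with omission; otherwise Laplace
    with DV replaced by the individual prediction (M3 can be requested
    explicitly as the censored-likelihood alternative).
    """
    out = {}
    for analyte, frac in blq_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"BLQ fraction for {analyte} outside [0, 1]")
        if frac < 0.10:
            out[analyte] = EstimationSettings(method="FOCE-I", blq_strategy="omit")
        else:
            out[analyte] = EstimationSettings(method="Laplace",
                                              blq_strategy="replace-with-ipred")
    return out


# ---------------------------------------------------------------------------
# model wrapper


class PopPKModel:
    """Maps a flat parameter dict onto per-observation predictions.

    ``kind`` selects the submodel: "tac" (TAC-alone periods, analytic
    solution), "mpa" (MMF-alone periods, ODE without TAC) or "integrated"
    (all dosed periods, full ODE with the interaction).  Optional covariate
    effects multiply the typical value of their target parameter.
    """

    def __init__(self, template: IntegratedModelSpec, kind: str = "tac",
                 covariate_effects: tuple[CovariateCandidate, ...] = (),
                 ode_rtol: float = 1e-6, ode_atol: float = 1e-8):
        if kind not in ("tac", "mpa", "integrated"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.template = template
        self.kind = kind
        self.covariate_effects = tuple(covariate_effects)
        self.ode_rtol = ode_rtol
        self.ode_atol = ode_atol
        if kind == "tac":
            self.theta_names = _TAC_THETAS
            eta_pool = _TAC_ETAS
            self.analytes = ("TAC",)
        elif kind == "mpa":
            self.theta_names = _MPA_THETAS
            eta_pool = _MPA_ETAS
            self.analytes = ("MPA", "MPAG", "AcMPAG")
        else:
            self.theta_names = _TAC_THETAS + _MPA_THETAS + ("slope",)
            eta_pool = _TAC_ETAS + _MPA_ETAS
            self.analytes = ("TAC", "MPA", "MPAG", "AcMPAG")
        self.theta_names = self.theta_names + tuple(
            c.theta_name for c in self.covariate_effects)
        self.eta_names = tuple(k for k in eta_pool
                               if template.iiv.omega2.get(k, 0.0) > 0)

    def initial_theta(self) -> dict[str, float]:
        t, m = self.template.tac, self.template.mpa
        full = {"cl_tac": t.cl, "v2": t.v2, "ka_tac": t.ka, "k23": t.k23,
                "k32": t.k32, "tlag": t.tlag, "cyp3a5_fold": t.cyp3a5_fold,
                "cl_mpa": m.cl, "v5": m.v5, "ka_mpa": m.ka, "k56": m.k56,
                "k65": m.k65, "ehc_frac": m.ehc_frac, "k70": m.k70,
                "v7": m.v7, "k84": m.k84, "mtime1": m.mtime1,
                "slope": self.template.interaction.slope}
        for c in self.covariate_effects:
            full[c.theta_name] = c.initial
        return {k: full[k] for k in self.theta_names}

    def spec_with(self, theta: dict[str, float]) -> IntegratedModelSpec:
        """Template spec with the given typical values substituted."""
        t, m = self.template.tac, self.template.mpa
        tac = replace(t, cl=theta.get("cl_tac", t.cl), v2=theta.get("v2", t.v2),
                      ka=theta.get("ka_tac", t.ka), k23=theta.get("k23", t.k23),
                      k32=theta.get("k32", t.k32), tlag=theta.get("tlag", t.tlag),
                      cyp3a5_fold=theta.get("cyp3a5_fold", t.cyp3a5_fold))
        mpa = replace(m, cl=theta.get("cl_mpa", m.cl), v5=theta.get("v5", m.v5),
                      ka=theta.get("ka_mpa", m.ka), k56=theta.get("k56", m.k56),
                      k65=theta.get("k65", m.k65),
                      ehc_frac=min(theta.get("ehc_frac", m.ehc_frac), 0.999),
                      k70=theta.get("k70", m.k70), v7=theta.get("v7", m.v7),
                      k84=theta.get("k84", m.k84),
                      mtime1=theta.get("mtime1", m.mtime1))
        inter = replace(self.template.interaction,
                        slope=theta.get("slope", self.template.interaction.slope))
        return replace(self.template, tac=tac, mpa=mpa, interaction=inter)

    def _cov_factor(self, target: str, theta: dict, subj: SubjectData) -> float:
        fac = 1.0
        for c in self.covariate_effects:
            if c.target == target:
                fac *= covariate_multiplier(c, theta[c.theta_name],
                                            subj.covariates[c.covariate])
        return fac

    def predict(self, theta: dict[str, float], eta: np.ndarray,
                subj: SubjectData) -> np.ndarray:
        """Individual predictions for every observation row of ``subj``."""
        ed = dict(zip(self.eta_names, np.clip(eta, -60.0, 60.0)))
        if self.kind == "tac":
            cl = theta["cl_tac"] * math.exp(ed.get("cl_tac", 0.0)) \
                * (theta["cyp3a5_fold"] if subj.is_expresser else 1.0) \
                * self._cov_factor("cl_tac", theta, subj)
            v2 = theta["v2"] * math.exp(ed.get("v2", 0.0)) \
                * self._cov_factor("v2", theta, subj)
            ka = theta["ka_tac"] * math.exp(ed.get("ka_tac", 0.0))
            out = []
            for per in subj.periods:
                out.append(_tac_closed_form(cl, v2, ka, theta["k23"],
                                            theta["k32"], theta["tlag"],
                                            per["dose_tac"], per["times"]))
            return np.concatenate(out) if out else np.empty(0)
        spec = self.spec_with(theta)
        if self.covariate_effects:
            tac = replace(spec.tac, cl=spec.tac.cl * self._cov_factor("cl_tac", theta, subj),
                          v2=spec.tac.v2 * self._cov_factor("v2", theta, subj))
            spec = replace(spec, tac=tac)
        ind = apply_etas(spec, ed)
        out = []
        for per in subj.periods:
            prof = predict_profiles(ind, per["dose_tac"], per["dose_mmf"],
                                    per["times"], subj.is_expresser,
                                    rtol=self.ode_rtol, atol=self.ode_atol)
            preds = np.array([prof[a][j] for j, a in enumerate(per["analytes"])])
            out.append(preds)
        return np.concatenate(out) if out else np.empty(0)


def prepare_subjects(ds: TrialDataset, kind: str = "tac",
                     blq_strategy: str = "omit") -> list[SubjectData]:
    """Group a dataset into fitting-ready per-subject arrays.

    Period selection by kind: "tac" uses TAC-only periods, "mpa" MMF-only
    periods, "integrated" every dosed period.  Records flagged missing are
    always dropped; BLQ records are dropped under the omit strategy and kept
    (with their LLOQ) otherwise.
    """
    subjects = []
    for sid in ds.subject_ids():
        cov = ds.covariates[sid]
        recs = [r for r in ds.records if r.subject_id == sid]
        periods = sorted({r.period for r in recs})
        pdata = []
        for per in periods:
            doses = {r.drug_or_analyte: r.amount for r in recs
                     if r.period == per and r.event_type == "dose"}
            dose_tac = doses.get("TAC-dose", 0.0)
            dose_mmf = doses.get("MMF-dose", 0.0)
            if kind == "tac" and not (dose_tac > 0 and dose_mmf == 0):
                continue
            if kind == "mpa" and not (dose_mmf > 0 and dose_tac == 0):
                continue
            if kind == "integrated" and not (dose_tac > 0 or dose_mmf > 0):
                continue
            obs = [r for r in recs
                   if r.period == per and r.event_type == "observation"
                   and not r.missing and r.value is not None
                   and r.drug_or_analyte in
                   (("TAC",) if kind == "tac"
                    else ("MPA", "MPAG", "AcMPAG") if kind == "mpa"
                    else ("TAC", "MPA", "MPAG", "AcMPAG"))]
            if blq_strategy == "omit":
                obs = [r for r in obs if not r.is_blq]
            obs.sort(key=lambda r: (r.time, r.drug_or_analyte))
            if not obs:
                continue
            pdata.append({
                "period": per, "dose_tac": dose_tac, "dose_mmf": dose_mmf,
                "times": np.array([r.time for r in obs]),
                "analytes": [r.drug_or_analyte for r in obs],
                "dv": np.array([r.value for r in obs]),
                "blq": np.array([r.is_blq for r in obs]),
                "lloq": np.array([ds.analyte_specs[r.drug_or_analyte].lloq for r in obs]),
            })
        if pdata:
            covd = {"CYP3A5": float(cov.cyp3a5_expresser), "AGE": cov.age,
                    "WT": cov.weight, "HT": cov.height, "SCR": cov.scr,
                    "GFR": cov.gfr, "HGB": cov.hgb, "HCT": cov.hct,
                    "ALB": cov.albumin, "TBIL": cov.tbil, "ANC": cov.anc}
            subjects.append(SubjectData(sid, bool(cov.cyp3a5_expresser), covd, pdata))
    return subjects


# ---------------------------------------------------------------------------
# likelihood pieces


def _obs_arrays(subj: SubjectData):
    dv = np.concatenate([p["dv"] for p in subj.periods])
    blq = np.concatenate([p["blq"] for p in subj.periods])
    lloq = np.concatenate([p["lloq"] for p in subj.periods])
    analytes = [a for p in subj.periods for a in p["analytes"]]
    return dv, blq, lloq, analytes


def individual_joint_m2ll(model: PopPKModel, subj: SubjectData,
                          theta: dict[str, float], omega2: np.ndarray,
                          sigma: dict[str, ResidualModel], eta: np.ndarray,
                          blq_strategy: str = "omit",
                          dv_override: np.ndarray | None = None) -> float:
    """-2 log joint density of (y, eta), 2*pi constants omitted.

    Sum over observations of log(var) + (dv - f)^2 / var, with residual
    variance evaluated at the eta-conditional prediction, plus the prior
    penalty log|Omega| + eta' Omega^-1 eta.  Under M3, BLQ rows contribute
    -2 log Phi((LLOQ - f) / sd) instead of the Gaussian density term.
    """
    f = model.predict(theta, eta, subj)
    dv, blq, lloq, analytes = _obs_arrays(subj)
    if dv_override is not None:
        dv = dv_override
    var = np.empty_like(f)
    for j, a in enumerate(analytes):
        var[j] = sigma[a].variance(f[j])
    quant = ~blq if blq_strategy == "M3" else np.ones(len(dv), dtype=bool)
    if np.any(var[quant] <= 0):
        raise ValueError(
            f"non-positive residual variance for subject {subj.subject_id} "
            "(zero prediction under a purely proportional error model)")
    val = float(np.sum(np.log(var[quant]) + (dv[quant] - f[quant]) ** 2 / var[quant]))
    if blq_strategy == "M3" and np.any(blq):
        sd = np.sqrt(np.maximum(var[blq], 1e-300))
        val += float(-2.0 * np.sum(norm.logcdf((lloq[blq] - f[blq]) / sd)))
    if len(eta):
        val += float(np.sum(np.log(omega2)) + np.sum(eta * eta / omega2))
    return val


def _prediction_jacobian(model, subj, theta, eta, f0, h=1e-4):
    """Forward-difference d f / d eta at eta (n_obs x n_eta)."""
    d = len(eta)
    F = np.empty((len(f0), d))
    for k in range(d):
        ek = eta.copy()
        ek[k] += h
        F[:, k] = (model.predict(theta, ek, subj) - f0) / h
    return F


def _inner_newton(model, subj, theta, omega2, sigma, eta0, tol,
                  dv_override=None, max_iter=60):
    """Damped Gauss-Newton minimization of the joint -2LL over eta.

    Exact gradient of the Gaussian objective (including the log-variance
    terms of the interaction), Gauss-Newton Hessian 2 F' W F + 2 Omega^-1
    (always positive definite), step halving to guarantee descent.  Returns
    (eta_hat, m2ll, f, F, var, converged); f / F / var are reused by the
    FOCE linearization.
    """
    dv, blq, lloq, analytes = _obs_arrays(subj)
    y = dv if dv_override is None else dv_override
    sp2 = np.array([sigma[a].sigma_prop ** 2
                    if sigma[a].model in ("prop", "add+prop") else 0.0
                    for a in analytes])
    sa2 = np.array([sigma[a].sigma_add ** 2
                    if sigma[a].model in ("add", "add+prop") else 0.0
                    for a in analytes])
    prior_const = float(np.sum(np.log(omega2))) if len(omega2) else 0.0
    inv_om = 1.0 / omega2

    def value(eta, f):
        var = sp2 * f * f + sa2
        if np.any(var <= 0):
            raise ValueError(
                f"non-positive residual variance for subject {subj.subject_id}")
        with np.errstate(over="ignore"):  # huge misfits become +inf, rejected
            v = float(np.sum(np.log(var) + (y - f) ** 2 / var))
        return v + prior_const + float(np.sum(eta * eta * inv_om)), var

    eta = np.asarray(eta0, dtype=float).copy()
    f = model.predict(theta, eta, subj)
    m2ll, var = value(eta, f)
    converged = False
    F = _prediction_jacobian(model, subj, theta, eta, f)
    for _ in range(max_iter):
        r = y - f
        dvar_df = 2.0 * sp2 * f
        gobs = (dvar_df / var) - (2.0 * r / var) - (r * r / var ** 2) * dvar_df
        grad = F.T @ gobs + 2.0 * eta * inv_om
        if np.max(np.abs(grad)) < max(tol, 1e-10) * max(1.0, abs(m2ll)):
            converged = True
            break
        H = 2.0 * (F.T * (1.0 / var)) @ F + 2.0 * np.diag(inv_om)
        try:
            gn_step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            gn_step = -grad / np.max(np.abs(np.diag(H)))
        improved = False
        # Gauss-Newton direction first; if its line search stalls (the GN
        # Hessian ignores log-variance curvature), fall back to steepest
        # descent before giving up
        for step in (gn_step, -grad / max(np.max(np.abs(grad)), 1.0)):
            lam = 1.0
            for _ in range(25):
                trial = eta + lam * step
                f_t = model.predict(theta, trial, subj)
                try:
                    m2ll_t, var_t = value(trial, f_t)
                except ValueError:
                    lam *= 0.5
                    continue
                if m2ll_t < m2ll - 1e-13:
                    eta, f, m2ll, var = trial, f_t, m2ll_t, var_t
                    improved = True
                    break
                lam *= 0.5
            if improved:
                break
        if not improved:
            converged = np.max(np.abs(grad)) < 1e-3
            break
        F = _prediction_jacobian(model, subj, theta, eta, f)
    return eta, m2ll, f, F, var, converged


def estimate_etas(model: PopPKModel, subj: SubjectData, theta: dict[str, float],
                  omega2: np.ndarray, sigma: dict[str, ResidualModel],
                  start: np.ndarray | None = None, blq_strategy: str = "omit",
                  dv_override: np.ndarray | None = None,
                  tol: float = 1e-7) -> tuple[np.ndarray, float, bool]:
    """Empirical-Bayes mode: minimize the joint -2LL over eta.

    Returns (eta_hat, objective value, converged).  The returned value is
    never worse than the starting point.  The censored M3 objective is
    non-Gaussian, so it goes through a quasi-Newton fallback instead of the
    Gauss-Newton path.
    """
    d = len(model.eta_names)
    if d == 0:
        eta = np.empty(0)
        return eta, individual_joint_m2ll(model, subj, theta, omega2, sigma,
                                          eta, blq_strategy, dv_override), True
    x0 = np.zeros(d) if start is None else np.asarray(start, dtype=float)

    _, blq, _, _ = _obs_arrays(subj)
    if blq_strategy != "M3" or not np.any(blq):
        eta, m2ll, *_ , conv = _inner_newton(model, subj, theta, omega2, sigma,
                                             x0, tol, dv_override)
        return eta, m2ll, conv

    def fun(eta):
        try:
            return individual_joint_m2ll(model, subj, theta, omega2, sigma,
                                         eta, blq_strategy, dv_override)
        except (ValueError, RuntimeError, OverflowError):
            return 1e12

    res = optimize.minimize(fun, x0, method="BFGS",
                            options={"gtol": tol, "maxiter": 200})
    f0 = fun(x0)
    if res.fun <= f0:
        return res.x, float(res.fun), bool(res.success)
    return x0, float(f0), False


def _subject_ofv(model, subj, theta, omega2, sigma, settings,
                 eta_start=None) -> tuple[float, np.ndarray]:
    """FOCE-I or Laplace -2 log marginal likelihood contribution of one subject."""
    strategy = settings.blq_strategy
    dv, blq, lloq, analytes = _obs_arrays(subj)

    if eta_start is not None:
        eta_start = np.asarray(eta_start, dtype=float)

    dv_override = None
    if strategy == "replace-with-ipred" and np.any(blq):
        eta_ref = eta_start if eta_start is not None else np.zeros(len(model.eta_names))
        ipred = model.predict(theta, np.asarray(eta_ref, dtype=float), subj)
        dv_override = np.where(blq, ipred, dv)

    d = len(model.eta_names)
    if d == 0:
        eta = np.empty(0)
        return individual_joint_m2ll(model, subj, theta, omega2, sigma, eta,
                                     strategy, dv_override), eta

    if strategy == "M3" and np.any(blq):
        eta_hat, m2ll_hat, _ = estimate_etas(model, subj, theta, omega2, sigma,
                                             start=eta_start,
                                             blq_strategy=strategy,
                                             dv_override=dv_override,
                                             tol=settings.inner_tol)
        f = model.predict(theta, eta_hat, subj)
        F = _prediction_jacobian(model, subj, theta, eta_hat, f)
        var = np.array([sigma[a].variance(f[j]) for j, a in enumerate(analytes)])
    elif eta_start is None:
        # cold evaluation: the joint surface can be multimodal (notably in
        # the absorption-rate effect), so probe a fixed set of starts
        sd = np.sqrt(omega2)
        best = None
        for start in (np.zeros(d), sd, -sd):
            cand = _inner_newton(model, subj, theta, omega2, sigma, start,
                                 settings.inner_tol, dv_override)
            if best is None or cand[1] < best[1]:
                best = cand
        eta_hat, m2ll_hat, f, F, var, _ = best
    else:
        # warm start from the cached mode, but guard against evaluation
        # history poisoning the result: if a fresh zero start would begin
        # below the warm solution, take the better of the two descents
        eta_hat, m2ll_hat, f, F, var, _ = _inner_newton(
            model, subj, theta, omega2, sigma, eta_start,
            settings.inner_tol, dv_override)
        try:
            v_zero = individual_joint_m2ll(model, subj, theta, omega2, sigma,
                                           np.zeros(d), strategy, dv_override)
        except (ValueError, RuntimeError, OverflowError):
            v_zero = np.inf
        if v_zero < m2ll_hat:
            alt = _inner_newton(model, subj, theta, omega2, sigma, np.zeros(d),
                                settings.inner_tol, dv_override)
            if alt[1] < m2ll_hat:
                eta_hat, m2ll_hat, f, F, var, _ = alt

    if settings.method == "Laplace":
        def fun(e):
            return individual_joint_m2ll(model, subj, theta, omega2, sigma, e,
                                         strategy, dv_override)
        H = approx_hess3(eta_hat, fun) / 2.0
        H = 0.5 * (H + H.T)
        w, V = np.linalg.eigh(H)
        w = np.maximum(w, 1e-8)  # regularize non-PD inner Hessians
        return m2ll_hat + float(np.sum(np.log(w))), eta_hat

    # FOCE-I: linearize predictions about eta_hat
    y = dv if dv_override is None else dv_override
    use = ~blq if strategy == "M3" else np.ones(len(y), dtype=bool)
    Fq = F[use]
    Vm = Fq @ (omega2[:, None] * Fq.T) + np.diag(var[use])
    r = (y - f + F @ eta_hat)[use]
    sign, logdet = np.linalg.slogdet(Vm)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"non-positive-definite FOCE covariance for subject {subj.subject_id}")
    ofv = float(logdet + r @ np.linalg.solve(Vm, r))
    if strategy == "M3" and np.any(blq):
        sd = np.sqrt(np.maximum(var[blq], 1e-300))
        ofv += float(-2.0 * np.sum(norm.logcdf((lloq[blq] - f[blq]) / sd)))
    return ofv, eta_hat


def marginal_ofv(subjects: list[SubjectData], model: PopPKModel,
                 theta: dict[str, float], omega2: np.ndarray,
                 sigma: dict[str, ResidualModel], settings: EstimationSettings,
                 eta_cache: dict[str, np.ndarray] | None = None) -> float:
    """Population OFV: sum of per-subject approximate -2 log marginal likelihoods.

    ``eta_cache`` (subject id -> eta) is read for warm starts and updated in
    place with the new empirical-Bayes modes.
    """
    total = 0.0
    for subj in subjects:
        start = eta_cache.get(subj.subject_id) if eta_cache is not None else None
        ofv_i, eta_hat = _subject_ofv(model, subj, theta, omega2, sigma,
                                      settings, eta_start=start)
        total += ofv_i
        if eta_cache is not None:
            eta_cache[subj.subject_id] = eta_hat
    return total


def dataset_ofv(ds: TrialDataset, spec: IntegratedModelSpec,
                settings: EstimationSettings, kind: str = "tac",
                covariate_effects: tuple[CovariateCandidate, ...] = ()) -> float:
    """Convenience wrapper: OFV of a dataset at the spec's own parameter values."""
    model = PopPKModel(spec, kind, covariate_effects)
    subjects = prepare_subjects(ds, kind, settings.blq_strategy)
    theta = model.initial_theta()
    omega2 = np.array([spec.iiv.omega2[k] for k in model.eta_names])
    return marginal_ofv(subjects, model, theta, omega2, spec.residual.per_analyte,
                        settings)


# ---------------------------------------------------------------------------
# population fit


def _build_parameter_vector(model: PopPKModel, spec: IntegratedModelSpec,
                            settings: EstimationSettings):
    """Names, initial values and log-scale bounds of the estimated parameters."""
    names, inits, bounds = [], [], []
    theta0 = model.initial_theta()
    first_obs = 1.0  # earliest post-dose sample of the design grid
    for k, v in theta0.items():
        if k in settings.fixed:
            continue
        if k == "cyp3a5_fold" and v == 1.0 and "cyp3a5_fold" in settings.fixed:
            continue
        names.append(k)
        inits.append(v)
        if k == "tlag":
            bounds.append((math.log(1e-3), math.log(0.95 * first_obs)))
        elif k == "ehc_frac":
            bounds.append((math.log(1e-3), math.log(0.99)))
        else:
            bounds.append((math.log(v) - 4.0, math.log(v) + 4.0))
    for k in model.eta_names:
        name = f"omega2_{k}"
        if name in settings.fixed:
            continue
        names.append(name)
        inits.append(spec.iiv.omega2[k])
        bounds.append((math.log(1e-6), math.log(25.0)))
    for a in model.analytes:
        res = spec.residual.per_analyte[a]
        if res.model in ("prop", "add+prop") and f"sigma_prop_{a}" not in settings.fixed:
            names.append(f"sigma_prop_{a}")
            inits.append(res.sigma_prop)
            bounds.append((math.log(1e-4), math.log(10.0)))
        if res.model in ("add", "add+prop") and f"sigma_add_{a}" not in settings.fixed:
            names.append(f"sigma_add_{a}")
            inits.append(res.sigma_add)
            bounds.append((math.log(1e-6), math.log(100.0)))
    return names, np.array(inits, dtype=float), bounds


def _unpack(names, x, model, spec):
    """Split an optimizer vector (log scale) into theta / omega2 / sigma."""
    vals = dict(zip(names, np.exp(x)))
    theta = model.initial_theta()
    theta.update({k: v for k, v in vals.items() if k in theta})
    omega2 = np.array([vals.get(f"omega2_{k}", spec.iiv.omega2[k])
                       for k in model.eta_names])
    sigma = {}
    for a, res in spec.residual.per_analyte.items():
        sigma[a] = replace(res,
                           sigma_prop=vals.get(f"sigma_prop_{a}", res.sigma_prop),
                           sigma_add=vals.get(f"sigma_add_{a}", res.sigma_add))
    return theta, omega2, sigma


def fit_population(ds: TrialDataset, spec: IntegratedModelSpec,
                   settings: EstimationSettings, kind: str = "tac",
                   covariate_effects: tuple[CovariateCandidate, ...] = (),
                   ode_rtol: float = 1e-6) -> FitResult:
    """Maximum-likelihood population fit.

    The spec carries the initial values; all positive parameters are
    estimated on the log scale with a quasi-Newton outer optimizer
    (L-BFGS-B, finite-difference gradients) around the FOCE-I/Laplace OFV.
    Empirical-Bayes etas are warm-started across outer evaluations.  The
    returned OFV is the best value seen, never worse than the initial one.
    """
    model = PopPKModel(spec, kind, covariate_effects, ode_rtol=ode_rtol)
    subjects = prepare_subjects(ds, kind, settings.blq_strategy)
    if len(subjects) < 2:
        raise ValueError("population fitting requires at least 2 subjects")
    names, inits, bounds = _build_parameter_vector(model, spec, settings)
    x0 = np.log(inits)
    eta_cache: dict[str, np.ndarray] = {}
    trace: list[tuple[int, float]] = []
    best = {"ofv": np.inf, "x": x0.copy()}
    neval = 0

    def objective(x):
        nonlocal neval
        neval += 1
        theta, omega2, sigma = _unpack(names, x, model, spec)
        try:
            ofv = marginal_ofv(subjects, model, theta, omega2, sigma,
                               settings, eta_cache)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            return 1e10
        if ofv < best["ofv"]:
            best["ofv"], best["x"] = ofv, x.copy()
        trace.append((neval, ofv))
        return ofv

    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": settings.max_iter,
                                     "ftol": settings.outer_tol,
                                     "gtol": 1e-6, "eps": 1e-3})
    x_best = best["x"] if best["ofv"] < res.fun else res.x
    theta, omega2, sigma = _unpack(names, x_best, model, spec)
    final_ofv = marginal_ofv(subjects, model, theta, omega2, sigma,
                             settings, eta_cache)
    etas = {s.subject_id: dict(zip(model.eta_names, eta_cache[s.subject_id]))
            for s in subjects}
    fitted_spec = model.spec_with(theta)
    fitted_spec = replace(
        fitted_spec,
        iiv=replace(spec.iiv, omega2={**spec.iiv.omega2,
                                      **dict(zip(model.eta_names, omega2))}),
        residual=type(spec.residual)(sigma),
    )
    return FitResult(theta=theta,
                     omega2=dict(zip(model.eta_names, omega2)),
                     sigma=sigma, ofv=float(final_ofv), etas=etas,
                     converged=bool(res.success), trace=trace,
                     spec=fitted_spec,
                     n_obs=sum(s.n_obs() for s in subjects),
                     message=str(res.message))


def bootstrap_fits(ds: TrialDataset, spec: IntegratedModelSpec,
                   settings: EstimationSettings, n_boot: int, seed: int,
                   kind: str = "tac") -> list[FitResult]:
    """Nonparametric bootstrap hook: refit on subject-resampled datasets.

    Subjects are drawn with replacement (resampled copies get fresh ids so
    duplicate keys stay valid).  Provided for uncertainty exploration;
    parameter precision (standard errors) is deliberately not part of the
    validated surface of this package.
    """
    rng = np.random.default_rng(seed)
    sids = ds.subject_ids()
    out = []
    for _ in range(n_boot):
        chosen = rng.choice(sids, size=len(sids), replace=True)
        records, covs = [], {}
        for new_idx, sid in enumerate(chosen):
            new_id = f"b{new_idx}"
            for r in ds.records:
                if r.subject_id == sid:
                    records.append(replace(r, subject_id=new_id))
            covs[new_id] = replace(ds.covariates[sid], subject_id=new_id)
        boot = TrialDataset(records, covs, dict(ds.analyte_specs))
        out.append(fit_population(boot, spec, settings, kind=kind))
    return out
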