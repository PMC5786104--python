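"""Model evaluation: pcVPC, conditional weighted residuals, eta shrinkage.

The prediction-corrected visual predictive check (pcVPC) simulates replicate
trials on the observed design, bins records by nominal sampling time, and
rescales both observed and simulated values within each bin by
median-typical-prediction / record-typical-prediction before computing
percentiles, removing interindividual trend from the comparison.  CWRES
standardizes residuals by the FOCE-linearized covariance at the subject's
empirical-Bayes mode and is approximately N(0,1) under a correct model.
Eta shrinkage is 100 * (1 - SD(eta_hat) / omega), the fraction of prior
variability not informed by the individual data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import (EstimationSettings, PopPKModel, SubjectData,
                         _inner_newton, _obs_arrays, prepare_subjects)
from .models import IntegratedModelSpec, ResidualModel


@dataclass
class VpcBin:
    time: float
    n: int
    observed: dict[int, float]                 # percentile -> observed value
    band_low: dict[int, float]                 # percentile -> simulated 2.5%
    band_high: dict[int, float]                # percentile -> simulated 97.5%


@dataclass
class VpcResult:
    analyte: str
    bins: list[VpcBin]
    n_sim: int
    prediction_corrected: bool

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside its simulated 95% confidence band."""
        inside = total = 0
        for b in self.bins:
            for q, obs in b.observed.items():
                total += 1
                if b.band_low[q] <= obs <= b.band_high[q]:
                    inside += 1
        return inside / total if total else float("nan")


@dataclass
class ShrinkageReport:
    shrinkage_pct: dict[str, float | None]


def eta_shrinkage(eta_hats: dict[str, dict[str, float]],
                  omega2: dict[str, float]) -> ShrinkageReport:
    """Per-effect shrinkage 100*(1 - SD(eta_hat)/omega), SD with ddof=1.

    Effects with omega = 0 are undefined and reported as None.
    """
    if len(eta_hats) < 2:
        raise ValueError("shrinkage requires at least 2 subjects")
    out: dict[str, float | None] = {}
    for name, om2 in omega2.items():
        if om2 <= 0:
            out[name] = None
            continue
        vals = np.array([e.get(name, 0.0) for e in eta_hats.values()])
        out[name] = float(100.0 * (1.0 - vals.std(ddof=1) / np.sqrt(om2)))
    return ShrinkageReport(out)


def cwres(ds, spec: IntegratedModelSpec, kind: str = "tac",
          settings: EstimationSettings | None = None) -> dict[str, np.ndarray]:
    """Conditional weighted residuals per subject.

    For each subject, predictions are linearized about the empirical-Bayes
    mode eta_hat: the population-conditional mean is f(eta_hat) - F eta_hat
    and the covariance V = F Omega F' + Sigma(f(eta_hat)); CWRES is the
    symmetric inverse square root of V applied to the residual.
    """
    settings = settings or EstimationSettings()
    model = PopPKModel(spec, kind)
    subjects = prepare_subjects(ds, kind, settings.blq_strategy)
    omega2 = np.array([spec.iiv.omega2[k] for k in model.eta_names])
    sigma = spec.residual.per_analyte
    theta = model.initial_theta()
    out = {}
    for subj in subjects:
        dv, blq, lloq, analytes = _obs_arrays(subj)
        eta_hat, _, f, F, var, _ = _inner_newton(
            model, subj, theta, omega2, sigma,
            np.zeros(len(model.eta_names)), settings.inner_tol)
        V = F @ (omega2[:, None] * F.T) + np.diag(var)
        w, Q = np.linalg.eigh(V)
        if np.any(w <= 0):
            raise np.linalg.LinAlgError(
                f"singular conditional covariance for subject {subj.subject_id}")
        inv_sqrt = Q @ np.diag(w ** -0.5) @ Q.T
        r = dv - (f - F @ eta_hat)
        out[subj.subject_id] = inv_sqrt @ r
    return out


def _typical_predictions(model: PopPKModel, subj: SubjectData, theta):
    return model.predict(theta, np.zeros(len(model.eta_names)), subj)


def run_vpc(ds, spec: IntegratedModelSpec, kind: str = "tac",
            n_sim: int = 1000, prediction_corrected: bool = True,
            seed: int = 0, percentiles=(5, 50, 95),
            analytes: tuple[str, ...] | None = None) -> dict[str, VpcResult]:
    """Prediction-corrected VPC on the observed design.

    Simulates ``n_sim`` replicates of the dataset (new etas and residual
    errors per replicate, design fixed), bins by nominal sampling time, and
    returns observed percentiles with the simulated 95% confidence band of
    each percentile.  BLQ observations are excluded from the percentiles.
    """
    if n_sim < 50:
        raise ValueError("n_sim < 50 gives meaningless confidence bands")
    rng = np.random.default_rng(seed)
    model = PopPKModel(spec, kind)
    subjects = prepare_subjects(ds, kind, "omit")
    theta = model.initial_theta()
    omega2 = np.array([spec.iiv.omega2[k] for k in model.eta_names])
    sigma = spec.residual.per_analyte
    if analytes is None:
        analytes = model.analytes

    # per-record metadata
    rec_analyte, rec_time, rec_dv, rec_pred = [], [], [], []
    for subj in subjects:
        dv, blq, lloq, alist = _obs_arrays(subj)
        pred = _typical_predictions(model, subj, theta)
        times = np.concatenate([p["times"] for p in subj.periods])
        rec_analyte.extend(alist)
        rec_time.extend(times)
        rec_dv.extend(dv)
        rec_pred.extend(pred)
    rec_analyte = np.array(rec_analyte)
    rec_time = np.array(rec_time)
    rec_dv = np.array(rec_dv)
    rec_pred = np.array(rec_pred)

    # simulate replicates
    n_eta = len(model.eta_names)
    sims = np.empty((n_sim, len(rec_dv)))
    for s in range(n_sim):
        row = []
        for subj in subjects:
            eta = rng.standard_normal(n_eta) * np.sqrt(omega2)
            f = model.predict(theta, eta, subj)
            _, _, _, alist = _obs_arrays(subj)
            y = np.empty(len(f))
            for j, a in enumerate(alist):
                res: ResidualModel = sigma[a]
                e_p = rng.standard_normal() * res.sigma_prop \
                    if res.model in ("prop", "add+prop") else 0.0
                e_a = rng.standard_normal() * res.sigma_add \
                    if res.model in ("add", "add+prop") else 0.0
                y[j] = max(f[j] * (1.0 + e_p) + e_a, 0.0)
            row.append(y)
        sims[s] = np.concatenate(row)

    results = {}
    for analyte in analytes:
        sel = rec_analyte == analyte
        if not np.any(sel):
            continue
        times = rec_time[sel]
        bins = []
        for t in np.unique(times):
            m = sel & (rec_time == t)
            obs = rec_dv[m]
            sim = sims[:, m]
            if prediction_corrected:
                pred = rec_pred[m]
                med = np.median(pred)
                scale = np.where(pred > 0, med / np.where(pred > 0, pred, 1.0), 1.0)
                obs = obs * scale
                sim = sim * scale[None, :]
            observed = {q: float(np.percentile(obs, q)) for q in percentiles}
            lo, hi = {}, {}
            for q in percentiles:
                sim_q = np.percentile(sim, q, axis=1)
                lo[q] = float(np.percentile(sim_q, 2.5))
                hi[q] = float(np.percentile(sim_q, 97.5))
            bins.append(VpcBin(time=float(t), n=int(m.sum()),
                               observed=observed, band_low=lo, band_high=hi))
        results[analyte] = VpcResult(analyte=analyte, bins=bins, n_sim=n_sim,
                                     prediction_corrected=prediction_corrected)
    return results


def plot_vpc(results: dict[str, VpcResult], path=None):
    """One panel per analyte: observed percentiles over simulated bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(results)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
    for ax, (analyte, res) in zip(axes[0], sorted(results.items())):
        t = [b.time for b in res.bins]
        for q, style in ((5, ":"), (50, "-"), (95, ":")):
            ax.plot(t, [b.observed[q] for b in res.bins], "k" + style, lw=1.2)
            ax.fill_between(t, [b.band_low[q] for b in res.bins],
                            [b.band_high[q] for b in res.bins], alpha=0.25)
        ax.set_title(analyte)
        ax.set_xlabel("time (h)")
    axes[0][0].set_ylabel("prediction-corrected concentration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
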