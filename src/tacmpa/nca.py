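"""Non-compartmental analysis of individual concentration-time profiles.

AUCs use the linear-up/log-down trapezoid (linear when the concentration
rises or either endpoint is zero, logarithmic when it falls between two
positive points).  The terminal slope lambda_z comes from a log-linear
regression over the best adjusted-R^2 window of at least three post-peak
points (Cmax excluded).  AUC_0-inf = AUC_last + C_last / lambda_z;
CL/F = dose / AUC_0-inf; Vz/F = CL/F / lambda_z.

Paired mono-versus-combination comparisons use a paired t-test when the
Shapiro-Wilk test does not reject normality of the within-subject
differences (alpha 0.05) and the Wilcoxon signed-rank test otherwise;
tmax is summarized as median (min-max) without a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TrialDataset
from .models import TAC_UNIT_FACTOR


@dataclass
class NCAResult:
    subject_id: str
    analyte: str
    cmax: float
    tmax: float
    auc_0_12: float
    auc_0_24: float
    auc_0_48: float
    auc_0_72: float
    auc_last: float
    auc_inf: float | None
    lambda_z: float | None
    extrapolated_fraction: float | None
    cl_f: float | None   # L/h
    vz_f: float | None   # L


@dataclass
class PairedComparison:
    parameter: str
    mean_mono: float
    sd_mono: float
    mean_combo: float
    sd_combo: float
    percent_change: float
    test: str            # "paired t" | "signed rank" | "none"
    p_value: float | None
    normality_p: float | None
    median_range_mono: tuple[float, float, float] | None = None
    median_range_combo: tuple[float, float, float] | None = None


def _trapezoid_linear_up_log_down(t, c) -> np.ndarray:
    """Per-interval AUC increments: linear on the way up / through zeros,
    logarithmic on the way down between positive concentrations."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    lin = 0.5 * (c0 + c1) * dt
    down = (c1 < c0) & (c1 > 0) & (c0 > 0)
    out = lin.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = (c0 - c1) / np.log(c0 / c1) * dt
    out[down] = logs[down]
    out[dt == 0] = 0.0
    return out


def _auc_to(t, c, upper: float) -> float:
    """AUC from t[0] to ``upper``; interpolates the final partial interval."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    if upper <= t[0]:
        return 0.0
    if upper >= t[-1]:
        return float(np.sum(_trapezoid_linear_up_log_down(t, c)))
    i = int(np.searchsorted(t, upper, side="right"))
    inc = _trapezoid_linear_up_log_down(t[:i], c[:i])
    total = float(np.sum(inc))
    t0, t1, c0, c1 = t[i - 1], t[i], c[i - 1], c[i]
    if t1 > t0 and upper > t0:
        if c1 < c0 and c0 > 0 and c1 > 0:  # log-down interpolation
            k = math.log(c0 / c1) / (t1 - t0)
            cu = c0 * math.exp(-k * (upper - t0))
            total += (c0 - cu) / k
        else:
            cu = c0 + (c1 - c0) * (upper - t0) / (t1 - t0)
            total += 0.5 * (c0 + cu) * (upper - t0)
    return total


def _terminal_slope(t, c, tmax_idx: int):
    """lambda_z by best adjusted-R^2 log-linear regression over terminal windows.

    Candidate windows end at the last positive point and start after Cmax
    (Cmax itself excluded) with at least three points.  Returns
    (lambda_z, n_points) or (None, 0) if no window gives a positive slope.
    """
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    pos = c > 0
    idx = np.nonzero(pos)[0]
    idx = idx[idx > tmax_idx]
    if len(idx) < 3:
        return None, 0
    best = None
    for start in range(len(idx) - 2):
        sel = idx[start:]
        x, y = t[sel], np.log(c[sel])
        n = len(sel)
        slope, intercept, r, *_ = stats.linregress(x, y)
        if slope >= 0:
            continue
        r2 = r * r
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, n)
    if best is None:
        return None, 0
    return best[1], best[2]


def compute_nca(times, concentrations, dose_mg: float, analyte: str,
                subject_id: str = "") -> NCAResult:
    """NCA of one profile; ``dose_mg`` in mg, concentrations in analyte units.

    Cmax/tmax are taken from the observed points (earliest time on ties).
    CL/F is unit-converted to L/h (TAC is measured in ng/mL, so its AUC is
    divided by 1000 to reach mg·h/L).  When no valid terminal slope exists,
    auc_inf, cl_f and vz_f are reported missing (None).
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    if len(t) < 2:
        raise ValueError("need at least two points")
    tmax_idx = int(np.argmax(c))  # np.argmax takes the first maximum
    cmax = float(c[tmax_idx])
    tmax = float(t[tmax_idx])
    auc_last = float(np.sum(_trapezoid_linear_up_log_down(t, c)))
    partial = {u: _auc_to(t, c, u) for u in (12.0, 24.0, 48.0, 72.0)}
    lz, _n = _terminal_slope(t, c, tmax_idx)
    c_last = float(c[np.nonzero(c > 0)[0][-1]]) if np.any(c > 0) else 0.0
    if lz is not None and lz > 0 and c_last > 0:
        auc_inf = auc_last + c_last / lz
        frac = 1.0 - auc_last / auc_inf
        unit = TAC_UNIT_FACTOR if analyte == "TAC" else 1.0  # ng/mL -> mg/L
        cl_f = dose_mg / (auc_inf / unit)
        vz_f = cl_f / lz
    else:
        auc_inf = frac = cl_f = vz_f = None
        lz = None
    return NCAResult(subject_id=subject_id, analyte=analyte, cmax=cmax,
                     tmax=tmax, auc_0_12=partial[12.0], auc_0_24=partial[24.0],
                     auc_0_48=partial[48.0], auc_0_72=partial[72.0],
                     auc_last=auc_last, auc_inf=auc_inf, lambda_z=lz,
                     extrapolated_fraction=frac, cl_f=cl_f, vz_f=vz_f)


def profile_from_dataset(ds: TrialDataset, subject_id: str, period: int,
                         analyte: str) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time, concentration) pairs for NCA.

    BLQ samples are excluded, except a BLQ/zero predose sample which is kept
    as a zero-concentration anchor at t=0.
    """
    pts = []
    for r in ds.records:
        if (r.subject_id == subject_id and r.period == period
                and r.event_type == "observation" and r.drug_or_analyte == analyte
                and not r.missing and r.value is not None):
            if r.is_blq:
                if r.time == 0.0:
                    pts.append((0.0, 0.0))
                continue
            pts.append((r.time, r.value))
    pts.sort()
    if not pts:
        return np.empty(0), np.empty(0)
    t, c = map(np.asarray, zip(*pts))
    return t.astype(float), c.astype(float)


def nca_by_period(ds: TrialDataset, analyte: str, period: int,
                  dose_mg: float) -> list[NCAResult]:
    out = []
    for sid in ds.subject_ids():
        t, c = profile_from_dataset(ds, sid, period, analyte)
        if len(t) < 3:
            continue
        out.append(compute_nca(t, c, dose_mg, analyte, subject_id=sid))
    return out


_COMPARED = ("cmax", "auc_0_12", "auc_0_24", "auc_0_48", "auc_0_72",
             "auc_inf", "cl_f")


def compare_periods(mono: list[NCAResult], combo: list[NCAResult],
                    parameters: tuple[str, ...] = _COMPARED,
                    alpha: float = 0.05) -> list[PairedComparison]:
    """Paired mono-vs-combination comparison of NCA parameters.

    Subjects present in both arms with non-missing values are paired.
    Normality of the paired differences is gated by Shapiro-Wilk at
    ``alpha``; tmax is always summarized as median (min-max) without a test.
    Raises for fewer than 3 complete pairs.
    """
    mono_by = {r.subject_id: r for r in mono}
    combo_by = {r.subject_id: r for r in combo}
    shared = sorted(set(mono_by) & set(combo_by))
    out = []
    for par in parameters:
        pairs = [(getattr(mono_by[s], par), getattr(combo_by[s], par))
                 for s in shared
                 if getattr(mono_by[s], par) is not None
                 and getattr(combo_by[s], par) is not None]
        if len(pairs) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {par}")
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        diff = b - a
        if np.allclose(diff, 0.0):
            test, p, norm_p = "paired t", 1.0, None
        else:
            norm_p = float(stats.shapiro(diff).pvalue)
            if norm_p >= alpha:
                test = "paired t"
                p = float(stats.ttest_rel(b, a).pvalue)
            else:
                test = "signed rank"
                p = float(stats.wilcoxon(b, a).pvalue)
        out.append(PairedComparison(
            parameter=par, mean_mono=float(a.mean()), sd_mono=float(a.std(ddof=1)),
            mean_combo=float(b.mean()), sd_combo=float(b.std(ddof=1)),
            percent_change=percent_change(float(a.mean()), float(b.mean())),
            test=test, p_value=p, normality_p=norm_p))
    # tmax: median (min-max), no p value
    tm = np.array([mono_by[s].tmax for s in shared])
    tc = np.array([combo_by[s].tmax for s in shared])
    out.append(PairedComparison(
        parameter="tmax", mean_mono=float(tm.mean()), sd_mono=float(tm.std(ddof=1)),
        mean_combo=float(tc.mean()), sd_combo=float(tc.std(ddof=1)),
        percent_change=percent_change(float(tm.mean()), float(tc.mean())),
        test="none", p_value=None, normality_p=None,
        median_range_mono=(float(np.median(tm)), float(tm.min()), float(tm.max())),
        median_range_combo=(float(np.median(tc)), float(tc.min()), float(tc.max()))))
    return out


def percent_change(mean_mono: float, mean_combo: float) -> float:
    """(combo - mono) / mono * 100."""
    return (mean_combo - mean_mono) / mean_mono * 100.0


def summary_table(comparisons: list[PairedComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "parameter": c.parameter,
            "mono_mean": c.mean_mono, "mono_sd": c.sd_mono,
            "combo_mean": c.mean_combo, "combo_sd": c.sd_combo,
            "percent_change": c.percent_change,
            "test": c.test, "p_value": c.p_value,
        })
    return pd.DataFrame(rows)
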