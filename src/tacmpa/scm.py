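"""Stepwise covariate modelling (SCM) on apparent clearance and volume.

Candidate covariate-parameter relations (linear, power, exponential for
continuous covariates centred on their medians; a fold factor for binary
covariates) are screened by greedy forward inclusion and stricter backward
elimination, with nested models compared by the likelihood-ratio test on
the OFV: inclusion requires dOFV > 3.84 (chi-square, df=1, p < 0.05) and
retention during backward elimination requires dOFV > 6.63 (p < 0.01).
Both thresholds are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import chi2


@dataclass(frozen=True)
class CovariateCandidate:
    """One covariate-parameter relation to screen.

    ``reference`` is the centring value (the population median) for
    continuous forms; binary covariates use the fold form with reference 0.
    ``initial`` is the starting value of the effect parameter: 0 leaves
    linear/power/exponential multipliers at 1, fold starts at 1.
    """

    target: str           # model parameter, e.g. "cl_tac" or "v2"
    covariate: str        # covariate column, e.g. "WT", "CYP3A5"
    form: str             # "linear" | "power" | "exponential" | "binary-fold"
    reference: float = 0.0
    initial: float = 0.0

    def __post_init__(self):
        if self.form not in ("linear", "power", "exponential", "binary-fold"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "binary-fold" and self.initial == 0.0:
            object.__setattr__(self, "initial", 1.0)

    @property
    def theta_name(self) -> str:
        return f"beta_{self.target}_{self.covariate}_{self.form}"


def covariate_multiplier(candidate: CovariateCandidate, theta_cov: float,
                         value: float) -> float:
    """Dimensionless factor the covariate contributes to its target parameter.

    linear: 1 + theta*(x - ref); power: (x/ref)^theta;
    exponential: exp(theta*(x - ref)); binary-fold: theta^x with x in {0,1}.
    All forms equal 1 at the reference (or at x=0 for binary).
    """
    if candidate.form == "linear":
        return 1.0 + theta_cov * (value - candidate.reference)
    if candidate.form == "power":
        if value <= 0 or candidate.reference <= 0:
            raise ValueError("power form requires positive covariate and reference")
        return (value / candidate.reference) ** theta_cov
    if candidate.form == "exponential":
        return math.exp(theta_cov * (value - candidate.reference))
    return theta_cov ** value  # binary-fold


FORWARD_DOFV = 3.84   # chi2(1) at p=0.05
BACKWARD_DOFV = 6.63  # chi2(1) at p=0.01


def lrt_decision(ofv_reduced: float, ofv_full: float, df: int = 1,
                 stage: str = "forward") -> tuple[bool, float]:
    """Likelihood-ratio decision for one nested comparison.

    Returns (significant, dOFV) with dOFV = OFV(reduced) - OFV(full).
    Strict inequality at both thresholds; df > 1 uses the matching
    chi-square quantile.  A negative forward dOFV is treated as not
    significant (with a warning-free pass, the caller may log it).
    """
    if stage not in ("forward", "backward"):
        raise ValueError(f"unknown stage {stage!r}")
    if not (math.isfinite(ofv_reduced) and math.isfinite(ofv_full)):
        raise ValueError("OFV values must be finite")
    dofv = ofv_reduced - ofv_full
    alpha = 0.05 if stage == "forward" else 0.01
    threshold = FORWARD_DOFV if stage == "forward" else BACKWARD_DOFV
    if df != 1:
        threshold = chi2.ppf(1.0 - alpha, df)
    return dofv > threshold, dofv


@dataclass
class ScmStep:
    stage: str
    candidate: CovariateCandidate
    dofv: float
    decision: str  # "included" | "rejected" | "retained" | "removed" | "skipped"


@dataclass
class ScmTrace:
    steps: list[ScmStep] = field(default_factory=list)
    selected: list[CovariateCandidate] = field(default_factory=list)
    final_ofv: float = math.nan


def run_scm(dataset, candidates: list[CovariateCandidate], fitter,
            max_forward_steps: int | None = None) -> ScmTrace:
    """Greedy forward inclusion then backward elimination.

    ``fitter(dataset, selected)`` must refit the model with the given
    covariate set and return its OFV (float).  At each forward step the
    candidate with the largest dOFV above 3.84 enters (ties broken by
    declaration order); only one functional form per (target, covariate)
    pair may be selected.  Backward elimination then removes, one at a time,
    the covariate whose removal costs the least, as long as its dOFV is not
    above 6.63.  Candidates whose fit fails are skipped with a trace entry.
    """
    trace = ScmTrace()
    selected: list[CovariateCandidate] = []
    base_ofv = fitter(dataset, tuple(selected))
    remaining = list(candidates)

    steps_left = max_forward_steps if max_forward_steps is not None else len(candidates)
    while remaining and steps_left > 0:
        results = []
        for cand in remaining:
            try:
                ofv = fitter(dataset, tuple(selected + [cand]))
            except Exception:
                trace.steps.append(ScmStep("forward", cand, math.nan, "skipped"))
                continue
            _, dofv = lrt_decision(base_ofv, ofv, stage="forward")
            results.append((dofv, cand, ofv))
        if not results:
            break
        best_dofv, best_cand, best_ofv = max(results, key=lambda r: r[0])
        significant, _ = lrt_decision(base_ofv, best_ofv, stage="forward")
        for dofv, cand, _ in results:
            if cand is not best_cand:
                trace.steps.append(ScmStep("forward", cand, dofv, "rejected"))
        if not significant:
            trace.steps.append(ScmStep("forward", best_cand, best_dofv, "rejected"))
            break
        trace.steps.append(ScmStep("forward", best_cand, best_dofv, "included"))
        selected.append(best_cand)
        base_ofv = best_ofv
        # one functional form per (target, covariate) pair
        remaining = [c for c in remaining
                     if (c.target, c.covariate) != (best_cand.target, best_cand.covariate)]
        steps_left -= 1

    # backward elimination at the stricter threshold
    changed = True
    while changed and selected:
        changed = False
        worst = None  # (dofv, candidate, reduced_ofv)
        for cand in selected:
            reduced = [c for c in selected if c is not cand]
            try:
                ofv_reduced = fitter(dataset, tuple(reduced))
            except Exception:
                trace.steps.append(ScmStep("backward", cand, math.nan, "skipped"))
                continue
            retain, dofv = lrt_decision(ofv_reduced, base_ofv, stage="backward")
            if not retain and (worst is None or dofv < worst[0]):
                worst = (dofv, cand, ofv_reduced)
            elif retain:
                trace.steps.append(ScmStep("backward", cand, dofv, "retained"))
        if worst is not None:
            dofv, cand, ofv_reduced = worst
            trace.steps.append(ScmStep("backward", cand, dofv, "removed"))
            selected = [c for c in selected if c is not cand]
            base_ofv = ofv_reduced
            changed = True

    trace.selected = selected
    trace.final_ofv = base_ofv
    return trace


def make_nlme_fitter(spec, settings, kind: str = "tac"):
    """Default fitter: refit the population model with the candidate set."""
    from .estimation import fit_population  # deferred: avoids import cycle

    def fitter(dataset, selected):
        fit = fit_population(dataset, spec, settings, kind=kind,
                             covariate_effects=tuple(selected))
        return fit.ofv

    return fitter
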