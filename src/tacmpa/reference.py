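"""Published population estimates of the healthy-volunteer TAC-MMF study.

Two parameter columns were reported: the *independent* models (TAC alone and
MMF alone, fitted separately to the single-drug periods) and the *integrated*
model (both drugs, with the exponential MPA-on-TAC-clearance interaction).
Interindividual variability was reported as CV%, converted here to log-normal
variances via omega^2 = ln(1 + CV^2).  Residual sigmas are standard
deviations (proportional term dimensionless, additive term in analyte units).

These constants parameterize the synthetic-trial generator and serve as
ground truth for simulation-estimation (recovery) experiments.
"""

from __future__ import annotations

import math

from .models import (IntegratedModelSpec, InteractionSpec, MpaStructuralParams,
                     RandomEffectsSpec, ResidualModel, ResidualSpec,
                     TacStructuralParams)

# study design constants
TAC_DOSE_MG = 5.0
MMF_DOSE_MG = 1000.0
SAMPLING_TIMES_H = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0, 168.0)
CYP3A5_EXPRESSER_PROB = 0.235  # 4 of 17 subjects


def omega2_from_cv(cv: float) -> float:
    """Log-normal variance from a coefficient of variation (fraction, not %)."""
    return math.log(1.0 + cv * cv)


def independent_spec() -> IntegratedModelSpec:
    """Single-drug model estimates (TAC-alone and MMF-alone columns)."""
    return IntegratedModelSpec(
        tac=TacStructuralParams(cl=17.8, v2=108.0, ka=3.75, k23=0.326,
                                k32=0.069, tlag=0.627, cyp3a5_fold=1.26),
        mpa=MpaStructuralParams(cl=16.1, v5=16.8, ka=2.06, k56=1.33, k65=0.109,
                                ehc_frac=0.427, k70=0.256, v7=5.13, k84=263.0,
                                mtime1=7.99),
        interaction=InteractionSpec(form="exponential", slope=0.0),
        iiv=RandomEffectsSpec({
            "cl_tac": omega2_from_cv(0.509),
            "v2": omega2_from_cv(0.444),
            "ka_tac": omega2_from_cv(1.60),
            "cl_mpa": omega2_from_cv(0.259),
            "v5": omega2_from_cv(0.409),
            "ka_mpa": omega2_from_cv(0.697),
            "ehc_frac": omega2_from_cv(0.301),
        }),
        residual=ResidualSpec({
            "TAC": ResidualModel("prop", sigma_prop=0.131),
            "MPA": ResidualModel("prop", sigma_prop=0.516),
            "MPAG": ResidualModel("add+prop", sigma_prop=0.172, sigma_add=0.186),
            "AcMPAG": ResidualModel("prop", sigma_prop=0.654),
        }),
    )


def integrated_spec() -> IntegratedModelSpec:
    """Combination-model estimates with the exponential interaction (slope 0.0294)."""
    return IntegratedModelSpec(
        tac=TacStructuralParams(cl=13.8, v2=93.0, ka=1.78, k23=0.313,
                                k32=0.0719, tlag=0.59, cyp3a5_fold=1.48),
        mpa=MpaStructuralParams(cl=16.3, v5=19.7, ka=2.29, k56=1.12, k65=0.131,
                                ehc_frac=0.367, k70=0.251, v7=5.83, k84=18.4,
                                mtime1=7.96),
        interaction=InteractionSpec(form="exponential", slope=0.0294),
        iiv=RandomEffectsSpec({
            "cl_tac": omega2_from_cv(0.264),
            "v2": omega2_from_cv(0.308),
            "ka_tac": omega2_from_cv(0.93),
            "cl_mpa": omega2_from_cv(0.187),
            "v5": omega2_from_cv(0.182),
            "ka_mpa": omega2_from_cv(0.566),
            "ehc_frac": omega2_from_cv(0.355),
        }),
        residual=ResidualSpec({
            "TAC": ResidualModel("prop", sigma_prop=0.131),
            "MPA": ResidualModel("prop", sigma_prop=0.524),
            "MPAG": ResidualModel("add+prop", sigma_prop=0.237, sigma_add=0.104),
            "AcMPAG": ResidualModel("prop", sigma_prop=0.651),
        }),
    )
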