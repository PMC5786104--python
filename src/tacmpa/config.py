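"""YAML model-specification files.

A spec file carries the fixed effects under their conventional symbol names
(cl_tac, v2, ka_tac, k23, k32, tlag, cyp3a5_fold; cl_mpa, v5, ka_mpa, k56,
k65, f_mpag, ehc_frac, k70, v7, k84, mtime1, mtime2, v9, k90), the
interaction form and parameters, IIV variances, residual-error models per
analyte, and an optional ``fixed`` list naming parameters to hold at their
stated values during estimation (f_mpag, mtime2, v9 and k90 are fixed by
convention in this analysis).
"""

from __future__ import annotations

import yaml

from .models import (IntegratedModelSpec, InteractionSpec, MpaStructuralParams,
                     RandomEffectsSpec, ResidualModel, ResidualSpec,
                     TacStructuralParams)

DEFAULT_FIXED = ("f_mpag", "mtime2", "v9", "k90")


def spec_to_dict(spec: IntegratedModelSpec,
                 fixed: tuple[str, ...] = DEFAULT_FIXED) -> dict:
    t, m, i = spec.tac, spec.mpa, spec.interaction
    return {
        "tacrolimus": {"cl_tac": t.cl, "v2": t.v2, "ka_tac": t.ka,
                       "k23": t.k23, "k32": t.k32, "tlag": t.tlag,
                       "cyp3a5_fold": t.cyp3a5_fold},
        "mycophenolate": {"cl_mpa": m.cl, "v5": m.v5, "ka_mpa": m.ka,
                          "k56": m.k56, "k65": m.k65, "f_mpag": m.f_mpag,
                          "ehc_frac": m.ehc_frac, "k70": m.k70, "v7": m.v7,
                          "k84": m.k84, "mtime1": m.mtime1, "mtime2": m.mtime2,
                          "v9": m.v9, "k90": m.k90},
        "interaction": {"form": i.form, "slope": i.slope, "emax": i.emax,
                        "ec50": i.ec50},
        "iiv_omega2": dict(spec.iiv.omega2),
        "residual": {a: {"model": r.model, "sigma_prop": r.sigma_prop,
                         "sigma_add": r.sigma_add}
                     for a, r in spec.residual.per_analyte.items()},
        "fixed": list(fixed),
    }


def spec_from_dict(d: dict) -> tuple[IntegratedModelSpec, frozenset]:
    t, m, i = d["tacrolimus"], d["mycophenolate"], d.get("interaction", {})
    spec = IntegratedModelSpec(
        tac=TacStructuralParams(cl=t["cl_tac"], v2=t["v2"], ka=t["ka_tac"],
                                k23=t["k23"], k32=t["k32"], tlag=t["tlag"],
                                cyp3a5_fold=t.get("cyp3a5_fold", 1.0)),
        mpa=MpaStructuralParams(cl=m["cl_mpa"], v5=m["v5"], ka=m["ka_mpa"],
                                k56=m["k56"], k65=m["k65"],
                                f_mpag=m.get("f_mpag", 0.85),
                                ehc_frac=m["ehc_frac"], k70=m["k70"],
                                v7=m["v7"], k84=m["k84"], mtime1=m["mtime1"],
                                mtime2=m.get("mtime2", 1.0),
                                v9=m.get("v9", 23.0), k90=m.get("k90", 2.15)),
        interaction=InteractionSpec(form=i.get("form", "exponential"),
                                    slope=i.get("slope", 0.0),
                                    emax=i.get("emax", 0.0),
                                    ec50=i.get("ec50", 1.0)),
        iiv=RandomEffectsSpec(dict(d.get("iiv_omega2", {}))),
        residual=ResidualSpec({a: ResidualModel(model=r["model"],
                                                sigma_prop=r.get("sigma_prop", 0.0),
                                                sigma_add=r.get("sigma_add", 0.0))
                               for a, r in d.get("residual", {}).items()}),
    )
    return spec, frozenset(d.get("fixed", DEFAULT_FIXED))


def save_spec(spec: IntegratedModelSpec, path,
              fixed: tuple[str, ...] = DEFAULT_FIXED) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec, fixed), fh, sort_keys=False)


def load_spec(path) -> tuple[IntegratedModelSpec, frozenset]:
    """Returns (spec, fixed-parameter set)."""
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
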