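"""Event-record datasets for a three-period single-dose crossover PK trial.

The in-memory containers mirror the NONMEM event-table idiom (dose and
observation rows keyed by subject / period / time) for a trial in which
subjects receive mycophenolate mofetil (MMF) alone, tacrolimus (TAC) alone,
and then the combination, with whole-blood TAC and plasma MPA / MPAG /
AcMPAG concentrations measured on a fixed sampling grid.

Units convention: doses are administered salt/ester amounts in mg (no
MMF-to-MPA molar conversion; apparent "/F" parameters absorb it), TAC
concentrations are ng/mL (whole blood) and MPA-family concentrations are
ug/mL (plasma).  Internally amounts are mg and volumes L, so a predicted
mg/L equals ug/mL directly, with a factor 1000 for TAC only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import pandas as pd

ANALYTES = ("TAC", "MPA", "MPAG", "AcMPAG")
DOSE_LABELS = ("MMF-dose", "TAC-dose")

#: CSV column order of the on-disk event-table dialect.
CSV_COLUMNS = [
    "ID", "PERIOD", "TIME", "EVID", "ANALYTE", "AMT", "DV", "MDV", "BLQ",
    "CYP3A5", "AGE", "WT", "HT", "SCR", "GFR", "HGB", "HCT", "ALB",
    "TBIL", "ANC",
]

_COVARIATE_COLS = {
    "CYP3A5": "cyp3a5_expresser", "AGE": "age", "WT": "weight",
    "HT": "height", "SCR": "scr", "GFR": "gfr", "HGB": "hgb",
    "HCT": "hct", "ALB": "albumin", "TBIL": "tbil", "ANC": "anc",
}


@dataclass(frozen=True)
class AnalyteSpec:
    """Assay specification of one analyte (matrix, units, quantification range)."""

    name: str
    matrix: str  # "whole-blood" | "plasma"
    units: str   # "ng/mL" | "ug/mL"
    lloq: float
    uloq: float

    def __post_init__(self):
        if self.name not in ANALYTES:
            raise ValueError(f"unknown analyte {self.name!r}")
        if not self.lloq > 0:
            raise ValueError("lloq must be > 0")
        if not self.uloq > self.lloq:
            raise ValueError("uloq must exceed lloq")


def default_analyte_specs() -> dict[str, AnalyteSpec]:
    """Validated assay ranges of the study: TAC 0.5-100 ng/mL (whole blood);
    MPA and MPAG 0.1-100 and AcMPAG 0.2-20 ug/mL (acidified plasma)."""
    return {
        "TAC": AnalyteSpec("TAC", "whole-blood", "ng/mL", 0.5, 100.0),
        "MPA": AnalyteSpec("MPA", "plasma", "ug/mL", 0.1, 100.0),
        "MPAG": AnalyteSpec("MPAG", "plasma", "ug/mL", 0.1, 100.0),
        "AcMPAG": AnalyteSpec("AcMPAG", "plasma", "ug/mL", 0.2, 20.0),
    }


@dataclass
class EventRecord:
    """One dose or observation row.

    ``time`` is hours after the first dose of the record's period (each
    period restarts at t=0; washouts are assumed complete, so periods are
    independent).  Doses carry ``amount`` (mg); observations carry ``value``
    in the analyte's units, with ``is_blq`` marking detectable-but-below-LLOQ
    values (the measured value is retained for audit).
    """

    subject_id: str
    period: int
    time: float
    event_type: str          # "dose" | "observation"
    drug_or_analyte: str     # dose label or analyte name
    amount: float | None = None
    value: float | None = None
    is_blq: bool = False
    missing: bool = False


@dataclass
class SubjectCovariates:
    subject_id: str
    cyp3a5_expresser: int
    age: float
    weight: float
    height: float
    scr: float
    gfr: float
    hgb: float
    hct: float
    albumin: float
    tbil: float
    anc: float


@dataclass
class TrialDataset:
    """Sorted event records plus per-subject covariates and analyte specs."""

    records: list[EventRecord]
    covariates: dict[str, SubjectCovariates]
    analyte_specs: dict[str, AnalyteSpec] = field(default_factory=default_analyte_specs)

    def __post_init__(self):
        self.records = sorted(
            self.records,
            key=lambda r: (r.subject_id, r.period, r.time, r.event_type == "observation", r.drug_or_analyte),
        )

    def observations(self) -> list[EventRecord]:
        return [r for r in self.records if r.event_type == "observation"]

    def doses(self) -> list[EventRecord]:
        return [r for r in self.records if r.event_type == "dose"]

    def subject_ids(self) -> list[str]:
        return sorted({r.subject_id for r in self.records})


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


def validate_dataset(ds: TrialDataset) -> ValidationReport:
    """Check every dataset invariant; an empty report means well-formed.

    Errors reported: negative times, malformed dose/observation payloads,
    observations for analytes without an :class:`AnalyteSpec`, observations
    in a period with no dose record, missing covariates, and duplicate
    (subject, period, time, analyte) observation keys.
    """
    rep = ValidationReport()
    dosed: set[tuple[str, int]] = set()
    for r in ds.records:
        if r.event_type == "dose":
            dosed.add((r.subject_id, r.period))

    seen_obs: set[tuple[str, int, float, str]] = set()
    for r in ds.records:
        tag = f"subject {r.subject_id} period {r.period} t={r.time} {r.drug_or_analyte}"
        if r.time < 0:
            rep.errors.append(f"negative time: {tag}")
        if r.event_type == "dose":
            if r.drug_or_analyte not in DOSE_LABELS:
                rep.errors.append(f"unknown dose label: {tag}")
            if r.amount is None or not r.amount > 0:
                rep.errors.append(f"dose without positive amount: {tag}")
            if r.value is not None:
                rep.errors.append(f"dose carries a DV value: {tag}")
        elif r.event_type == "observation":
            if r.drug_or_analyte not in ds.analyte_specs:
                rep.errors.append(f"observation for analyte without spec: {tag}")
            if not (r.missing or r.is_blq or (r.value is not None and r.value >= 0)):
                rep.errors.append(f"observation without usable value: {tag}")
            if r.value is not None and r.value < 0:
                rep.errors.append(f"negative concentration: {tag}")
            if (r.subject_id, r.period) not in dosed:
                rep.errors.append(f"observation in undosed period: {tag}")
            key = (r.subject_id, r.period, r.time, r.drug_or_analyte)
            if key in seen_obs:
                rep.errors.append(f"duplicate observation key: {tag}")
            seen_obs.add(key)
        else:
            rep.errors.append(f"unknown event type {r.event_type!r}: {tag}")

    for sid in {r.subject_id for r in ds.records}:
        if sid not in ds.covariates:
            rep.errors.append(f"subject {sid} has no covariate row")
    for sid, cov in ds.covariates.items():
        if cov.cyp3a5_expresser not in (0, 1):
            rep.errors.append(f"subject {sid}: cyp3a5_expresser must be 0/1")
        for f in dataclasses.fields(cov):
            if f.name in ("subject_id", "cyp3a5_expresser"):
                continue
            v = getattr(cov, f.name)
            if not v > 0:
                rep.errors.append(f"subject {sid}: covariate {f.name} not positive")
    return rep


def censor_blq(ds: TrialDataset) -> tuple[TrialDataset, dict[str, float]]:
    """Flag detectable observations below the LLOQ; return BLQ fractions.

    An observation with ``0 < value < lloq`` is flagged ``is_blq`` (the value
    itself is retained).  A value exactly equal to the LLOQ is quantifiable
    and is kept unflagged.  Idempotent: flags are only ever set, never
    cleared.  Returns the new dataset and, per analyte, the fraction of
    observations flagged (flagged / total, counting pre-existing flags).
    """
    new_records = []
    flagged: dict[str, int] = {a: 0 for a in ds.analyte_specs}
    total: dict[str, int] = {a: 0 for a in ds.analyte_specs}
    for r in ds.records:
        if r.event_type != "observation" or r.missing:
            new_records.append(replace(r))
            continue
        spec = ds.analyte_specs.get(r.drug_or_analyte)
        if spec is None:
            raise ValueError(f"no analyte spec for {r.drug_or_analyte!r}")
        if r.value is not None and r.value < 0:
            raise ValueError(
                f"negative concentration for subject {r.subject_id} "
                f"t={r.time} {r.drug_or_analyte}"
            )
        blq = r.is_blq or (r.value is not None and 0 < r.value < spec.lloq)
        total[r.drug_or_analyte] += 1
        flagged[r.drug_or_analyte] += int(blq)
        new_records.append(replace(r, is_blq=blq))
    fractions = {
        a: (flagged[a] / total[a]) if total[a] else 0.0 for a in ds.analyte_specs
    }
    return TrialDataset(new_records, dict(ds.covariates), dict(ds.analyte_specs)), fractions


def to_frame(ds: TrialDataset) -> pd.DataFrame:
    """Render the dataset as a NONMEM-style event table (one row per event)."""
    rows = []
    for r in ds.records:
        cov = ds.covariates[r.subject_id]
        rows.append({
            "ID": r.subject_id,
            "PERIOD": r.period,
            "TIME": r.time,
            "EVID": 1 if r.event_type == "dose" else 0,
            "ANALYTE": r.drug_or_analyte,
            "AMT": r.amount if r.event_type == "dose" else None,
            "DV": r.value if r.event_type == "observation" else None,
            "MDV": int(r.missing or r.event_type == "dose"),
            "BLQ": int(r.is_blq),
            **{col: getattr(cov, attr) for col, attr in _COVARIATE_COLS.items()},
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_dataset(ds: TrialDataset, path) -> None:
    """Write the CSV event-table dialect; missing numeric cells become '.'."""
    df = to_frame(ds)
    # %.17g guarantees binary round-trip of float64 concentrations
    df.to_csv(path, index=False, na_rep=".", float_format="%.17g")


def read_dataset(path, analyte_specs: dict[str, AnalyteSpec] | None = None) -> TrialDataset:
    """Read the CSV event-table dialect written by :func:`write_dataset`.

    Raises ``ValueError`` naming the offending column or line for malformed
    headers, non-numeric fields and unknown analytes.
    """
    specs = analyte_specs or default_analyte_specs()
    df = pd.read_csv(path, dtype={"ID": str}, na_values=["."],
                     keep_default_na=False, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dataset file {path} is missing columns: {missing_cols}")
    for col in CSV_COLUMNS:
        if col in ("ID", "ANALYTE"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col}: {exc}") from exc

    records: list[EventRecord] = []
    covariates: dict[str, SubjectCovariates] = {}
    for i, row in df.iterrows():
        label = str(row["ANALYTE"])
        evid = int(row["EVID"])
        if evid == 1:
            if label not in DOSE_LABELS:
                raise ValueError(f"line {i + 2}: unknown dose label {label!r}")
            rec = EventRecord(str(row["ID"]), int(row["PERIOD"]), float(row["TIME"]),
                              "dose", label, amount=float(row["AMT"]))
        else:
            if label not in specs:
                raise ValueError(f"line {i + 2}: unknown analyte {label!r}")
            mdv = bool(row["MDV"])
            dv = row["DV"]
            rec = EventRecord(str(row["ID"]), int(row["PERIOD"]), float(row["TIME"]),
                              "observation", label,
                              value=None if pd.isna(dv) else float(dv),
                              is_blq=bool(row["BLQ"]), missing=mdv)
        records.append(rec)
        sid = str(row["ID"])
        if sid not in covariates:
            covariates[sid] = SubjectCovariates(
                subject_id=sid,
                cyp3a5_expresser=int(row["CYP3A5"]),
                **{attr: float(row[col]) for col, attr in _COVARIATE_COLS.items()
                   if attr != "cyp3a5_expresser"},
            )
    return TrialDataset(records, covariates, specs)
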