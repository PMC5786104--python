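import pytest

from tacmpa import reference
from tacmpa.dataset import (EventRecord, SubjectCovariates, TrialDataset,
                            default_analyte_specs)
from tacmpa.simulate import TrialDesign, generate_trial


def make_covariates(sid: str, expresser: int = 0) -> SubjectCovariates:
    return SubjectCovariates(subject_id=sid, cyp3a5_expresser=expresser,
                             age=25.0, weight=70.0, height=173.0, scr=0.9,
                             gfr=100.0, hgb=15.0, hct=44.0, albumin=4.5,
                             tbil=0.8, anc=3000.0)


@pytest.fixture
def toy_dataset() -> TrialDataset:
    """Two subjects, one TAC-alone period each, well formed."""
    records = []
    for sid in ("1", "2"):
        records.append(EventRecord(sid, 2, 0.0, "dose", "TAC-dose", amount=5.0))
        for t, v in ((1.0, 20.0), (4.0, 10.0), (24.0, 2.0)):
            records.append(EventRecord(sid, 2, t, "observation", "TAC", value=v))
    covs = {sid: make_covariates(sid) for sid in ("1", "2")}
    return TrialDataset(records, covs, default_analyte_specs())


@pytest.fixture(scope="session")
def small_tac_trial() -> TrialDataset:
    """A 12-subject TAC-alone trial simulated at the published single-drug
    estimates (shared across tests; treat as read-only)."""
    design = TrialDesign(n_subjects=12, periods=(2,))
    return generate_trial(design, reference.independent_spec(), seed=2024)


@pytest.fixture(scope="session")
def crossover_trial() -> TrialDataset:
    """An 8-subject full three-period crossover at the integrated estimates."""
    design = TrialDesign(n_subjects=8)
    return generate_trial(design, reference.integrated_spec(), seed=7)
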