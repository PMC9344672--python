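"""Shared fixtures and builders for constructed cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pmrelapse import CohortConfig, generate_cohort

BASE = pd.Timestamp("2015-01-01")

PATIENT_DEFAULTS = dict(
    age=66.0, sex="female", cvd_history=False, malignancy_history=False,
    smoking="never", symptom_duration_weeks=14.0, severity_score=4,
    arthritis=False, systemic_symptoms=False, crp=29.0, esr=37.0, hb=8.2,
    meets_eular_acr_core=True,
)

VISIT_FLAG_DEFAULTS = dict(
    rj_not_in_remission=False, rj_interval_relapse=False,
    dose_increased_since_prev=False, dmard_intensified_for_inefficacy=False,
    gc_injection_added=False,
)


def make_patient(patient_id="P1", followup_end=2000, **overrides) -> dict:
    row = dict(patient_id=patient_id, baseline_date=BASE,
               followup_end_date=BASE + pd.Timedelta(days=followup_end))
    row.update(PATIENT_DEFAULTS)
    row.update(overrides)
    return row


def make_cohort(visit_specs, patient_id="P1", followup_end=2000,
                **patient_overrides) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-patient cohort from a list of visit dicts with at least day & dose."""
    patients = pd.DataFrame([make_patient(patient_id, followup_end,
                                          **patient_overrides)])
    rows = []
    for spec in visit_specs:
        row = dict(patient_id=patient_id,
                   visit_date=BASE + pd.Timedelta(days=spec["day"]),
                   pred_dose=float(spec["dose"]))
        row.update(VISIT_FLAG_DEFAULTS)
        row.update({k: v for k, v in spec.items() if k not in ("day", "dose")})
        rows.append(row)
    visits = pd.DataFrame(rows)
    return patients, visits


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort under default generator settings."""
    cfg = CohortConfig(n_patients=300, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_patients():
    """A cohort with missingness disabled (fully observed covariates)."""
    cfg = CohortConfig(n_patients=300, seed=43,
                       missing_rates={k: 0.0 for k in
                                      ("smoking", "symptom_duration", "crp", "esr", "hb")})
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
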