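"""Longitudinal data model, table IO and visit-eligibility rules.

The in-memory containers are two pandas DataFrames:

``patients`` — one row per patient with baseline covariates measured before
glucocorticoid treatment started, plus the follow-up window:
``patient_id, baseline_date, age, sex, cvd_history, malignancy_history,
smoking, symptom_duration_weeks, severity_score, arthritis, systemic_symptoms,
crp, esr, hb, meets_eular_acr_core, followup_end_date``.

``visits`` — one row per dated encounter:
``patient_id, visit_date, pred_dose, rj_not_in_remission, rj_interval_relapse,
dose_increased_since_prev, dmard_intensified_for_inefficacy,
gc_injection_added``.

On disk both are plain CSV with a header row, ISO-8601 dates, booleans as 0/1
and the empty string for missing values.  ``pred_dose`` is the oral
prednisolone dose (mg/day) prescribed *at* the visit; between-visit dose
changes are carried by ``dose_increased_since_prev``.

A visit can contribute a relapse only during active tapering above low-dose
prednisolone: it must fall strictly more than 30 days after treatment start
(the initial-response period), carry a prescribed dose strictly above
2.5 mg/day, lie no more than 90 days after oral prednisolone treatment ended,
and be inside the patient's follow-up window.  ``eligibility_table`` applies
these rules and returns one decision with a single reason per visit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PATIENT_COLUMNS",
    "VISIT_COLUMNS",
    "ELIGIBILITY_REASONS",
    "CohortParseError",
    "CohortIntegrityError",
    "read_cohort",
    "write_cohort",
    "treatment_end_days",
    "eligibility_table",
    "filter_eligible_visits",
]

PATIENT_COLUMNS = [
    "patient_id", "baseline_date", "age", "sex", "cvd_history",
    "malignancy_history", "smoking", "symptom_duration_weeks",
    "severity_score", "arthritis", "systemic_symptoms", "crp", "esr", "hb",
    "meets_eular_acr_core", "followup_end_date",
]

VISIT_COLUMNS = [
    "patient_id", "visit_date", "pred_dose", "rj_not_in_remission",
    "rj_interval_relapse", "dose_increased_since_prev",
    "dmard_intensified_for_inefficacy", "gc_injection_added",
]

_PATIENT_BOOL = ["cvd_history", "malignancy_history", "arthritis",
                 "systemic_symptoms", "meets_eular_acr_core"]
_PATIENT_FLOAT = ["age", "symptom_duration_weeks", "crp", "esr", "hb"]
_VISIT_BOOL = ["rj_not_in_remission", "rj_interval_relapse",
               "dose_increased_since_prev", "dmard_intensified_for_inefficacy",
               "gc_injection_added"]

# precedence order when several exclusion rules apply to the same visit
ELIGIBILITY_REASONS = ("ok", "after_followup_end", "post_treatment_window",
                       "too_early", "dose_at_or_below_2_5")

INITIAL_RESPONSE_DAYS = 30
MIN_DOSE = 2.5
POST_TREATMENT_DAYS = 90


class CohortParseError(ValueError):
    """A table cell could not be parsed; the message names file and line."""


class CohortIntegrityError(ValueError):
    """Cross-record constraint violated (duplicates, orphans, ordering)."""


def _parse_numeric(series: pd.Series, column: str, path) -> pd.Series:
    out = pd.to_numeric(series.replace("", np.nan), errors="coerce")
    bad = out.isna() & series.notna() & (series != "")
    if bad.any():
        # +2: header line plus 1-based counting
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CohortParseError(
            f"{path}, line {line}: cannot parse {column}={series[bad].iloc[0]!r} "
            "(period decimal separator required)"
        )
    return out


def _parse_bool(series: pd.Series, column: str, path) -> pd.Series:
    num = _parse_numeric(series, column, path)
    bad = num.notna() & ~num.isin([0, 1])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CohortParseError(f"{path}, line {line}: {column} must be 0 or 1")
    return num.fillna(0).astype(bool)


def _parse_date(series: pd.Series, column: str, path) -> pd.Series:
    out = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = out.isna() & series.notna() & (series != "")
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CohortParseError(
            f"{path}, line {line}: cannot parse {column}={series[bad].iloc[0]!r} as ISO date"
        )
    return out


def read_cohort(patients_path, visits_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two cohort tables.

    Empty fields become missing; per-patient visits are sorted by date.
    Raises :class:`CohortParseError` on malformed cells and
    :class:`CohortIntegrityError` on duplicate (patient_id, visit_date) pairs
    or visits whose patient is absent from the patients table.
    """
    patients = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    visits = pd.read_csv(visits_path, dtype=str, keep_default_na=False)
    for df, cols, path in ((patients, PATIENT_COLUMNS, patients_path),
                           (visits, VISIT_COLUMNS, visits_path)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CohortParseError(f"{path}: missing column(s) {missing}")

    patients = patients.mask(patients == "")
    for c in _PATIENT_FLOAT:
        patients[c] = _parse_numeric(patients[c], c, patients_path)
    for c in _PATIENT_BOOL:
        patients[c] = _parse_bool(patients[c], c, patients_path)
    patients["severity_score"] = _parse_numeric(
        patients["severity_score"], "severity_score", patients_path
    ).astype("Int64")
    for c in ("baseline_date", "followup_end_date"):
        patients[c] = _parse_date(patients[c], c, patients_path)

    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortIntegrityError(f"duplicate patient_id {dup!r}")
    bad_sev = patients["severity_score"].dropna()
    if ((bad_sev < 0) | (bad_sev > 8)).any():
        raise CohortIntegrityError("severity_score outside 0-8")
    if (patients["followup_end_date"] < patients["baseline_date"]).any():
        raise CohortIntegrityError("followup_end_date before baseline_date")

    visits = visits.mask(visits == "")
    visits["pred_dose"] = _parse_numeric(visits["pred_dose"], "pred_dose", visits_path)
    if (visits["pred_dose"] < 0).any():
        raise CohortIntegrityError("pred_dose must be nonnegative")
    for c in _VISIT_BOOL:
        visits[c] = _parse_bool(visits[c], c, visits_path)
    visits["visit_date"] = _parse_date(visits["visit_date"], "visit_date", visits_path)

    if visits.duplicated(subset=["patient_id", "visit_date"]).any():
        row = visits[visits.duplicated(subset=["patient_id", "visit_date"])].iloc[0]
        raise CohortIntegrityError(
            f"duplicate visit for patient {row['patient_id']!r} on "
            f"{row['visit_date'].date()}"
        )
    orphans = ~visits["patient_id"].isin(patients["patient_id"])
    if orphans.any():
        raise CohortIntegrityError(
            f"visit for unknown patient {visits.loc[orphans, 'patient_id'].iloc[0]!r}"
        )
    visits = visits.sort_values(["patient_id", "visit_date"], kind="stable")
    return patients.reset_index(drop=True), visits.reset_index(drop=True)


def write_cohort(patients: pd.DataFrame, visits: pd.DataFrame,
                 patients_path, visits_path) -> None:
    """Write the two tables as CSV (ISO dates, 0/1 booleans, empty = missing)."""
    p = patients.copy()
    for c in ("baseline_date", "followup_end_date"):
        p[c] = pd.to_datetime(p[c]).dt.strftime("%Y-%m-%d")
    for c in _PATIENT_BOOL:
        p[c] = p[c].astype(int)
    p[PATIENT_COLUMNS].to_csv(patients_path, index=False)

    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"]).dt.strftime("%Y-%m-%d")
    for c in _VISIT_BOOL:
        v[c] = v[c].astype(int)
    v[VISIT_COLUMNS].to_csv(visits_path, index=False)


def treatment_end_days(days: np.ndarray, doses: np.ndarray) -> float | None:
    """Day (since baseline) oral prednisolone treatment ended, or None.

    Treatment ended at the first zero-dose visit that is not followed by any
    later visit with a positive dose.
    """
    doses = np.asarray(doses, dtype=float)
    days = np.asarray(days, dtype=float)
    if len(doses) == 0:
        return None
    last_pos = np.flatnonzero(doses > 0)
    start = 0 if len(last_pos) == 0 else last_pos[-1] + 1
    zeros = np.flatnonzero(doses[start:] == 0)
    if len(zeros) == 0:
        return None
    return float(days[start + zeros[0]])


def eligibility_table(patients: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Eligibility decision for every visit of every patient.

    Returns a DataFrame aligned with ``visits`` (same order) with columns
    ``patient_id, visit_date, day, eligible, reason``.  ``day`` is days since
    the patient's baseline.  A visit is eligible iff its reason is ``"ok"``;
    otherwise the single reason reported follows the precedence
    after_followup_end > post_treatment_window > too_early >
    dose_at_or_below_2_5.  Requires per-patient date-sorted visits.
    """
    if len(visits) == 0:
        return pd.DataFrame(columns=["patient_id", "visit_date", "day", "eligible", "reason"])
    pat = patients.set_index("patient_id")
    pid = visits["patient_id"]
    unknown = ~pid.isin(pat.index)
    if unknown.any():
        raise CohortIntegrityError(
            f"visit for unknown patient {pid[unknown].iloc[0]!r}")
    dates = pd.to_datetime(visits["visit_date"])
    if (dates.groupby(pid.to_numpy(), sort=False).diff().dt.days < 0).any():
        raise CohortIntegrityError("visits are not date-sorted within patient")
    base = pid.map(pat["baseline_date"])
    days = (dates - base).dt.days.astype(float)
    if (days < 0).any():
        raise CohortIntegrityError("visit before the patient's baseline")
    fend = (pid.map(pat["followup_end_date"]) - base).dt.days.astype(float)
    doses = visits["pred_dose"].astype(float)

    # treatment end: first zero-dose visit with no later positive dose
    grp = pid.to_numpy()
    pos_after_or_at = pd.Series((doses > 0).to_numpy()[::-1]).groupby(
        grp[::-1], sort=False).cummax().to_numpy()[::-1]
    pos_after = pd.Series(pos_after_or_at, index=visits.index).groupby(
        grp, sort=False).shift(-1, fill_value=False).astype(bool)
    t_end = days.where((doses == 0) & ~pos_after).groupby(grp, sort=False).transform("min")

    reason = np.full(len(visits), "ok", dtype=object)
    reason[(doses <= MIN_DOSE).to_numpy()] = "dose_at_or_below_2_5"
    reason[(days <= INITIAL_RESPONSE_DAYS).to_numpy()] = "too_early"
    reason[(days > t_end + POST_TREATMENT_DAYS).to_numpy()] = "post_treatment_window"
    reason[(days > fend).to_numpy()] = "after_followup_end"

    res = pd.DataFrame({
        "patient_id": pid, "visit_date": dates, "day": days, "reason": reason,
    }, index=visits.index)
    res["eligible"] = res["reason"] == "ok"
    return res[["patient_id", "visit_date", "day", "eligible", "reason"]]


def filter_eligible_visits(patient: pd.Series, visits: pd.DataFrame) -> pd.DataFrame:
    """Eligibility decisions for one patient's (sorted) visit list."""
    patients = pd.DataFrame([patient])
    if not (visits["patient_id"] == patient["patient_id"]).all():
        raise CohortIntegrityError("visits do not all belong to the given patient")
    return eligibility_table(patients, visits)


@dataclass(frozen=True)
class EligibilityDecision:
    """Single-visit decision (convenience record view of one table row)."""

    patient_id: str
    visit_date: pd.Timestamp
    day: float
    eligible: bool
    reason: str
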