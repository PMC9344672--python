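"""Relapse incidence summaries: cumulative incidence and incidence rate.

Cumulative incidence at a horizon is the proportion of patients with at least
one relapse within that many years of treatment start; by default the
denominator is every patient in the analysis set regardless of individual
follow-up length (an at-risk-denominator variant is available).  The
incidence rate is total relapse events divided by total person-time, per
patient-year; person-time runs from baseline to the end of the eligible-visit
window: follow-up end, capped at 90 days after oral prednisolone treatment
ended (a last-visit variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import POST_TREATMENT_DAYS, treatment_end_days

DAYS_PER_YEAR = 365.25

__all__ = ["IncidenceResult", "person_years", "incidence_summary", "DAYS_PER_YEAR"]


class DegenerateInputError(ValueError):
    """Zero person-time; incidence rate undefined."""


@dataclass(frozen=True)
class IncidenceResult:
    criterion: str
    n_patients: int
    cum_inc_counts: dict[float, int]
    cum_inc_props: dict[float, float]
    total_events: int
    person_years: float
    ir: float


def person_years(patients: pd.DataFrame, visits: pd.DataFrame | None = None,
                 rule: str = "treatment_window") -> pd.Series:
    """Per-patient person-time at risk, in years, indexed by patient_id.

    ``rule="treatment_window"`` (default): from baseline to
    min(followup_end, treatment_end + 90 days); ``treatment_end`` is derived
    from the visit dose record when ``visits`` is given, otherwise follow-up
    end already encodes the cap.  ``rule="last_visit"``: to the last recorded
    visit (requires ``visits``).
    """
    base = patients.set_index("patient_id")["baseline_date"]
    fend = patients.set_index("patient_id")["followup_end_date"]
    end_day = (fend - base).dt.days.astype(float)
    if rule == "treatment_window":
        if visits is not None:
            for pid, grp in visits.groupby("patient_id", sort=False):
                days = (pd.to_datetime(grp["visit_date"]) - base[pid]).dt.days.to_numpy(float)
                t_end = treatment_end_days(days, grp["pred_dose"].to_numpy(float))
                if t_end is not None:
                    end_day[pid] = min(end_day[pid], t_end + POST_TREATMENT_DAYS)
    elif rule == "last_visit":
        if visits is None:
            raise ValueError("rule='last_visit' requires the visits table")
        last = visits.groupby("patient_id")["visit_date"].max()
        end_day = (pd.to_datetime(last).reindex(base.index) - base).dt.days.astype(float)
    else:
        raise ValueError("rule must be 'treatment_window' or 'last_visit'")
    return (end_day / DAYS_PER_YEAR).rename("person_years")


def incidence_summary(events: pd.DataFrame, patients: pd.DataFrame,
                      horizons: tuple[float, ...] = (1.0, 2.0),
                      visits: pd.DataFrame | None = None,
                      criterion: str = "",
                      denominator: str = "all",
                      py_rule: str = "treatment_window") -> IncidenceResult:
    """Cumulative incidence at each horizon plus the overall incidence rate.

    ``denominator="all"`` (default) uses every patient as the cumulative-
    incidence denominator; ``"at_risk"`` restricts to patients whose own
    follow-up reaches the horizon (the default can understate cumulative
    incidence when follow-up is short).
    """
    if len(patients) == 0:
        raise DegenerateInputError("empty cohort")
    unknown = set(events["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise ValueError(f"events refer to unknown patient(s): {sorted(unknown)[:3]}")
    py = person_years(patients, visits, rule=py_rule)
    total_py = float(py.sum())
    if total_py <= 0:
        raise DegenerateInputError("total person-time is zero")
    total_events = int(len(events))
    counts: dict[float, int] = {}
    props: dict[float, float] = {}
    fdays = (patients["followup_end_date"] - patients["baseline_date"]).dt.days
    for h in horizons:
        cut = h * DAYS_PER_YEAR
        pos = events.loc[events["event_day"] <= cut, "patient_id"].unique()
        if denominator == "all":
            denom_ids = patients["patient_id"]
        elif denominator == "at_risk":
            denom_ids = patients.loc[fdays.to_numpy() >= cut, "patient_id"]
            pos = np.intersect1d(pos, denom_ids)
        else:
            raise ValueError("denominator must be 'all' or 'at_risk'")
        if len(denom_ids) == 0:
            raise DegenerateInputError(f"no patients at risk at horizon {h}")
        counts[h] = int(len(pos))
        props[h] = len(pos) / len(denom_ids)
    return IncidenceResult(
        criterion=criterion, n_patients=len(patients),
        cum_inc_counts=counts, cum_inc_props=props,
        total_events=total_events, person_years=total_py,
        ir=total_events / total_py,
    )
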