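"""Relapse adjudication under the two criteria.

Two operational relapse criteria are applied to each patient's stream of
*eligible* visits:

* **RJ (rheumatologist judgement)** — the treating rheumatologist judges the
  patient not in remission at the visit, or the rheumatologist and/or patient
  report a relapse since the previous visit.
* **TI (treatment intensification)** — a prednisolone dose increase between
  visits (or advice to increase), a DMARD started/increased for inefficacy,
  or a local / intramuscular glucocorticoid injection added.

Either way the raw clause only counts as a relapse when the *previous* visit
showed no relapse under the same criterion ("debouncing"), so a single
uninterrupted episode is not counted at consecutive visits.  By default the
debounce compares against the raw clause state at the previous *eligible*
visit; both choices are switchable (``debounce_on="raw"|"flag"``,
``previous="eligible"|"any"``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import eligibility_table

__all__ = ["debounce", "adjudicate_rj", "adjudicate_ti", "adjudicate_cohort",
           "relapse_events"]


def debounce(raw: np.ndarray, on: str = "raw") -> np.ndarray:
    """Suppress positives that directly follow a positive visit.

    ``on="raw"`` compares with the previous raw clause state (default);
    ``on="flag"`` compares with the previous debounced flag, which lets a long
    episode re-trigger on alternate visits.
    """
    raw = np.asarray(raw, dtype=bool)
    out = np.zeros_like(raw)
    if len(raw) == 0:
        return out
    out[0] = raw[0]
    if on == "raw":
        out[1:] = raw[1:] & ~raw[:-1]
    elif on == "flag":
        for i in range(1, len(raw)):
            out[i] = raw[i] and not out[i - 1]
    else:
        raise ValueError("debounce 'on' must be 'raw' or 'flag'")
    return out


def _raw_rj(visits: pd.DataFrame) -> np.ndarray:
    return (visits["rj_not_in_remission"].to_numpy(dtype=bool)
            | visits["rj_interval_relapse"].to_numpy(dtype=bool))


def _raw_ti(visits: pd.DataFrame) -> np.ndarray:
    return (visits["dose_increased_since_prev"].to_numpy(dtype=bool)
            | visits["dmard_intensified_for_inefficacy"].to_numpy(dtype=bool)
            | visits["gc_injection_added"].to_numpy(dtype=bool))


def _adjudicate_one(visits: pd.DataFrame, raw_fn, names: tuple[str, str],
                    debounce_on: str) -> pd.DataFrame:
    dates = pd.to_datetime(visits["visit_date"])
    if not dates.is_monotonic_increasing:
        raise ValueError("visits must be date-ordered")
    raw = raw_fn(visits)
    flag = debounce(raw, on=debounce_on)
    out = visits[["patient_id", "visit_date"]].copy()
    out[names[0]] = raw
    out[names[1]] = flag
    return out


def adjudicate_rj(eligible_visits: pd.DataFrame, debounce_on: str = "raw") -> pd.DataFrame:
    """Adjudicate the RJ criterion on one patient's eligible, date-ordered visits.

    Returns the visit keys plus ``rj_raw`` (clause truth) and ``rj_relapse``
    (debounced flag).
    """
    return _adjudicate_one(eligible_visits, _raw_rj, ("rj_raw", "rj_relapse"), debounce_on)


def adjudicate_ti(eligible_visits: pd.DataFrame, debounce_on: str = "raw") -> pd.DataFrame:
    """Adjudicate the TI criterion on one patient's eligible, date-ordered visits."""
    return _adjudicate_one(eligible_visits, _raw_ti, ("ti_raw", "ti_relapse"), debounce_on)


def adjudicate_cohort(patients: pd.DataFrame, visits: pd.DataFrame,
                      debounce_on: str = "raw",
                      previous: str = "eligible") -> pd.DataFrame:
    """Eligibility plus RJ/TI adjudication for a whole cohort.

    Returns one row per *input* visit with columns ``patient_id, visit_date,
    day, eligible, reason, rj_raw, ti_raw, rj_relapse, ti_relapse``; the raw
    and relapse columns are False on ineligible visits, which do not take part
    in adjudication when ``previous="eligible"`` (default).  With
    ``previous="any"`` the debounce looks back at the previous calendar visit,
    eligible or not, but only eligible visits can carry a relapse flag.
    """
    if previous not in ("eligible", "any"):
        raise ValueError("previous must be 'eligible' or 'any'")
    if debounce_on not in ("raw", "flag"):
        raise ValueError("debounce 'on' must be 'raw' or 'flag'")
    elig = eligibility_table(patients, visits)
    res = elig.copy()
    mask = elig["eligible"].to_numpy() if len(elig) else np.zeros(0, dtype=bool)
    pid_all = visits["patient_id"].to_numpy()
    for raw_fn, raw_name, flag_name in (
        (_raw_rj, "rj_raw", "rj_relapse"),
        (_raw_ti, "ti_raw", "ti_relapse"),
    ):
        raw_all = raw_fn(visits) if len(visits) else np.zeros(0, dtype=bool)
        if previous == "eligible":
            pid = pid_all[mask]
            raw = raw_all[mask]
        else:
            pid = pid_all
            raw = raw_all
        if debounce_on == "raw":
            prev = pd.Series(raw).groupby(pid, sort=False).shift(fill_value=False)
            flag = raw & ~prev.to_numpy(dtype=bool)
        else:
            flag = np.zeros(len(raw), dtype=bool)
            for _, idx in pd.Series(raw).groupby(pid, sort=False).indices.items():
                flag[idx] = debounce(raw[idx], on="flag")
        full_raw = np.zeros(len(visits), dtype=bool)
        full_flag = np.zeros(len(visits), dtype=bool)
        if previous == "eligible":
            full_raw[mask] = raw
            full_flag[mask] = flag
        else:
            full_raw = raw_all & mask
            full_flag = flag & mask
        res[raw_name] = full_raw
        res[flag_name] = full_flag
    return res


def relapse_events(adjudicated: pd.DataFrame, criterion: str) -> pd.DataFrame:
    """Relapse event stream for one criterion.

    Parameters
    ----------
    adjudicated : output of :func:`adjudicate_cohort`.
    criterion : ``"RJ"`` or ``"TI"``.

    Returns a DataFrame ``patient_id, event_day`` with one row per flagged
    visit, ``event_day`` in days since the patient's baseline, ordered within
    patient.
    """
    crit = criterion.upper()
    if crit not in ("RJ", "TI"):
        raise ValueError("criterion must be 'RJ' or 'TI'")
    col = "rj_relapse" if crit == "RJ" else "ti_relapse"
    ev = adjudicated.loc[adjudicated[col], ["patient_id", "day"]].copy()
    ev = ev.rename(columns={"day": "event_day"})
    ev = ev.sort_values(["patient_id", "event_day"], kind="stable")
    return ev.reset_index(drop=True)
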