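"""Synthetic PMR cohort generator.

Generates baseline and visit tables with the statistical structure the
downstream analysis assumes, so the full pipeline is testable without any
patient data.  The generative model:

* Baseline covariates are drawn independently from configured marginals
  (normal age and haemoglobin, log-normal acute-phase reactants, gamma
  symptom duration, categorical smoking and severity score).
* Each patient starts oral prednisolone at the top of a stepwise taper and is
  seen roughly every ``visit_interval_mean`` days (uniform +/- jitter).  With
  no intervening relapse the dose steps down one taper position per visit;
  follow-up ends at ``followup_max`` days or once 90 days have passed after
  the dose reached zero.
* True relapses arrive as a Poisson process with per-patient rate
  ``exp(intercept + sum(beta * centred covariate))`` per patient-year, active
  over each inter-visit gap.  A gap with at least one true event makes the
  closing visit record a treatment intensification: a prednisolone step-up
  (back one taper step, but always to a dose above 2.5 mg/day), a DMARD
  start/increase, or a glucocorticoid injection, per the configured mixture.
  At doses at or below 2.5 mg/day (including after treatment stopped) the
  action is always a step-up.
* Rheumatologist-judgement fields are the TI state corrupted by the
  configured conditional probabilities, split between the "not in remission
  at the visit" and "relapse since previous visit" clauses.

With a fixed config (including its seed) the output tables are bit-identical
across runs.  :class:`SyntheticTruth` carries the true event times and the
effect sizes used, enabling parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HAZARD_COVARIATES, CohortConfig, ConfigError

__all__ = ["SyntheticTruth", "generate_cohort", "inject_missingness", "patient_hazards"]

_ORIGIN = pd.Timestamp("2008-04-01")
DAYS_PER_YEAR = 365.25


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``events`` has one row per true relapse (``patient_id, event_day``, days
    since baseline, float); ``betas`` are the log hazard ratios used;
    ``hazard`` maps patient_id to the true relapse rate per patient-year.
    """

    events: pd.DataFrame
    betas: dict[str, float]
    hazard: pd.Series


def _hazard_design(patients: pd.DataFrame, name: str) -> np.ndarray:
    column, scale, center = HAZARD_COVARIATES[name]
    if name == "female":
        x = (patients["sex"] == "female").to_numpy(dtype=float)
    elif name == "smoking_stopped":
        x = (patients["smoking"] == "stopped").to_numpy(dtype=float)
    elif name == "smoking_current":
        x = (patients["smoking"] == "current").to_numpy(dtype=float)
    elif column in ("cvd_history", "malignancy_history", "arthritis", "systemic_symptoms"):
        x = patients[column].to_numpy(dtype=float)
    else:
        x = patients[column].to_numpy(dtype=float)
    return (x - center) / scale


def patient_hazards(patients: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """True relapse rate per patient-year for each patient row."""
    lp = np.full(len(patients), config.relapse_log_hazard_intercept, dtype=float)
    for name, beta in config.relapse_log_hazard_betas.items():
        lp = lp + beta * _hazard_design(patients, name)
    return np.exp(lp)


def _draw_baseline(rng: np.random.Generator, cfg: CohortConfig) -> pd.DataFrame:
    n = cfg.n_patients
    smoking_levels = np.array(["never", "stopped", "current"], dtype=object)
    sp = np.asarray(cfg.smoking_probs, dtype=float)
    sp = sp / sp.sum()
    # gamma matched to the configured mean/sd keeps symptom duration positive and skewed
    shape = (cfg.symptom_duration_mean / cfg.symptom_duration_sd) ** 2
    scale = cfg.symptom_duration_sd**2 / cfg.symptom_duration_mean
    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "baseline_date": _ORIGIN + pd.to_timedelta(rng.integers(0, 3000, n), unit="D"),
        "age": rng.normal(cfg.age_mean, cfg.age_sd, n),
        "sex": np.where(rng.random(n) < cfg.prop_female, "female", "male"),
        "cvd_history": rng.random(n) < cfg.prop_cvd_history,
        "malignancy_history": rng.random(n) < cfg.prop_malignancy_history,
        "smoking": smoking_levels[rng.choice(3, size=n, p=sp)],
        "symptom_duration_weeks": rng.gamma(shape, scale, n),
        "severity_score": rng.choice(9, size=n, p=np.asarray(cfg.severity_score_probs)),
        "arthritis": rng.random(n) < cfg.prop_arthritis,
        "systemic_symptoms": rng.random(n) < cfg.prop_systemic,
        "crp": np.exp(rng.normal(cfg.crp_log_mean, cfg.crp_log_sd, n)),
        "esr": np.exp(rng.normal(cfg.esr_log_mean, cfg.esr_log_sd, n)),
        "hb": np.maximum(rng.normal(cfg.hb_mean, cfg.hb_sd, n), 0.1),
        "meets_eular_acr_core": rng.random(n) < cfg.prop_eular_acr_core,
    })
    return df


def _simulate_patient(rng: np.random.Generator, cfg: CohortConfig,
                      hazard_per_year: float):
    """One patient's visit rows, true event days and follow-up end day."""
    taper = cfg.taper_schedule
    last = len(taper) - 1
    lowest_ok = max(i for i, d in enumerate(taper) if d > 2.5)
    lam = hazard_per_year / DAYS_PER_YEAR
    rows = [(0.0, taper[0], False, False, False, False, False)]
    events: list[float] = []
    day = 0.0
    pos = 0
    t_zero = None  # day the dose first reached 0 on the current zero-dose run
    while True:
        gap = cfg.visit_interval_mean + rng.uniform(-cfg.visit_jitter, cfg.visit_jitter)
        nd = day + gap
        if nd > cfg.followup_max:
            fend = cfg.followup_max if t_zero is None else min(cfg.followup_max, t_zero + 90.0)
            break
        if t_zero is not None and nd > t_zero + 90.0:
            fend = min(cfg.followup_max, t_zero + 90.0)
            break
        n_ev = int(rng.poisson(lam * gap)) if lam > 0 else 0
        dose_inc = dmard = inj = False
        if n_ev:
            ts = day + np.sort(rng.random(n_ev)) * gap
            events.extend(float(t) for t in ts)
            if taper[pos] <= 2.5:
                action = 0  # at low/zero dose the intensification is a dose raise
            else:
                action = int(rng.choice(3, p=cfg.ti_action_probs))
            if action == 0:
                new_pos = pos - 1 if pos > 0 else 0
                if taper[new_pos] <= 2.5:
                    new_pos = lowest_ok
                pos = new_pos
                dose_inc = True  # covers "advice to increase" when already at the top
                t_zero = None
            elif action == 1:
                dmard = True
            else:
                inj = True
        else:
            if cfg.false_positive_ti_rate and rng.random() < cfg.false_positive_ti_rate:
                inj = True
            if pos < last:
                pos += 1
            if taper[pos] == 0 and t_zero is None:
                t_zero = nd
        ti_here = dose_inc or dmard or inj
        p_rj = cfg.p_rj_given_ti if ti_here else cfg.p_rj_given_no_ti
        rj_rem = rj_int = False
        if rng.random() < p_rj:
            if rng.random() < cfg.p_rj_interval_share:
                rj_int = True
            else:
                rj_rem = True
        rows.append((nd, taper[pos], rj_rem, rj_int, dose_inc, dmard, inj))
        day = nd
    return rows, events, fend


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (patients, visits, truth) tables from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _draw_baseline(rng, config)
    hazards = patient_hazards(patients, config)

    visit_rows = []
    event_rows = []
    fend_days = np.empty(len(patients))
    for i, pid in enumerate(patients["patient_id"]):
        rows, events, fend = _simulate_patient(rng, config, float(hazards[i]))
        fend_days[i] = fend
        for r in rows:
            visit_rows.append((pid,) + r)
        for t in events:
            event_rows.append((pid, t))

    base = patients.set_index("patient_id")["baseline_date"]
    visits = pd.DataFrame(visit_rows, columns=[
        "patient_id", "day", "pred_dose", "rj_not_in_remission",
        "rj_interval_relapse", "dose_increased_since_prev",
        "dmard_intensified_for_inefficacy", "gc_injection_added",
    ])
    visits["visit_date"] = base.loc[visits["patient_id"]].to_numpy() + pd.to_timedelta(
        np.floor(visits["day"].to_numpy()), unit="D"
    )
    visits = visits.drop(columns="day")
    visits = visits[["patient_id", "visit_date", "pred_dose", "rj_not_in_remission",
                     "rj_interval_relapse", "dose_increased_since_prev",
                     "dmard_intensified_for_inefficacy", "gc_injection_added"]]

    patients["followup_end_date"] = patients["baseline_date"] + pd.to_timedelta(
        np.ceil(fend_days), unit="D"
    )
    events = pd.DataFrame(event_rows, columns=["patient_id", "event_day"])
    truth = SyntheticTruth(
        events=events,
        betas=dict(config.relapse_log_hazard_betas),
        hazard=pd.Series(hazards, index=patients["patient_id"], name="hazard_per_year"),
    )
    patients = inject_missingness(
        patients, config.missing_rates, seed=int(rng.integers(2**31)),
        mode=config.missingness_mode, age_mean=config.age_mean,
    )
    return patients, visits, truth


_MISSING_COLUMN = {
    "smoking": "smoking",
    "symptom_duration": "symptom_duration_weeks",
    "crp": "crp",
    "esr": "esr",
    "hb": "hb",
}


def inject_missingness(patients: pd.DataFrame, rates: dict[str, float], seed: int,
                       mode: str = "mcar", age_mean: float = 66.4) -> pd.DataFrame:
    """Blank out baseline covariates at the given per-field rates.

    ``mode="mcar"`` blanks cells independently at each field's rate.
    ``mode="mar"`` makes the missingness probability increase with age
    (logistic in centred age, slope 0.05/year) while keeping roughly the
    target marginal rate; useful for stress-testing imputation.
    Other fields are untouched; the input frame is not modified.
    """
    unknown = set(rates) - set(_MISSING_COLUMN)
    if unknown:
        raise ConfigError(f"missing_rates has unknown field(s): {sorted(unknown)}")
    for name, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ConfigError(f"missing_rates[{name!r}] must be in [0, 1], got {r}")
    if mode not in ("mcar", "mar"):
        raise ConfigError("missingness mode must be 'mcar' or 'mar'")
    out = patients.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    for field_name, rate in rates.items():
        if rate == 0:
            continue
        col = _MISSING_COLUMN[field_name]
        if mode == "mcar":
            p = np.full(n, rate)
        else:
            centred = out["age"].to_numpy(dtype=float) - age_mean
            logit = math.log(rate / (1 - rate)) if 0 < rate < 1 else (
                -math.inf if rate == 0 else math.inf)
            p = 1.0 / (1.0 + np.exp(-(logit + 0.05 * centred)))
        mask = rng.random(n) < p
        out.loc[mask, col] = np.nan
    return out
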