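"""Univariable association screening between baseline predictors and relapse.

Each of the twelve candidate baseline predictors is fit alone against three
outcomes of treatment-intensification relapse: relapse within 1 year
(logistic), relapse within 2 years (logistic) and relapses per patient-year
(Poisson with a log person-time offset).  Effects are reported as odds
ratios / incidence rate ratios with Wald 95% intervals and p-values, on
complete cases for the predictor.  The acute-phase reactants enter divided by
10 (per 10 mg/L CRP, per 10 mm/h ESR) and symptom duration in months, for
coefficient interpretability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .incidence import DAYS_PER_YEAR, person_years

__all__ = [
    "PredictorSpec", "AssociationResult", "default_predictor_specs",
    "build_design", "binary_outcome", "event_counts",
    "univariable_logistic", "univariable_poisson", "association_table",
    "DegenerateOutcomeError", "SeparationError",
]

WEEKS_PER_MONTH = 4.345


class DegenerateOutcomeError(ValueError):
    """Outcome constant (or no events); the regression is undefined."""


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


@dataclass(frozen=True)
class PredictorSpec:
    """How one baseline field enters a regression.

    ``transform``: identity, divide_by_10 or weeks_to_months for continuous
    fields; ``kind="categorical"`` expands to dummy contrasts against
    ``reference``.  ``positive_level`` maps a two-level field to 0/1.
    """

    name: str
    source: str
    kind: str = "continuous"            # continuous | binary | categorical
    transform: str = "identity"         # identity | divide_by_10 | weeks_to_months
    reference: str | None = None
    positive_level: str | None = None
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.transform not in ("identity", "divide_by_10", "weeks_to_months"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.kind != "continuous" and self.transform != "identity":
            raise ValueError("transforms apply to continuous predictors only")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError("categorical predictor needs a reference level")


def default_predictor_specs(symptom_duration_unit: str = "months") -> list[PredictorSpec]:
    """The twelve candidate baseline predictors.

    ``symptom_duration_unit`` is ``"months"`` (default) or ``"weeks"``; both
    are exposed because source reports mix the two conventions.
    """
    if symptom_duration_unit not in ("months", "weeks"):
        raise ValueError("symptom_duration_unit must be 'months' or 'weeks'")
    sd_transform = "weeks_to_months" if symptom_duration_unit == "months" else "identity"
    return [
        PredictorSpec("age", "age"),
        PredictorSpec("sex_female", "sex", kind="binary", positive_level="female"),
        PredictorSpec("cvd_history", "cvd_history", kind="binary"),
        PredictorSpec("malignancy_history", "malignancy_history", kind="binary"),
        PredictorSpec("smoking", "smoking", kind="categorical", reference="never",
                      levels=("never", "stopped", "current")),
        PredictorSpec(f"symptom_duration_{symptom_duration_unit}",
                      "symptom_duration_weeks", transform=sd_transform),
        PredictorSpec("severity_score", "severity_score"),
        PredictorSpec("arthritis", "arthritis", kind="binary"),
        PredictorSpec("systemic_symptoms", "systemic_symptoms", kind="binary"),
        PredictorSpec("crp_per10", "crp", transform="divide_by_10"),
        PredictorSpec("esr_per10", "esr", transform="divide_by_10"),
        PredictorSpec("hb", "hb"),
    ]


def build_design(patients: pd.DataFrame, spec: PredictorSpec) -> pd.DataFrame:
    """Design columns for one predictor (NaN rows where the source is missing)."""
    src = patients[spec.source]
    if spec.kind == "continuous":
        x = src.astype(float)
        if spec.transform == "divide_by_10":
            x = x / 10.0
        elif spec.transform == "weeks_to_months":
            x = x / WEEKS_PER_MONTH
        return x.to_frame(spec.name)
    if spec.kind == "binary":
        if spec.positive_level is not None:
            x = src.map(lambda v: np.nan if pd.isna(v) else float(v == spec.positive_level))
        else:
            x = src.astype(float)
        return x.to_frame(spec.name)
    levels = spec.levels or tuple(sorted(set(src.dropna())))
    cols = {}
    for lv in levels:
        if lv == spec.reference:
            continue
        cols[f"{spec.name}_{lv}"] = src.map(
            lambda v: np.nan if pd.isna(v) else float(v == lv))
    return pd.DataFrame(cols, index=patients.index)


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    term: str
    outcome: str                 # relapse_0_1y | relapse_0_2y | relapse_rate
    effect: float                # OR or IRR
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    significant: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "significant", self.p_value < 0.05)


def binary_outcome(patients: pd.DataFrame, events: pd.DataFrame,
                   horizon: float) -> pd.Series:
    """1 if the patient has >=1 relapse within ``horizon`` years, else 0."""
    cut = horizon * DAYS_PER_YEAR
    pos = set(events.loc[events["event_day"] <= cut, "patient_id"])
    return patients["patient_id"].isin(pos).astype(float)


def event_counts(patients: pd.DataFrame, events: pd.DataFrame) -> pd.Series:
    counts = events.groupby("patient_id").size()
    return patients["patient_id"].map(counts).fillna(0).astype(float)


def _check_separation(result, X: np.ndarray, y: np.ndarray) -> None:
    fitted = result.predict()
    if np.all((fitted > 1 - 1e-8) == (y > 0.5)) and np.all(np.abs(result.params) > 0) \
            and np.any(np.abs(result.params[1:]) > 15):
        raise SeparationError("perfect separation: the MLE diverges")


def _wald(result, names: list[str], effect_label: str, outcome: str,
          predictor: str, n_used: int) -> list[AssociationResult]:
    z = norm.ppf(0.975)
    out = []
    for term in names:
        beta = result.params[term]
        se = result.bse[term]
        out.append(AssociationResult(
            predictor=predictor, term=term, outcome=outcome,
            effect=float(np.exp(beta)),
            ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
            p_value=float(result.pvalues[term]), n_used=n_used,
        ))
    return out


def univariable_logistic(patients: pd.DataFrame, events: pd.DataFrame,
                         spec: PredictorSpec, horizon: float) -> list[AssociationResult]:
    """Odds ratio(s) for relapse within ``horizon`` years, complete cases."""
    X = build_design(patients, spec)
    y = binary_outcome(patients, events, horizon)
    keep = X.notna().all(axis=1)
    Xc, yc = X[keep], y[keep].to_numpy()
    if len(Xc) == 0 or yc.min() == yc.max():
        raise DegenerateOutcomeError("outcome is constant among complete cases")
    design = sm.add_constant(Xc.to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(yc, design).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise SeparationError(str(err)) from err
    _check_separation(res, design, yc)
    params = pd.Series(res.params, index=["const", *Xc.columns])
    wrapped = _Wrapped(params, pd.Series(res.bse, index=params.index),
                       pd.Series(res.pvalues, index=params.index))
    outcome = f"relapse_0_{int(horizon)}y" if float(horizon).is_integer() else f"relapse_0_{horizon}y"
    return _wald(wrapped, list(Xc.columns), "OR", outcome, spec.name, int(keep.sum()))


def univariable_poisson(patients: pd.DataFrame, events: pd.DataFrame,
                        spec: PredictorSpec,
                        py: pd.Series | None = None) -> list[AssociationResult]:
    """Incidence rate ratio(s) from per-patient event counts with log-py offset."""
    X = build_design(patients, spec)
    counts = event_counts(patients, events)
    if py is None:
        py = person_years(patients)
    py_arr = patients["patient_id"].map(py).to_numpy(dtype=float)
    keep = X.notna().all(axis=1) & (py_arr > 0)
    Xc = X[keep]
    yc = counts[keep].to_numpy()
    if len(Xc) == 0:
        raise DegenerateOutcomeError("no complete cases with positive person-time")
    if yc.sum() == 0:
        raise DegenerateOutcomeError("zero relapse events among complete cases")
    design = sm.add_constant(Xc.to_numpy(), has_constant="add")
    res = sm.GLM(yc, design, family=sm.families.Poisson(),
                 offset=np.log(py_arr[keep])).fit()
    params = pd.Series(res.params, index=["const", *Xc.columns])
    wrapped = _Wrapped(params, pd.Series(res.bse, index=params.index),
                       pd.Series(res.pvalues, index=params.index))
    return _wald(wrapped, list(Xc.columns), "IRR", "relapse_rate", spec.name,
                 int(keep.sum()))


@dataclass(frozen=True)
class _Wrapped:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series


def association_table(patients: pd.DataFrame, events: pd.DataFrame,
                      specs: list[PredictorSpec] | None = None,
                      py: pd.Series | None = None) -> pd.DataFrame:
    """The full predictor x outcome screening table.

    One row per predictor term (smoking contributes two contrasts) with the
    three outcomes side by side; a fit that fails for a cell is marked in its
    ``status`` column instead of aborting the table.
    """
    specs = specs if specs is not None else default_predictor_specs()
    if py is None:
        py = person_years(patients)
    rows: dict[str, dict] = {}

    def put(term, outcome, payload):
        rows.setdefault(term, {"term": term})
        rows[term].update({f"{outcome}_{k}": v for k, v in payload.items()})

    for spec in specs:
        terms = list(build_design(patients, spec).columns)
        for outcome, fit in (
            ("relapse_0_1y", lambda: univariable_logistic(patients, events, spec, 1.0)),
            ("relapse_0_2y", lambda: univariable_logistic(patients, events, spec, 2.0)),
            ("relapse_rate", lambda: univariable_poisson(patients, events, spec, py)),
        ):
            try:
                for r in fit():
                    put(r.term, outcome, {
                        "effect": r.effect, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                        "p": r.p_value, "n": r.n_used, "status": "ok",
                    })
            except (DegenerateOutcomeError, SeparationError, np.linalg.LinAlgError) as err:
                for term in terms:
                    put(term, outcome, {
                        "effect": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan, "n": 0, "status": f"failed: {err}",
                    })
    return pd.DataFrame(list(rows.values()))
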