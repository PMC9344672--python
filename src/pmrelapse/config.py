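"""Configuration of the synthetic PMR cohort generator.

:class:`CohortConfig` collects every knob of the generator: baseline covariate
marginals, visit scheduling, the prednisolone taper, the relapse hazard and the
noise processes that produce imperfect rheumatologist-judgement labels.  The
defaults describe a realistic hospital outpatient cohort of newly treated
polymyalgia rheumatica patients: age ~ N(66.4, 8.8) years, 55.9% female, skewed
acute-phase reactants (CRP median 29 mg/L, ESR median 37 mm/h), haemoglobin
8.2 mmol/L, and a stepwise oral prednisolone taper from 15 mg/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

SCHEMA_VERSION = 1

__all__ = ["CohortConfig", "ConfigError", "default_severity_probs", "HAZARD_COVARIATES"]


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


# Marginal distributions of the four 0/1/2 clinical-severity items
# (pain/stiffness and movement restriction at shoulder and hip girdles;
# none / unilateral / bilateral).  The 0-8 severity sum score is their
# convolution under independence.
_SEVERITY_ITEM_PROBS: tuple[tuple[float, float, float], ...] = (
    (11 / 417, 16 / 417, 390 / 417),   # shoulder pain/stiffness
    (39 / 417, 10 / 417, 368 / 417),   # hip pain/stiffness
    (222 / 417, 26 / 417, 169 / 417),  # shoulder movement restriction
    (325 / 417, 26 / 417, 66 / 417),   # hip movement restriction
)


def default_severity_probs() -> tuple[float, ...]:
    """Distribution of the 0-8 severity sum score implied by the item marginals."""
    dist = [1.0]
    for item in _SEVERITY_ITEM_PROBS:
        s = sum(item)
        probs = [p / s for p in item]
        new = [0.0] * (len(dist) + 2)
        for i, p in enumerate(dist):
            for j, q in enumerate(probs):
                new[i + j] += p * q
        dist = new
    total = sum(dist)
    return tuple(p / total for p in dist)


# Covariates the relapse log-hazard may load on, as
# name -> (patient column, scale divisor, centring value).
# Continuous covariates are centred so that exp(intercept) is the relapse rate
# of a reference patient with covariates at their centring values.
HAZARD_COVARIATES: dict[str, tuple[str, float, float]] = {
    "age_per10": ("age", 10.0, 66.4),
    "female": ("sex", 1.0, 0.0),
    "cvd_history": ("cvd_history", 1.0, 0.0),
    "malignancy_history": ("malignancy_history", 1.0, 0.0),
    "smoking_stopped": ("smoking", 1.0, 0.0),
    "smoking_current": ("smoking", 1.0, 0.0),
    "symptom_duration_weeks": ("symptom_duration_weeks", 1.0, 14.0),
    "severity_score": ("severity_score", 1.0, 3.45),
    "arthritis": ("arthritis", 1.0, 0.0),
    "systemic_symptoms": ("systemic_symptoms", 1.0, 0.0),
    "crp_per10": ("crp", 10.0, 29.0),
    "esr_per10": ("esr", 10.0, 37.0),
    "hb": ("hb", 1.0, 8.2),
}

_MISSINGNESS_FIELDS = frozenset({"smoking", "symptom_duration", "crp", "esr", "hb"})


def _default_missing_rates() -> dict[str, float]:
    return {
        "smoking": 0.19,
        "symptom_duration": 0.01,
        "crp": 0.13,
        "esr": 0.05,
        "hb": 0.24,
    }


def _default_betas() -> dict[str, float]:
    # Modest acute-phase-reactant effects: rate ratio 1.04 per 10 mg/L CRP and
    # 1.09 per 10 mm/h ESR.
    return {"crp_per10": math.log(1.04), "esr_per10": math.log(1.09)}


@dataclass
class CohortConfig:
    """All parameters of :func:`pmrelapse.simulate.generate_cohort`.

    Probabilities are in [0, 1]; doses in mg/day oral prednisolone; durations
    in days unless the field name says otherwise.  ``relapse_log_hazard_intercept``
    is the log relapse rate per patient-year of a reference patient;
    ``relapse_log_hazard_betas`` maps covariate names (keys of
    :data:`HAZARD_COVARIATES`) to log hazard ratios.
    """

    n_patients: int = 417
    seed: int = 0

    # baseline covariates
    age_mean: float = 66.4
    age_sd: float = 8.8
    prop_female: float = 0.559
    prop_cvd_history: float = 0.141
    prop_malignancy_history: float = 0.122
    # never / stopped / current; the remainder up to 1 is the smoking
    # missingness share, handled through missing_rates.
    smoking_probs: tuple[float, float, float] = (0.472, 0.209, 0.125)
    symptom_duration_mean: float = 14.0   # weeks
    symptom_duration_sd: float = 13.7     # weeks
    crp_log_mean: float = 3.3673          # log mg/L (median 29)
    crp_log_sd: float = 0.9287            # log IQR 15-52.5
    esr_log_mean: float = 3.6109          # log mm/h (median 37)
    esr_log_sd: float = 0.4994            # log IQR 26-51
    hb_mean: float = 8.2                  # mmol/L
    hb_sd: float = 0.7413                 # IQR 7.6-8.6
    severity_score_probs: tuple[float, ...] = field(default_factory=default_severity_probs)
    prop_arthritis: float = 0.153
    prop_systemic: float = 0.436
    prop_eular_acr_core: float = 0.79
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    missingness_mode: str = "mcar"        # "mcar" or "mar" (age-dependent)

    # visits and treatment
    visit_interval_mean: float = 42.0     # days
    visit_jitter: float = 7.0             # uniform +/- days
    start_dose: float = 15.0
    taper_schedule: tuple[float, ...] = (15.0, 12.5, 10.0, 8.75, 7.5, 6.25, 5.0, 3.75, 2.5, 0.0)
    followup_max: float = 1825.0          # days

    # relapse process
    relapse_log_hazard_intercept: float = math.log(0.35)
    relapse_log_hazard_betas: dict[str, float] = field(default_factory=_default_betas)
    ti_action_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)  # step-up / DMARD / injection
    false_positive_ti_rate: float = 0.0   # spurious TI actions per visit, default off

    # rheumatologist-judgement noise, conditional on the visit carrying a TI action
    p_rj_given_ti: float = 0.63
    p_rj_given_no_ti: float = 0.09
    p_rj_interval_share: float = 0.3      # share of RJ positives recorded as between-visit reports

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        probs = {
            "prop_female": self.prop_female,
            "prop_cvd_history": self.prop_cvd_history,
            "prop_malignancy_history": self.prop_malignancy_history,
            "prop_arthritis": self.prop_arthritis,
            "prop_systemic": self.prop_systemic,
            "prop_eular_acr_core": self.prop_eular_acr_core,
            "p_rj_given_ti": self.p_rj_given_ti,
            "p_rj_given_no_ti": self.p_rj_given_no_ti,
            "p_rj_interval_share": self.p_rj_interval_share,
            "false_positive_ti_rate": self.false_positive_ti_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if len(self.smoking_probs) != 3 or any(p < 0 for p in self.smoking_probs):
            raise ConfigError("smoking_probs must be 3 nonnegative probabilities")
        if sum(self.smoking_probs) > 1.0 + 1e-9:
            raise ConfigError("smoking_probs must sum to at most 1")
        if sum(self.smoking_probs) <= 0:
            raise ConfigError("smoking_probs must have positive mass")
        if abs(sum(self.severity_score_probs) - 1.0) > 1e-6 or any(
            p < 0 for p in self.severity_score_probs
        ):
            raise ConfigError("severity_score_probs must be a distribution over 0-8")
        if len(self.severity_score_probs) != 9:
            raise ConfigError("severity_score_probs must have 9 entries (scores 0-8)")
        for name, sd in (
            ("age_sd", self.age_sd),
            ("symptom_duration_sd", self.symptom_duration_sd),
            ("crp_log_sd", self.crp_log_sd),
            ("esr_log_sd", self.esr_log_sd),
            ("hb_sd", self.hb_sd),
        ):
            if sd <= 0:
                raise ConfigError(f"{name} must be positive")
        extra = set(self.missing_rates) - _MISSINGNESS_FIELDS
        if extra:
            raise ConfigError(f"missing_rates has unknown field(s): {sorted(extra)}")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"missing_rates[{name!r}] must be in [0, 1], got {r}")
        if self.missingness_mode not in ("mcar", "mar"):
            raise ConfigError("missingness_mode must be 'mcar' or 'mar'")
        if self.visit_interval_mean <= 0:
            raise ConfigError("visit_interval_mean must be positive")
        if not 0 <= self.visit_jitter < self.visit_interval_mean:
            raise ConfigError("visit_jitter must be in [0, visit_interval_mean)")
        if self.start_dose <= 2.5:
            raise ConfigError("start_dose must be > 2.5 mg/day")
        taper = self.taper_schedule
        if len(taper) < 2 or any(b >= a for a, b in zip(taper, taper[1:])):
            raise ConfigError("taper_schedule must be strictly decreasing")
        if any(d < 0 for d in taper):
            raise ConfigError("taper_schedule doses must be nonnegative")
        if taper[0] != self.start_dose:
            raise ConfigError("start_dose must equal the first taper_schedule step")
        if not any(d > 2.5 for d in taper):
            raise ConfigError("taper_schedule must contain a dose > 2.5 mg/day")
        if self.followup_max <= 0:
            raise ConfigError("followup_max must be positive")
        if len(self.ti_action_probs) != 3 or any(p < 0 for p in self.ti_action_probs):
            raise ConfigError("ti_action_probs must be 3 nonnegative values")
        if abs(sum(self.ti_action_probs) - 1.0) > 1e-9:
            raise ConfigError("ti_action_probs must sum to 1")
        unknown = set(self.relapse_log_hazard_betas) - set(HAZARD_COVARIATES)
        if unknown:
            raise ConfigError(f"relapse_log_hazard_betas has unknown covariate(s): {sorted(unknown)}")
        if math.isnan(self.relapse_log_hazard_intercept):
            raise ConfigError("relapse_log_hazard_intercept must not be NaN")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        d.pop("schema_version", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        for name in ("smoking_probs", "severity_score_probs", "taper_schedule", "ti_action_probs"):
            if name in d and isinstance(d[name], Sequence):
                d[name] = tuple(d[name])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for name in ("smoking_probs", "severity_score_probs", "taper_schedule", "ti_action_probs"):
            d[name] = list(d[name])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
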