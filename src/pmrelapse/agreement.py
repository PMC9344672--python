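"""Agreement between the RJ and TI relapse criteria.

Cohen's kappa corrects the observed proportion of agreement Po for the
agreement Pe expected by chance from the two criteria's marginal positive
rates: kappa = (Po - Pe) / (1 - Pe).  With rare relapses most visits are
double negatives, so Pe is dominated by the double-negative chance cell
(reported separately as ``pe_negative_cell``), which is why a high percentage
agreement can coexist with a moderate kappa.

Intervals: Wilson score interval for Po; large-sample (Fleiss-Cohen-Everitt)
standard error with a normal approximation for kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .incidence import DAYS_PER_YEAR

__all__ = ["ContingencyTable2x2", "AgreementResult", "agreement_from_table",
           "kappa_from_marginals", "visit_level_agreement",
           "patient_level_agreement", "DegenerateMarginalsError", "EmptyInputError"]


class EmptyInputError(ValueError):
    """No observations to assess agreement on."""


class DegenerateMarginalsError(ValueError):
    """Chance agreement is 1; kappa is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-classification counts; rows = criterion A +/-, columns = criterion B."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise EmptyInputError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def a_pos(self) -> int:
        return self.n11 + self.n10

    @property
    def b_pos(self) -> int:
        return self.n11 + self.n01


@dataclass(frozen=True)
class AgreementResult:
    table: ContingencyTable2x2
    po: float
    pe: float
    pe_negative_cell: float
    kappa: float
    po_ci: tuple[float, float]
    kappa_ci: tuple[float, float]


def _kappa_se(table: ContingencyTable2x2, kappa: float, pe: float) -> float:
    """Large-sample SE of Cohen's kappa (Fleiss, Cohen & Everitt 1969)."""
    n = table.total
    p = np.array([[table.n11, table.n10], [table.n01, table.n00]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
        for i in range(2)
    )
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def agreement_from_table(table: ContingencyTable2x2) -> AgreementResult:
    """Full agreement summary (Po, Pe, kappa, 95% intervals) from counts."""
    n = table.total
    po = (table.n11 + table.n00) / n
    pa, pb = table.a_pos / n, table.b_pos / n
    pe_neg = (1 - pa) * (1 - pb)
    pe = pa * pb + pe_neg
    if pe >= 1.0:
        raise DegenerateMarginalsError(
            "chance agreement is 1 (degenerate marginals); kappa undefined")
    kappa = (po - pe) / (1 - pe)
    n_agree = table.n11 + table.n00
    po_ci = proportion_confint(n_agree, n, alpha=0.05, method="wilson")
    se = _kappa_se(table, kappa, pe)
    z = norm.ppf(0.975)
    kappa_ci = (kappa - z * se, min(kappa + z * se, 1.0))
    return AgreementResult(table, po, pe, pe_neg, kappa,
                           (float(po_ci[0]), float(po_ci[1])),
                           (float(kappa_ci[0]), float(kappa_ci[1])))


def kappa_from_marginals(total: int, a_pos: int, b_pos: int,
                         po: float) -> tuple[float, float, float]:
    """(pe, pe_negative_cell, kappa) from marginal counts and observed agreement.

    Closed form: pe = (a_pos * b_pos + (total - a_pos) * (total - b_pos)) / total**2
    and kappa = (po - pe) / (1 - pe).  Lets the published summary of a cohort
    (marginal positives under each criterion plus percentage agreement) be
    turned back into kappa and its chance decomposition.
    """
    if total <= 0:
        raise EmptyInputError("total must be positive")
    if not (0 <= a_pos <= total and 0 <= b_pos <= total):
        raise ValueError("marginal counts must lie in [0, total]")
    if not 0.0 <= po <= 1.0:
        raise ValueError("po must be in [0, 1]")
    # implied double-positive count must be a feasible cell
    n11 = (po * total - total + a_pos + b_pos) / 2.0
    lo, hi = max(0.0, a_pos + b_pos - total), float(min(a_pos, b_pos))
    if not lo - 0.5 <= n11 <= hi + 0.5:
        raise ValueError("po is inconsistent with the marginals (negative implied cell)")
    pa, pb = a_pos / total, b_pos / total
    pe_neg = (1 - pa) * (1 - pb)
    pe = pa * pb + pe_neg
    if pe >= 1.0:
        raise DegenerateMarginalsError(
            "chance agreement is 1 (degenerate marginals); kappa undefined")
    kappa = (po - pe) / (1 - pe)
    return pe, pe_neg, kappa


def _table_from_flags(a: np.ndarray, b: np.ndarray) -> ContingencyTable2x2:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return ContingencyTable2x2(
        n11=int(np.sum(a & b)), n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)), n00=int(np.sum(~a & ~b)),
    )


def visit_level_agreement(adjudicated: pd.DataFrame) -> AgreementResult:
    """RJ vs TI agreement across all eligible adjudicated visits."""
    elig = adjudicated[adjudicated["eligible"]] if "eligible" in adjudicated else adjudicated
    if len(elig) == 0:
        raise EmptyInputError("no eligible visits to assess agreement on")
    return agreement_from_table(
        _table_from_flags(elig["rj_relapse"].to_numpy(), elig["ti_relapse"].to_numpy())
    )


def patient_level_agreement(events_rj: pd.DataFrame, events_ti: pd.DataFrame,
                            patients: pd.DataFrame, horizon: float) -> AgreementResult:
    """Agreement on per-patient relapse-within-horizon status.

    A patient is positive under a criterion when they have at least one
    relapse event within ``horizon`` years (horizon * 365.25 days) of
    baseline.  The denominator is all patients.
    """
    if len(patients) == 0:
        raise EmptyInputError("empty cohort")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    cut = horizon * DAYS_PER_YEAR
    ids = patients["patient_id"]

    def positives(events: pd.DataFrame) -> np.ndarray:
        if len(events) == 0:
            return np.zeros(len(ids), dtype=bool)
        pos = set(events.loc[events["event_day"] <= cut, "patient_id"])
        return ids.isin(pos).to_numpy()

    return agreement_from_table(
        _table_from_flags(positives(events_rj), positives(events_ti))
    )
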