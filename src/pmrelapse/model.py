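"""Multivariable prediction of treatment-intensification relapse within 1 year.

Development recipe (standard practice for prognostic models on multiply
imputed data):

1. impute the incomplete baseline covariates m times by chained equations
   (:class:`pmrelapse.impute.MultipleImputer`), with the outcome in every
   imputation model;
2. within each completed dataset, backward elimination from the full
   candidate set using Wald tests at retention level ``selection_alpha``
   (default 0.157, the AIC-equivalent threshold);
3. keep the variables retained in more than ``inclusion_threshold`` (default
   0.5) of the imputation sets;
4. refit the kept variables on every completed dataset and pool by Rubin's
   rules (mean coefficients; total variance = within + (1 + 1/m) * between);
5. internal validation by the Harrell bootstrap: resample patients, repeat
   the whole procedure (imputation and selection included), and estimate the
   optimism of the apparent c-statistic; corrected AUC = apparent - optimism.

The apparent AUC is the c-statistic of the pooled linear predictor, averaged
over imputation sets and reported with its across-set range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .association import PredictorSpec, build_design, default_predictor_specs
from .impute import DEFAULT_IMPUTE_VARIABLES, MultipleImputer

__all__ = [
    "RelapseRiskModel", "pool_rubin", "aggregate_selection", "backward_eliminate",
    "sensitivity_subset", "develop_model", "validate_model", "predict_risk",
    "MissingCovariateError", "EmptySubsetError",
]


class MissingCovariateError(ValueError):
    """A selected covariate is missing and no imputed value was supplied."""


class EmptySubsetError(ValueError):
    """A patient subset used for a sensitivity analysis is empty."""


def pool_rubin(coefs: np.ndarray, covs: np.ndarray):
    """Rubin's rules for m coefficient vectors and covariance matrices.

    Returns (pooled coefficients, total variances, within, between); total
    variance per coefficient is within + (1 + 1/m) * between, never below the
    mean within-imputation variance.
    """
    coefs = np.asarray(coefs, dtype=float)
    covs = np.asarray(covs, dtype=float)
    m = coefs.shape[0]
    pooled = coefs.mean(axis=0)
    within = np.diagonal(covs, axis1=1, axis2=2).mean(axis=0)
    if m > 1:
        between = coefs.var(axis=0, ddof=1)
    else:
        between = np.zeros_like(pooled)
    total = within + (1.0 + 1.0 / m) * between
    return pooled, total, within, between


def _fit_logit(X: np.ndarray, y: np.ndarray):
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return np.asarray(res.params), np.asarray(res.cov_params())


def backward_eliminate(X: pd.DataFrame, groups: dict[str, list[str]],
                       y: np.ndarray, alpha: float) -> list[str]:
    """Backward elimination over variables (dummy groups dropped together).

    Starting from all variables, repeatedly refit and drop the variable with
    the largest Wald p-value (chi-squared over its group of columns) until
    every remaining variable has p <= ``alpha``.  Returns the retained
    variable names (may be empty).
    """
    remaining = [v for v in groups if groups[v]]
    while remaining:
        cols = [c for v in remaining for c in groups[v]]
        design = np.column_stack([np.ones(len(X)), X[cols].to_numpy(dtype=float)])
        params, cov = _fit_logit(design, y)
        worst, worst_p = None, -1.0
        offset = 1
        for v in remaining:
            k = len(groups[v])
            idx = []
            pos = 1
            for w in remaining:
                if w == v:
                    idx = list(range(pos, pos + len(groups[w])))
                pos += len(groups[w])
            b = params[idx]
            sub = cov[np.ix_(idx, idx)]
            stat = float(b @ np.linalg.solve(sub, b))
            p = float(chi2.sf(stat, df=k))
            if p > worst_p:
                worst, worst_p = v, p
        if worst_p <= alpha:
            break
        remaining = [v for v in remaining if v != worst]
    return remaining


def aggregate_selection(selections: list[list[str]], candidates: list[str],
                        threshold: float) -> tuple[list[str], dict[str, float]]:
    """Across-imputation selection: keep variables retained in > threshold of sets."""
    m = len(selections)
    fractions = {v: sum(v in s for s in selections) / m for v in candidates}
    selected = [v for v in candidates if fractions[v] > threshold]
    return selected, fractions


def sensitivity_subset(patients: pd.DataFrame) -> pd.DataFrame:
    """Patients fulfilling the 2012 EULAR/ACR core classification criteria."""
    sub = patients[patients["meets_eular_acr_core"].astype(bool)]
    if len(sub) == 0:
        raise EmptySubsetError("no patient meets EULAR/ACR core criteria")
    return sub.reset_index(drop=True)


class RelapseRiskModel(BaseEstimator):
    """Pooled logistic model for relapse within the first treatment year.

    Parameters
    ----------
    candidates : list of :class:`PredictorSpec` (default: the twelve baseline
        candidate predictors).
    m : number of imputation sets (>= 2).
    n_iterations, n_donors : chained-equations settings.
    selection_alpha : Wald retention level for backward elimination.
    inclusion_threshold : across-imputation inclusion fraction a variable
        must exceed to enter the final model.
    random_state : seed for imputation and the bootstrap.

    Fitted attributes (trailing underscore) include ``selected_variables_``,
    ``inclusion_fractions_``, ``coef_`` / ``var_`` (pooled, Rubin's rules),
    ``coef_per_imputation_``, ``apparent_auc_`` with ``auc_range_``, and after
    :meth:`validate` also ``optimism_`` and ``corrected_auc_``.
    """

    def __init__(self, candidates=None, m: int = 20, n_iterations: int = 10,
                 n_donors: int = 5, selection_alpha: float = 0.157,
                 inclusion_threshold: float = 0.5,
                 random_state: int | None = None):
        self.candidates = candidates
        self.m = m
        self.n_iterations = n_iterations
        self.n_donors = n_donors
        self.selection_alpha = selection_alpha
        self.inclusion_threshold = inclusion_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _specs(self) -> list[PredictorSpec]:
        return list(self.candidates) if self.candidates is not None \
            else default_predictor_specs()

    def _imputation_frame(self, patients: pd.DataFrame, y: np.ndarray,
                          specs: list[PredictorSpec]) -> tuple[pd.DataFrame, list[str]]:
        """Frame holding the impute targets, their complete predictors and y."""
        targets = [v for v in DEFAULT_IMPUTE_VARIABLES
                   if v in patients.columns
                   and any(s.source == v for s in specs)
                   and patients[v].isna().any()]
        frame = pd.DataFrame(index=patients.index)
        for v in targets:
            frame[v] = patients[v]
        for s in specs:
            if s.source in targets:
                continue
            block = build_design(patients, s)
            for c in block.columns:
                frame[c] = block[c]
        frame["_outcome"] = np.asarray(y, dtype=float)
        return frame, targets

    def _designs(self, patients: pd.DataFrame, y: np.ndarray, specs,
                 seed) -> tuple[list[pd.DataFrame], dict[str, list[str]]]:
        """Per-imputation full design matrices and variable->columns map."""
        frame, targets = self._imputation_frame(patients, y, specs)
        groups: dict[str, list[str]] = {}
        if targets:
            imputer = MultipleImputer(
                variables=targets, n_imputations=self.m,
                n_iterations=self.n_iterations, n_donors=self.n_donors,
                random_state=seed)
            completed = imputer.fit_transform(frame)
            patient_sets = []
            for comp in completed:
                pat = patients.copy()
                for v in targets:
                    pat[v] = comp[v]
                patient_sets.append(pat)
        else:
            patient_sets = [patients]
        designs = []
        for pat in patient_sets:
            blocks = []
            for s in specs:
                block = build_design(pat, s)
                groups[s.name] = list(block.columns)
                blocks.append(block)
            X = pd.concat(blocks, axis=1)
            if X.isna().any().any():
                missing_cols = X.columns[X.isna().any()].tolist()
                raise MissingCovariateError(
                    f"missing values remain in {missing_cols}; impute first")
            designs.append(X)
        if len(patient_sets) == 1:
            designs = designs * self.m  # complete data: m identical sets
        return designs, groups

    def fit(self, patients: pd.DataFrame, y) -> "RelapseRiskModel":
        """Develop the model: impute, select, pool, and score apparent AUC."""
        if self.m < 2:
            raise ValueError("m must be >= 2")
        y = np.asarray(y, dtype=float)
        if len(y) != len(patients):
            raise ValueError("y must align with the patients table")
        if y.min() == y.max():
            raise ValueError("outcome is constant; nothing to model")
        specs = self._specs()
        n_events = int(min(y.sum(), (1 - y).sum()))
        if len(specs) > n_events / 10:
            warnings.warn(
                f"{len(specs)} candidate variables for {n_events} events "
                "exceeds the 10-events-per-variable rule of thumb",
                UserWarning, stacklevel=2)
        designs, groups = self._designs(patients, y, specs, self.random_state)
        identical = all(d is designs[0] for d in designs[1:])

        if identical:
            sel = backward_eliminate(designs[0], groups, y, self.selection_alpha)
            selections = [sel] * self.m
        else:
            selections = [backward_eliminate(X, groups, y, self.selection_alpha)
                          for X in designs]
        selected, fractions = aggregate_selection(
            selections, [s.name for s in specs], self.inclusion_threshold)
        if not selected:
            warnings.warn("no variable retained in enough imputation sets; "
                          "fitting intercept-only model", UserWarning, stacklevel=2)
        sel_cols = [c for v in selected for c in groups[v]]

        coefs, covs = [], []
        fit_sets = designs[:1] if identical else designs
        for X in fit_sets:
            design = np.column_stack([np.ones(len(X))] +
                                     ([X[sel_cols].to_numpy(dtype=float)] if sel_cols else []))
            params, cov = _fit_logit(design, y)
            coefs.append(params)
            covs.append(cov)
        if identical:
            coefs, covs = coefs * self.m, covs * self.m
        pooled, total, within, between = pool_rubin(np.array(coefs), np.array(covs))

        self.specs_ = specs
        self.groups_ = groups
        self.selected_variables_ = selected
        self.inclusion_fractions_ = fractions
        self.selections_per_imputation_ = selections
        self.coef_names_ = ["const", *sel_cols]
        self.coef_ = pooled
        self.var_ = total
        self.within_var_ = within
        self.between_var_ = between
        self.coef_per_imputation_ = np.array(coefs)
        self._designs_ = designs
        self._y_ = y

        aucs = [self._auc_on(X, y, self.coef_names_, pooled) for X in designs]
        self.apparent_auc_ = float(np.mean(aucs))
        self.auc_range_ = (float(np.min(aucs)), float(np.max(aucs)))
        return self

    @staticmethod
    def _auc_on(X: pd.DataFrame, y: np.ndarray, coef_names: list[str],
                coef: np.ndarray) -> float:
        lp = np.full(len(X), coef[0])
        for name, b in zip(coef_names[1:], coef[1:]):
            lp = lp + b * X[name].to_numpy(dtype=float)
        if np.allclose(lp, lp[0]):
            return 0.5  # intercept-only model has no discrimination
        return float(roc_auc_score(y, lp))

    def validate(self, patients: pd.DataFrame, y, n_bootstrap: int = 500,
                 random_state: int | None = None) -> "RelapseRiskModel":
        """Harrell bootstrap optimism correction of the apparent AUC.

        Each resample redevelops the model from scratch (imputation and
        selection included); optimism is the mean excess of the bootstrap
        model's AUC on its own sample over its AUC on the original data.
        Resamples with a constant outcome are redrawn (capped retries).
        """
        if n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit the model before validating it")
        y = np.asarray(y, dtype=float)
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(None if seed is None else seed + 1)
        n = len(patients)
        optimisms = []
        for b in range(n_bootstrap):
            for attempt in range(10):
                idx = rng.integers(0, n, n)
                yb = y[idx]
                if yb.min() < yb.max():
                    break
            else:
                warnings.warn("bootstrap resample kept a constant outcome after "
                              "10 retries; skipping it", UserWarning, stacklevel=2)
                continue
            boot = RelapseRiskModel(
                candidates=self.candidates, m=self.m,
                n_iterations=self.n_iterations, n_donors=self.n_donors,
                selection_alpha=self.selection_alpha,
                inclusion_threshold=self.inclusion_threshold,
                random_state=int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                boot.fit(patients.iloc[idx].reset_index(drop=True), yb)
            test_aucs = [self._auc_on(X, y, boot.coef_names_, boot.coef_)
                         for X in self._designs_]
            optimisms.append(boot.apparent_auc_ - float(np.mean(test_aucs)))
        self.optimism_ = float(np.mean(optimisms)) if optimisms else 0.0
        self.n_bootstrap_ = len(optimisms)
        self.corrected_auc_ = self.apparent_auc_ - self.optimism_
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, patients: pd.DataFrame) -> np.ndarray:
        """Predicted relapse risk in (0, 1) for each patient row.

        Requires observed (or externally imputed) values for every selected
        covariate; raises :class:`MissingCovariateError` otherwise.
        """
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit the model before predicting")
        blocks = []
        for s in self.specs_:
            if s.name in self.selected_variables_:
                blocks.append(build_design(patients, s))
        X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=patients.index)
        if len(X.columns) and X.isna().any().any():
            bad = X.columns[X.isna().any()].tolist()
            raise MissingCovariateError(
                f"missing value(s) in selected covariate(s) {bad}; impute first")
        lp = np.full(len(patients), self.coef_[0])
        for name, b in zip(self.coef_names_[1:], self.coef_[1:]):
            lp = lp + b * X[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-lp))

    predict_risk = predict_proba

    def summary(self) -> pd.DataFrame:
        """Pooled coefficient table with Rubin total standard errors."""
        se = np.sqrt(self.var_)
        return pd.DataFrame({
            "term": self.coef_names_,
            "coef": self.coef_,
            "se_total": se,
            "odds_ratio": np.exp(self.coef_),
        })


# ---------------------------------------------------------------- wrappers

@dataclass(frozen=True)
class FittedModel:
    """Read-only view of a fitted/validated :class:`RelapseRiskModel`."""

    selected_variables: list[str]
    inclusion_fractions: dict[str, float]
    coef_names: list[str]
    coef: np.ndarray
    var: np.ndarray
    apparent_auc: float
    auc_range: tuple[float, float]
    optimism: float | None
    corrected_auc: float | None


def develop_model(patients, y, candidates=None, m=20, inclusion_threshold=0.5,
                  selection_alpha=0.157, seed=None) -> RelapseRiskModel:
    return RelapseRiskModel(
        candidates=candidates, m=m, inclusion_threshold=inclusion_threshold,
        selection_alpha=selection_alpha, random_state=seed).fit(patients, y)


def validate_model(model: RelapseRiskModel, patients, y, n_bootstrap=500,
                   seed=None) -> RelapseRiskModel:
    return model.validate(patients, y, n_bootstrap=n_bootstrap, random_state=seed)


def predict_risk(model: RelapseRiskModel, patients: pd.DataFrame) -> np.ndarray:
    return model.predict_proba(patients)
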