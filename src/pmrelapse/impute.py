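"""Multiple imputation by chained equations (MICE).

Missing baseline covariates (smoking, symptom duration, CRP, ESR, Hb) are
filled in m times by cycling per-variable conditional models given all other
covariates and the outcome:

* continuous variables: Bayesian linear regression (posterior draw of the
  coefficients and residual variance) followed by predictive-mean matching —
  each missing cell receives the observed value of one of the ``n_donors``
  cases whose posterior predictions are closest, so imputations stay inside
  the observed support;
* categorical variables: multinomial logistic regression, category drawn
  from the predicted probabilities.

Observed cells are never altered; only originally-missing cells differ
across the m completed datasets.  Fully observed inputs return m identical
copies.  Deterministic under a fixed ``random_state``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

__all__ = ["MultipleImputer", "ImputationError", "impute"]

DEFAULT_IMPUTE_VARIABLES = ("smoking", "symptom_duration_weeks", "crp", "esr", "hb")
_CATEGORICAL = {"smoking"}


class ImputationError(ValueError):
    """Imputation infeasible (e.g. a variable with no observed values)."""


def _predictor_matrix(df: pd.DataFrame, columns: list[str], skip: str) -> np.ndarray:
    """Numeric design from current completed data, excluding ``skip``."""
    cols = []
    for c in columns:
        if c == skip:
            continue
        s = df[c]
        if c in _CATEGORICAL or s.dtype == object:
            for lv in sorted(set(s.dropna()))[1:]:
                cols.append((s == lv).to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=float))
    if not cols:
        return np.ones((len(df), 1))
    X = np.column_stack(cols)
    return np.column_stack([np.ones(len(df)), X])


def _bayes_linear_pmm(rng, X_obs, y_obs, X_mis, n_donors):
    """Posterior-draw linear prediction + predictive-mean matching."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(sigma2 * XtX_inv + 1e-12 * np.eye(p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    pred_obs = X_obs @ beta_star
    pred_mis = X_mis @ beta_star
    # nearest observed predictions donate their observed values
    out = np.empty(len(pred_mis))
    k = min(n_donors, len(y_obs))
    for i, pm in enumerate(pred_mis):
        idx = np.argpartition(np.abs(pred_obs - pm), k - 1)[:k]
        out[i] = y_obs[idx[rng.integers(k)]]
    return out


def _multinomial_draw(rng, X_obs, y_obs, X_mis):
    levels, y_codes = np.unique(y_obs, return_inverse=True)
    if len(levels) == 1:
        return np.repeat(levels[0], len(X_mis))
    # standardize for the lbfgs solver; mild ridge keeps the draw well posed
    mu = X_obs.mean(axis=0)
    sd = X_obs.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=200, C=1.0)
    clf.fit((X_obs - mu) / sd, y_codes)
    probs = clf.predict_proba((X_mis - mu) / sd)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))[:, None]
    picks = (u > cum).sum(axis=1)
    return levels[np.minimum(picks, len(levels) - 1)]


class MultipleImputer(BaseEstimator):
    """Chained-equations multiple imputation of baseline covariates.

    Parameters
    ----------
    variables : columns to impute (default: the baseline covariates with
        missingness in routine PMR records).  Columns without missing values
        are skipped.
    n_imputations : m, number of completed datasets (>= 2).
    n_iterations : chained-equation cycles per dataset.
    n_donors : donor-pool size for predictive-mean matching.
    predictors : columns used in every conditional model (default: all other
        imputation variables plus every other numeric/boolean column of the
        input, which should include the analysis outcome).
    random_state : seed for all randomness.
    """

    def __init__(self, variables=None, n_imputations: int = 20,
                 n_iterations: int = 10, n_donors: int = 5,
                 predictors=None, random_state: int | None = None):
        self.variables = variables
        self.n_imputations = n_imputations
        self.n_iterations = n_iterations
        self.n_donors = n_donors
        self.predictors = predictors
        self.random_state = random_state

    def _model_columns(self, df: pd.DataFrame, variables) -> list[str]:
        if self.predictors is not None:
            cols = list(dict.fromkeys(list(self.predictors) + list(variables)))
        else:
            cols = [c for c in df.columns
                    if c in variables
                    or pd.api.types.is_numeric_dtype(df[c])
                    or pd.api.types.is_bool_dtype(df[c])]
            cols = [c for c in cols if c not in ("patient_id",)]
        return cols

    def fit_transform(self, df: pd.DataFrame) -> list[pd.DataFrame]:
        """Return the m completed copies of ``df``."""
        if self.n_imputations < 2:
            raise ImputationError("n_imputations must be >= 2")
        variables = list(self.variables) if self.variables is not None else [
            c for c in DEFAULT_IMPUTE_VARIABLES if c in df.columns]
        rng = np.random.default_rng(self.random_state)
        for v in variables:
            if v not in df.columns:
                raise ImputationError(f"column {v!r} not in the input")
            if df[v].notna().sum() == 0 and df[v].isna().any():
                raise ImputationError(f"covariate {v!r} is fully missing")
        targets = [v for v in variables if df[v].isna().any()]
        if not targets:
            return [df.copy() for _ in range(self.n_imputations)]
        model_cols = self._model_columns(df, variables)
        # booleans to float for the linear algebra
        work_base = df.copy()
        for c in model_cols:
            if pd.api.types.is_bool_dtype(work_base[c]):
                work_base[c] = work_base[c].astype(float)

        completed = []
        for _ in range(self.n_imputations):
            work = work_base.copy()
            miss = {v: work[v].isna().to_numpy() for v in targets}
            # initial fill: random draws from the observed values
            for v in targets:
                obs = work[v].dropna().to_numpy()
                work.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))
            for _ in range(self.n_iterations):
                for v in targets:
                    X = _predictor_matrix(work, model_cols, skip=v)
                    obs_mask = ~miss[v]
                    if v in _CATEGORICAL:
                        drawn = _multinomial_draw(
                            rng, X[obs_mask][:, 1:], df.loc[obs_mask, v].to_numpy(),
                            X[miss[v]][:, 1:])
                        work.loc[miss[v], v] = drawn
                    else:
                        drawn = _bayes_linear_pmm(
                            rng, X[obs_mask],
                            df.loc[obs_mask, v].to_numpy(dtype=float),
                            X[miss[v]], self.n_donors)
                        work.loc[miss[v], v] = drawn
            out = df.copy()
            for v in targets:
                out.loc[miss[v], v] = work.loc[miss[v], v]
            completed.append(out)
        return completed


def impute(patients: pd.DataFrame, m: int = 20, seed: int | None = None,
           **kwargs) -> list[pd.DataFrame]:
    """Functional wrapper over :class:`MultipleImputer`."""
    return MultipleImputer(n_imputations=m, random_state=seed,
                           **kwargs).fit_transform(patients)
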