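"""Prediction model: pooling identities, selection, validation, risk output."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pmrelapse import (PredictorSpec, RelapseRiskModel, aggregate_selection,
                       pool_rubin, sensitivity_subset)
from pmrelapse.model import EmptySubsetError, MissingCovariateError, backward_eliminate
from .conftest import BASE


def patients_with(rng, n, **cols):
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "baseline_date": BASE,
        "followup_end_date": BASE + pd.Timedelta(days=730),
        "meets_eular_acr_core": True,
    })
    for k, v in cols.items():
        df[k] = v
    return df


class TestPooling:
    def test_identical_sets_reduce_to_single_fit(self, rng):
        coefs = np.tile(rng.normal(size=4), (5, 1))
        covs = np.tile(np.diag(rng.uniform(0.1, 1, 4)), (5, 1, 1))
        pooled, total, within, between = pool_rubin(coefs, covs)
        assert np.allclose(pooled, coefs[0])
        assert np.allclose(between, 0.0)
        assert np.allclose(total, within)

    def test_total_variance_at_least_within(self, rng):
        coefs = rng.normal(size=(8, 3))
        covs = np.array([np.diag(rng.uniform(0.1, 1, 3)) for _ in range(8)])
        _, total, within, _ = pool_rubin(coefs, covs)
        assert (total >= within - 1e-12).all()


class TestSelection:
    def test_forty_percent_inclusion_is_dropped_at_half_threshold(self):
        selections = [["v"] if i < 8 else [] for i in range(20)]
        selected, fractions = aggregate_selection(selections, ["v"], 0.5)
        assert fractions["v"] == pytest.approx(0.40)
        assert selected == []

    def test_majority_inclusion_is_kept(self):
        selections = [["v"] if i < 11 else [] for i in range(20)]
        selected, _ = aggregate_selection(selections, ["v"], 0.5)
        assert selected == ["v"]

    def test_backward_elimination_keeps_a_strong_signal(self, rng):
        n = 1500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.8 + 1.2 * x1)))).astype(float)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        kept = backward_eliminate(X, {"x1": ["x1"], "x2": ["x2"]}, y, alpha=0.157)
        assert "x1" in kept


class TestFit:
    def test_complete_data_pooled_fit_matches_statsmodels(self, rng):
        n = 800
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.9 * x)))).astype(float)
        pats = patients_with(rng, n, x=x)
        mdl = RelapseRiskModel(candidates=[PredictorSpec("x", "x")], m=4,
                               random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
        assert mdl.selected_variables_ == ["x"]
        assert np.allclose(mdl.between_var_, 0.0)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert mdl.coef_ == pytest.approx(np.asarray(ref.params), rel=1e-6)

    def test_strong_predictor_has_full_inclusion_fraction(self, rng):
        """A single real effect (OR 3) among nulls is selected in every set."""
        n = 2000
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        hb = 8.2 + rng.normal(0, 0.7, n)
        hb[rng.random(n) < 0.2] = np.nan   # force the multiple-imputation path
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + np.log(3) * x)))).astype(float)
        pats = patients_with(rng, n, x=x, z=z, hb=hb)
        cands = [PredictorSpec("x", "x"), PredictorSpec("z", "z"),
                 PredictorSpec("hb", "hb")]
        mdl = RelapseRiskModel(candidates=cands, m=5, n_iterations=5,
                               random_state=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
        assert mdl.inclusion_fractions_["x"] == pytest.approx(1.0)
        assert "x" in mdl.selected_variables_

    def test_constant_outcome_rejected(self, rng):
        pats = patients_with(rng, 30, x=rng.normal(size=30))
        with pytest.raises(ValueError, match="constant"):
            RelapseRiskModel(candidates=[PredictorSpec("x", "x")]).fit(
                pats, np.zeros(30))

    def test_events_per_variable_warning(self, rng):
        n = 60
        x = rng.normal(size=(n, 3))
        y = np.zeros(n)
        y[:5] = 1.0   # 5 events for 3 candidates < 10 per variable
        pats = patients_with(rng, n, a=x[:, 0], b=x[:, 1], c=x[:, 2])
        cands = [PredictorSpec(c, c) for c in "abc"]
        with pytest.warns(UserWarning, match="events"):
            RelapseRiskModel(candidates=cands, m=2, random_state=0).fit(pats, y)


class TestPredict:
    def _intercept_only_model(self, rng, prevalence=0.32, n=400):
        pats = patients_with(rng, n, x=rng.normal(size=n))
        y = np.zeros(n)
        y[: int(prevalence * n)] = 1.0
        rng.shuffle(y)
        mdl = RelapseRiskModel(candidates=[PredictorSpec("x", "x")], m=2,
                               selection_alpha=1e-9, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)   # x is null: alpha tiny forces intercept-only
        return mdl, pats, y

    def test_intercept_only_risk_equals_sample_proportion(self, rng):
        """Logistic MLE identity: intercept-only predicted risk = prevalence."""
        mdl, pats, y = self._intercept_only_model(rng)
        if mdl.selected_variables_:   # null variable got in by chance at tiny alpha
            pytest.skip("selection kept a null variable despite alpha=1e-9")
        risk = mdl.predict_proba(pats)
        assert np.allclose(risk, y.mean(), atol=1e-8)

    def test_monotone_in_a_positive_coefficient(self, rng):
        n = 1200
        esr = rng.normal(37, 10, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.05 * (esr - 37))))).astype(float)
        pats = patients_with(rng, n, esr=esr)
        mdl = RelapseRiskModel(candidates=[
            PredictorSpec("esr_per10", "esr", transform="divide_by_10")],
            m=2, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
        lo = pats.copy(); lo["esr"] = 30.0
        hi = pats.copy(); hi["esr"] = 60.0
        assert (mdl.predict_proba(hi) > mdl.predict_proba(lo)).all()
        assert ((mdl.predict_proba(pats) > 0) & (mdl.predict_proba(pats) < 1)).all()

    def test_missing_selected_covariate_raises(self, rng):
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + x)))).astype(float)
        pats = patients_with(rng, n, x=x)
        mdl = RelapseRiskModel(candidates=[PredictorSpec("x", "x")], m=2,
                               random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
        broken = pats.copy()
        broken.loc[0, "x"] = np.nan
        with pytest.raises(MissingCovariateError):
            mdl.predict_proba(broken)


class TestValidate:
    def test_bootstrap_floor_enforced(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        pats = patients_with(rng, n, x=x)
        mdl = RelapseRiskModel(candidates=[PredictorSpec("x", "x")], m=2,
                               random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
        with pytest.raises(ValueError, match="n_bootstrap"):
            mdl.validate(pats, y, n_bootstrap=50)

    def test_validate_populates_optimism_fields(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.8 + 0.8 * x)))).astype(float)
        pats = patients_with(rng, n, x=x)
        mdl = RelapseRiskModel(candidates=[PredictorSpec("x", "x")], m=2,
                               random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl.fit(pats, y)
            mdl.validate(pats, y, n_bootstrap=100)
        assert mdl.corrected_auc_ == pytest.approx(
            mdl.apparent_auc_ - mdl.optimism_)
        assert 0.0 <= mdl.corrected_auc_ <= 1.0


class TestSensitivitySubset:
    def test_all_meeting_is_identity(self, rng):
        pats = patients_with(rng, 10, x=rng.normal(size=10))
        pd.testing.assert_frame_equal(sensitivity_subset(pats), pats)

    def test_subset_proportion(self, default_cohort):
        pats, _, _ = default_cohort
        sub = sensitivity_subset(pats)
        frac = len(sub) / len(pats)
        assert abs(frac - 0.79) < 4 * np.sqrt(0.79 * 0.21 / len(pats))

    def test_empty_subset_rejected(self, rng):
        pats = patients_with(rng, 5, x=np.zeros(5))
        pats["meets_eular_acr_core"] = False
        with pytest.raises(EmptySubsetError):
            sensitivity_subset(pats)


def test_null_selection_is_calibrated(rng):
    """All-null candidates: each variable enters the final model rarely."""
    n_runs, n = 30, 400
    counts = {c: 0 for c in "abcd"}
    for run in range(n_runs):
        r = np.random.default_rng(1000 + run)
        cols = {c: r.normal(size=n) for c in "abcd"}
        y = (r.random(n) < 0.33).astype(float)
        pats = patients_with(rng, n, **cols)
        cands = [PredictorSpec(c, c) for c in "abcd"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mdl = RelapseRiskModel(candidates=cands, m=2, random_state=run).fit(pats, y)
        for v in mdl.selected_variables_:
            counts[v] += 1
    # per-variable null retention ~ alpha=0.157; far below half the runs
    for v, c in counts.items():
        assert c <= 0.4 * n_runs, (v, c)
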