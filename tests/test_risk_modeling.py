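"""Design matrix, penalized/unpenalized logistic fits, ROC-AUC."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from faersig.report_store import ReportSet
from faersig.risk_modeling import (
    DesignMatrix,
    build_design_matrix,
    compute_roc_auc,
    fit_lasso_logistic,
    fit_logistic_irls,
    rank_auc,
)
from conftest import mk_report


def _random_dm(n=400, p_drugs=5, seed=0, beta=None) -> DesignMatrix:
    """Random logistic fixture: binary drug columns + continuous noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"d{j}": (rng.random(n) < 0.3).astype(float) for j in range(p_drugs)})
    X["age_years"] = rng.normal(65, 10, n)
    X["weight_kg"] = rng.normal(70, 15, n)
    X["sex_female"] = (rng.random(n) < 0.6).astype(float)
    if beta is None:
        beta = np.r_[rng.normal(0, 0.8, p_drugs), 0.02, 0.005, 0.3]
    eta = -2.0 + X.to_numpy() @ beta
    y = (rng.random(n) < expit(eta)).astype(float)
    return DesignMatrix(X=X, y=y, drug_columns=tuple(f"d{j}" for j in range(p_drugs)))


class TestDesignMatrix:
    def test_column_count_and_sums(self, ten_report_set):
        dm = build_design_matrix(ten_report_set, ["DRUG X", "DRUG Y"], {"CATARACT"})
        assert dm.X.shape == (10, 5)
        assert dm.X["DRUG X"].sum() == 5  # exposed reports
        assert dm.X["DRUG Y"].sum() == 3
        assert dm.y.sum() == 4            # cataract reports

    def test_non_candidate_drug_rows_all_zero(self, ten_report_set):
        dm = build_design_matrix(ten_report_set, ["DRUG X"], {"CATARACT"})
        z_rows = [rid for rid in dm.X.index if rid.startswith("N5") or rid.startswith("N6")]
        assert (dm.X.loc[z_rows, "DRUG X"] == 0).all()

    def test_zero_exposure_candidate_dropped_with_warning(self, ten_report_set):
        with pytest.warns(UserWarning, match="NOSUCHDRUG"):
            dm = build_design_matrix(ten_report_set, ["DRUG X", "NOSUCHDRUG"], {"CATARACT"})
        assert dm.drug_columns == ("DRUG X",)

    def test_incomplete_demographics_rejected(self):
        rs = ReportSet.from_reports([mk_report("R1", age=None), mk_report("R2", reactions=("NAUSEA",))])
        with pytest.raises(ValueError, match="demographic"):
            build_design_matrix(rs, [], {"CATARACT"})


class TestIrls:
    def test_intercept_only_closed_form(self):
        # a constant covariate is dropped as collinear -> intercept-only fit
        n = 400
        y = np.r_[np.ones(100), np.zeros(300)]
        X = pd.DataFrame({"flat": np.ones(n)})
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_logistic_irls(DesignMatrix(X=X, y=y, drug_columns=()))
        assert fit.dropped_columns == ("flat",)
        assert fit.params.loc["intercept", "coef"] == pytest.approx(math.log(1 / 3), abs=1e-8)

    def test_single_binary_covariate_matches_2x2_log_or(self):
        # saturated model: coefficient = ln(ad/bc) of the implied table
        a, b, c, d = 30, 20, 10, 40
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        dm = DesignMatrix(X=pd.DataFrame({"drug": x}), y=y, drug_columns=("drug",))
        fit = fit_logistic_irls(dm)
        assert fit.params.loc["drug", "coef"] == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)
        assert fit.params.loc["intercept", "coef"] == pytest.approx(math.log(c / d), abs=1e-8)

    def test_matches_statsmodels_newton_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        dm = _random_dm(seed=3)
        fit = fit_logistic_irls(dm)
        X = np.concatenate([np.ones((dm.n, 1)), dm.X.to_numpy(float)], axis=1)
        oracle = sm.Logit(dm.y, X).fit(method="newton", disp=False, tol=1e-12)
        np.testing.assert_allclose(fit.params["coef"].to_numpy(), oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.params["se"].to_numpy(), oracle.bse, atol=1e-6)
        assert fit.converged

    def test_wald_or_ci_log_symmetric(self):
        fit = fit_logistic_irls(_random_dm(seed=5))
        p = fit.params
        np.testing.assert_allclose(
            np.sqrt(p["or_low"] * p["or_high"]), p["or_point"], rtol=1e-10
        )

    def test_bonferroni_over_drug_terms_only(self):
        dm = _random_dm(seed=7, p_drugs=4)
        fit = fit_logistic_irls(dm)
        drugs = [c for c in fit.params.index if c.startswith("d")]
        for c in drugs:
            expected = min(1.0, 4 * fit.params.loc[c, "p_raw"])
            assert fit.params.loc[c, "p_adj"] == pytest.approx(expected)
        assert np.isnan(fit.params.loc["age_years", "p_adj"])

    def test_separation_flagged_but_fit_returned(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        x = y.copy()  # perfect separation
        dm = DesignMatrix(X=pd.DataFrame({"drug": x}), y=y, drug_columns=("drug",))
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic_irls(dm)
        assert bool(fit.params.loc["drug", "separation"])


class TestLasso:
    def test_all_drug_coefficients_zero_at_lambda_max(self):
        dm = _random_dm(seed=1)
        path = fit_lasso_logistic(dm, grid_size=8, k_folds=3, seed=0)
        first = path.coefficients.iloc[0]
        assert all(abs(first[c]) < 1e-10 for c in dm.drug_columns)
        # demographics stay unpenalized, hence nonzero even at lambda_max
        assert abs(first["sex_female"]) > 1e-6

    def test_small_lambda_matches_irls(self):
        dm = _random_dm(n=500, p_drugs=5, seed=2)
        path = fit_lasso_logistic(dm, grid_size=12, k_folds=3, seed=0)
        mle = fit_logistic_irls(dm)
        last = path.coefficients.iloc[-1]  # lambda = lambda_max * 1e-4
        for col in ("intercept",) + dm.columns:
            assert last[col] == pytest.approx(mle.params.loc[col, "coef"], abs=1e-4)

    def test_matches_sklearn_saga_oracle_on_penalized_only_fixture(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(4)
        n, p = 500, 6
        raw = rng.normal(size=(n, p))
        raw = (raw - raw.mean(0)) / raw.std(0)  # exactly standardized
        beta = np.r_[1.0, -0.8, 0.5, 0.0, 0.0, 0.0]
        y = (rng.random(n) < expit(-0.5 + raw @ beta)).astype(float)
        cols = [f"d{j}" for j in range(p)]
        dm = DesignMatrix(X=pd.DataFrame(raw, columns=cols), y=y, drug_columns=tuple(cols))
        path = fit_lasso_logistic(dm, grid_size=10, k_folds=3, seed=0)
        lam = path.lambda_grid[4]
        ours = path.coefficients.iloc[4]
        clf = sklearn_linear.LogisticRegression(
            penalty="l1", C=1.0 / (n * lam), solver="saga", tol=1e-10, max_iter=50_000
        ).fit(raw, y)
        np.testing.assert_allclose(ours[cols].to_numpy(), clf.coef_[0], atol=1e-4)
        assert ours["intercept"] == pytest.approx(clf.intercept_[0], abs=1e-4)

    def test_row_permutation_invariance(self):
        dm = _random_dm(n=300, seed=6)
        perm = np.random.default_rng(0).permutation(dm.n)
        dm_perm = DesignMatrix(X=dm.X.iloc[perm], y=dm.y[perm], drug_columns=dm.drug_columns)
        a = fit_lasso_logistic(dm, grid_size=6, k_folds=3, seed=9)
        b = fit_lasso_logistic(dm_perm, grid_size=6, k_folds=3, seed=9)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)
        assert a.selected_columns == b.selected_columns

    def test_true_signals_selected_on_synthetic_fixture(self):
        # 3 strong signals among 12 drugs: selection keeps all three
        rng = np.random.default_rng(8)
        n, p = 4_000, 12
        X = pd.DataFrame({f"d{j}": (rng.random(n) < 0.2).astype(float) for j in range(p)})
        X["age_years"] = rng.normal(65, 10, n)
        X["weight_kg"] = rng.normal(70, 15, n)
        X["sex_female"] = (rng.random(n) < 0.6).astype(float)
        beta = np.zeros(p)
        beta[:3] = [1.5, 1.2, 1.0]
        eta = -2.5 + X.iloc[:, :p].to_numpy() @ beta + 0.02 * (X["age_years"] - 65)
        y = (rng.random(n) < expit(eta)).astype(float)
        dm = DesignMatrix(X=X, y=y, drug_columns=tuple(f"d{j}" for j in range(p)))
        path = fit_lasso_logistic(dm, grid_size=20, k_folds=5, seed=1)
        assert {"d0", "d1", "d2"} <= set(path.selected_columns)


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        scores = np.r_[np.linspace(0.6, 0.9, 50), np.linspace(0.1, 0.4, 50)]
        assert rank_auc(scores, y) == pytest.approx(1.0)

    def test_all_ties(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        assert rank_auc(np.full(100, 0.5), y) == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(12)
        y = (rng.random(200) < 0.4).astype(float)
        scores = np.round(rng.random(200), 2)  # force ties
        pos, neg = scores[y == 1], scores[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert rank_auc(scores, y) == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-10)

    def test_matches_sklearn(self):
        metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(13)
        y = (rng.random(500) < 0.3).astype(float)
        scores = rng.random(500)
        assert rank_auc(scores, y) == pytest.approx(metrics.roc_auc_score(y, scores), abs=1e-12)

    def test_curve_monotone_and_auc_attached(self):
        dm = _random_dm(seed=10)
        fit = fit_logistic_irls(dm)
        roc = compute_roc_auc(fit, dm)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.fpr[-1] == pytest.approx(1.0) and roc.tpr[-1] == pytest.approx(1.0)
        assert 0.0 <= roc.auc <= 1.0

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.arange(5, dtype=float), np.ones(5))
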