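import numpy as np
import pandas as pd
import pytest

from viscowin import (
    CohortConfig,
    adjusted_odds_ratio,
    design_matrix,
    generate_cohort_frame,
    loocv_metrics,
    plsr_fit,
    subgroup_analysis,
    validate_cohort,
)
from viscowin.exceptions import ParameterError, RankError


def random_problem(seed, n=60, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=0.5, size=n)
    return X, y


def frame_from_counts(a, b, c, d):
    """Cohort-like frame from a 2x2 table (aligned x responder)."""
    rows = (
        [(True, True)] * a + [(True, False)] * b + [(False, True)] * c + [(False, False)] * d
    )
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "aligned": [r[0] for r in rows],
            "responder": [r[1] for r in rows],
            "age": rng.uniform(45, 78, len(rows)),
            "sex": rng.choice(["F", "M"], len(rows)),
        }
    )


class TestPLSR:
    def test_full_components_equal_ordinary_least_squares(self):
        """With all components PLSR reproduces the OLS predictions."""
        X, y = random_problem(1)
        model = plsr_fit(X, y, n_components=X.shape[1])
        ols = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(ols, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), ols @ beta, atol=1e-8)

    def test_single_component_single_predictor_is_simple_regression(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 3.0 * x + rng.normal(size=50)
        model = plsr_fit(x[:, None], y, n_components=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        expected = y.mean() + slope * (x - x.mean())
        np.testing.assert_allclose(model.predict(x[:, None]), expected, atol=1e-8)

    def test_matches_sklearn_reference(self):
        """Cross-check the NIPALS fit against scikit-learn's PLS."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(3, n=80, p=6)
        for k in (1, 2, 4):
            ours = plsr_fit(X, y, n_components=k).predict(X)
            ref = sklearn_pls.PLSRegression(n_components=k, scale=True).fit(X, y)
            np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_scores_are_mutually_orthogonal(self):
        X, y = random_problem(4, n=70, p=6)
        x_mean, x_std = X.mean(0), X.std(0)
        model = plsr_fit(X, y, n_components=4)
        Xc = (X - x_mean) / x_std
        # reconstruct scores by running the deflation forward
        scores = []
        for k in range(4):
            t = Xc @ model.weights[:, k]
            scores.append(t)
            Xc = Xc - np.outer(t, model.x_loadings[:, k])
        T = np.column_stack(scores)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_duplicated_column_weights_split_and_fit_subspace_unchanged(self):
        """Duplicating a predictor splits its weight symmetrically and leaves
        the fitted subspace (hence full-rank predictions) unchanged."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(scale=0.4, size=50)
        single = plsr_fit(x[:, None], y, n_components=1).predict(x[:, None])
        dup_model = plsr_fit(np.column_stack([x, x]), y, n_components=1)
        np.testing.assert_allclose(
            dup_model.predict(np.column_stack([x, x])), single, atol=1e-8
        )
        assert dup_model.weights[0, 0] == pytest.approx(dup_model.weights[1, 0])

        X, yv = random_problem(5, n=50, p=3)
        dup = np.column_stack([X, X[:, 0]])
        p1 = plsr_fit(X, yv, n_components=3).predict(X)
        p2 = plsr_fit(dup, yv, n_components=3).predict(dup)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        X, y = random_problem(6, n=40, p=3)
        Xc = np.column_stack([X, np.full(40, 7.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            model = plsr_fit(Xc, y, n_components=2)
        assert model.coef[-1] == 0.0

    def test_excess_components_rejected(self):
        X, y = random_problem(7, n=30, p=4)
        with pytest.raises(RankError):
            plsr_fit(X, y, n_components=5)

    def test_pure_noise_has_no_in_sample_fit(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 5))
        y = rng.normal(size=2000)
        model = plsr_fit(X, y, n_components=1)
        resid = y - model.predict(X)
        r2 = 1 - resid.var() / y.var()
        assert r2 < 0.01


class TestLOOCV:
    def test_noiseless_linear_signal_is_recovered(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = 2.0 + 5.0 * x
        r2, rmse = loocv_metrics(x[:, None], y, n_components=1)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert rmse == pytest.approx(0.0, abs=1e-8)

    def test_permuted_outcome_has_no_predictive_power(self):
        cfg = CohortConfig(n=126, seed=31)
        X, y = design_matrix(generate_cohort_frame(cfg))
        rng = np.random.default_rng(31)
        r2, _ = loocv_metrics(X, rng.permutation(y), n_components=2)
        assert r2 <= 0.05

    def test_loocv_does_not_beat_in_sample_fit(self):
        cfg = CohortConfig(n=126, seed=32)
        X, y = design_matrix(generate_cohort_frame(cfg))
        model = plsr_fit(X, y, n_components=2)
        in_sample_r2 = 1 - np.var(y - model.predict(X)) / np.var(y)
        loo_r2, _ = loocv_metrics(X, y, n_components=2)
        assert loo_r2 <= in_sample_r2 + 1e-9

    def test_degenerate_outcome_rejected(self):
        X, _ = random_problem(10, n=20)
        with pytest.raises(ParameterError):
            loocv_metrics(X, np.full(20, 3.0), n_components=1)


class TestOddsRatio:
    def test_balanced_table_has_unit_odds_ratio(self):
        res = adjusted_odds_ratio(frame_from_counts(10, 10, 10, 10), adjustment=())
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_closed_form_agreement(self):
        res = adjusted_odds_ratio(frame_from_counts(20, 10, 10, 20), adjustment=())
        assert res.odds_ratio == pytest.approx(4.0, abs=1e-8)

    def test_random_tables_match_ad_over_bc(self):
        """Covariate-free IRLS equals the closed-form 2x2 odds ratio."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b, c, d = rng.integers(3, 60, size=4)
            res = adjusted_odds_ratio(frame_from_counts(a, b, c, d), adjustment=())
            assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-8)
            assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_swapping_arms_inverts_the_odds_ratio(self):
        frame = frame_from_counts(25, 12, 9, 30)
        res = adjusted_odds_ratio(frame, adjustment=())
        flipped = frame.assign(aligned=~frame["aligned"])
        res_f = adjusted_odds_ratio(flipped, adjustment=())
        assert res_f.odds_ratio == pytest.approx(1.0 / res.odds_ratio, rel=1e-8)

    def test_relabelling_exposure_and_outcome_preserves_or(self):
        frame = frame_from_counts(25, 12, 9, 30)
        res = adjusted_odds_ratio(frame, adjustment=())
        both = frame.assign(aligned=~frame["aligned"], responder=~frame["responder"])
        res_b = adjusted_odds_ratio(both, adjustment=())
        assert res_b.odds_ratio == pytest.approx(res.odds_ratio, rel=1e-8)

    def test_single_arm_rejected(self):
        frame = frame_from_counts(10, 10, 0, 0).query("aligned")
        with pytest.raises(ParameterError):
            adjusted_odds_ratio(frame, adjustment=())

    def test_independent_covariates_leave_or_near_crude(self):
        frame = generate_cohort_frame(CohortConfig(n=20000, seed=41))
        crude = adjusted_odds_ratio(frame, adjustment=()).odds_ratio
        adjusted = adjusted_odds_ratio(frame, adjustment=("age", "sex")).odds_ratio
        assert adjusted == pytest.approx(crude, rel=0.02)


class TestSubgroupAnalysis:
    def test_rates_and_reference_arm(self):
        frame = generate_cohort_frame(CohortConfig(n=100000, seed=42))
        table = subgroup_analysis(frame).set_index("stratum")
        assert table.loc["A1", "responder_pct"] == pytest.approx(78.4, abs=1.0)
        assert table.loc["N", "responder_pct"] == pytest.approx(44.1, abs=1.0)
        assert np.isnan(table.loc["N", "crude_or"])
        assert table.loc["A1", "crude_or"] > table.loc["A3", "crude_or"]

    def test_all_responder_stratum_flagged_infinite(self):
        frame = generate_cohort_frame(CohortConfig(n=300, seed=43)).copy()
        mask = frame["stratum"] == "A1"
        frame.loc[mask, "womac_improvement"] = 90.0
        frame.loc[mask, "responder"] = True
        table = subgroup_analysis(frame).set_index("stratum")
        assert np.isinf(table.loc["A1", "crude_or"])
        assert table.loc["A1", "responder_pct"] == 100.0

    def test_empty_stratum_reported_missing(self):
        frame = generate_cohort_frame(
            CohortConfig(n=500, stratum_weights=(0.5, 0.5, 0.0), seed=44)
        )
        table = subgroup_analysis(frame).set_index("stratum")
        assert table.loc["A3", "n"] == 0
        assert np.isnan(table.loc["A3", "responder_pct"])


class TestValidateCohort:
    def test_bundle_is_consistent(self):
        frame = generate_cohort_frame(CohortConfig(seed=45))
        result = validate_cohort(frame)
        assert result.rmse_loocv >= 0
        assert result.r2_loocv <= 1
        assert result.or_ci[0] <= result.or_adjusted <= result.or_ci[1]
        assert set(result.subgroup_table["stratum"]) == {"A1", "A2", "A3", "N"}
        assert result.n_components == 2
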