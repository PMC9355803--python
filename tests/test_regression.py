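"""Outlier screening and stepwise hierarchical Huber regression."""

import numpy as np
import pandas as pd
import pytest

from f0track.regression import (
    OutlierConfig,
    StepwiseHierarchicalModel,
    anomaly_score,
    harmonic_number,
    huber_fit,
    isolation_forest_outliers,
    path_length_normalizer,
    stepwise_hierarchical,
)
from f0track.words import FEATURE_ORDER


class TestIsolationForest:
    def test_normalizer_hand_values(self):
        """c(2) = 2 H(1) - 2 (1/2) = 1 (harmonic-number formula by hand)."""
        assert path_length_normalizer(2) == pytest.approx(1.0)
        assert harmonic_number(3) == pytest.approx(1 + 0.5 + 1 / 3)
        # c(4) = 2(1 + 1/2 + 1/3) - 2*3/4
        assert path_length_normalizer(4) == pytest.approx(2 * (11 / 6) - 1.5)

    def test_root_isolated_point_score(self):
        """E[h] = 1 in a 256-point subsample: s = 2^(-1/c(256))."""
        c = path_length_normalizer(256)
        assert anomaly_score(1.0, 256) == pytest.approx(2 ** (-1.0 / c))
        assert anomaly_score(1.0, 256) > 0.5  # flagged by the auto rule

    def test_extreme_point_flagged(self, rng):
        data = rng.standard_normal((1000, 8))
        data = np.vstack([data, np.full((1, 8), 10.0)])
        mask = isolation_forest_outliers(data, OutlierConfig(n_trees=200, seed=0))
        assert not mask[-1]
        assert mask[:-1].mean() > 0.8

    def test_identical_points_all_kept(self):
        data = np.ones((50, 3))
        mask = isolation_forest_outliers(data, OutlierConfig(n_trees=10, seed=0))
        assert mask.all()

    def test_deterministic_given_seed(self, rng):
        data = rng.standard_normal((300, 4))
        cfg = OutlierConfig(n_trees=100, seed=7)
        assert np.array_equal(
            isolation_forest_outliers(data, cfg), isolation_forest_outliers(data, cfg)
        )


class TestHuberFit:
    def test_exact_line(self, rng):
        x = rng.standard_normal(200)
        fit = huber_fit(x, 0.5 * x)
        assert fit.coeff == pytest.approx(0.5, abs=1e-8)
        assert fit.p < 1e-10
        assert fit.se < 1e-8
        assert fit.ci[0] <= 0.5 <= fit.ci[1]

    def test_robust_to_gross_outliers(self, rng):
        """1% gross outliers at the high-leverage points: Huber beats OLS
        (the OLS oracle) on every seeded replicate."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 1000
            x = r.standard_normal(n)
            y = 0.5 * x + 0.3 * r.standard_normal(n)
            bad = np.argsort(x)[-(n // 100):]  # contaminate where leverage is high
            y[bad] = 20.0
            ols = (x @ y) / (x @ x)
            fit = huber_fit(x, y)
            assert abs(fit.coeff - 0.5) < abs(ols - 0.5)

    def test_null_coefficient_calibration(self):
        """Independent x, y (n = 2000): |coeff| small and p > 0.05 in >= 90%
        of replicates (null simulation)."""
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            r = np.random.default_rng(1000 + seed)
            fit = huber_fit(r.standard_normal(2000), r.standard_normal(2000))
            if abs(fit.coeff) < 0.06 and fit.p > 0.05:
                ok += 1
        assert ok >= 0.9 * n_rep

    def test_matches_statsmodels_rlm(self, rng):
        """Independent IRLS oracle: statsmodels RLM with HuberT(1.345) and
        MAD scale converges to the same coefficient."""
        import statsmodels.api as sm

        x = rng.standard_normal(500)
        y = 0.3 * x + rng.standard_normal(500)
        y[::50] += 8.0
        fit = huber_fit(x, y)
        rlm = sm.RLM(y, x[:, None], M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad", maxiter=300
        )
        assert fit.coeff == pytest.approx(float(rlm.params[0]), abs=1e-4)

    def test_constant_predictor_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            huber_fit(np.zeros(100), rng.standard_normal(100))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 10"):
            huber_fit(np.arange(5.0), np.arange(5.0))


def _standardize(a):
    return (a - a.mean(0)) / a.std(0)


class TestStepwiseHierarchical:
    def test_orthogonal_features_match_simple_slopes(self, rng):
        """With mutually orthogonal predictors every stepwise coefficient
        equals its simple-regression slope on the original scores
        (per-feature fit oracle).

        Huber reweighting makes the step fits only approximately
        orthogonal projections, so the oracle agreement carries a small
        practical tolerance rather than machine precision.
        """
        n = 2000
        Q = np.linalg.qr(rng.standard_normal((n, 7)))[0] * np.sqrt(n)
        y = Q @ np.array([0.3, -0.2, 0.1, 0.0, 0.05, -0.1, 0.02]) + 0.5 * rng.standard_normal(n)
        ys = _standardize(y)
        res = stepwise_hierarchical(Q, ys)
        for k in range(7):
            simple = huber_fit(Q[:, k], ys).coeff
            assert res.table["coeff"].iloc[k] == pytest.approx(simple, abs=0.01)
        # order permutation leaves coefficients unchanged for orthogonal x
        perm = [3, 1, 0, 6, 4, 2, 5]
        res_p = stepwise_hierarchical(Q[:, perm], ys)
        for pos, k in enumerate(perm):
            assert res_p.table["coeff"].iloc[pos] == pytest.approx(
                res.table["coeff"].iloc[k], abs=0.01
            )

    def test_order_dependence_for_correlated_features(self, rng):
        n = 3000
        x1 = rng.standard_normal(n)
        x2 = 0.8 * x1 + 0.6 * rng.standard_normal(n)
        y = x1 + rng.standard_normal(n)
        X = _standardize(np.column_stack([x1, x2]))
        a = stepwise_hierarchical(X, _standardize(y), order=("a", "b"))
        b = stepwise_hierarchical(X[:, ::-1], _standardize(y), order=("b", "a"))
        # the second-fitted coefficient differs when the order is swapped
        assert abs(a.table["coeff"].iloc[1] - b.table["coeff"].iloc[0]) > 0.1

    def test_residual_variance_non_increasing(self, rng):
        n = 2000
        X = _standardize(rng.standard_normal((n, 7)))
        y = _standardize(X @ rng.normal(0, 0.3, 7) + rng.standard_normal(n))
        res = stepwise_hierarchical(X, y)
        # Huber slopes are not exactly the variance-minimizing ones, so
        # allow a sliver of numerical/reweighting slack on each step
        assert np.all(np.diff(res.residual_variance) <= 1e-4)

    def test_null_scores_rarely_significant(self):
        """Pure-noise scores, n = 3000: almost never any BY-significant
        feature (null simulation over 30 replicates)."""
        bad = 0
        n_rep = 30
        for seed in range(n_rep):
            r = np.random.default_rng(2000 + seed)
            X = _standardize(r.standard_normal((3000, 7)))
            y = _standardize(r.standard_normal(3000))
            res = stepwise_hierarchical(X, y)
            if (res.table["p_fdr"] < 0.05).any():
                bad += 1
        assert bad <= max(1, int(0.05 * n_rep))

    def test_planted_betas_recovered_with_correlated_features(self):
        """Scores = -0.17 x1 - 0.07 x2 - 0.04 x4 + noise on features with
        the naturalistic correlation structure: signs recovered, x1 and
        x2 BY-significant in >= 90% of replicates at n = 5732."""
        from f0track.synthetic import correlated_word_features

        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            r = np.random.default_rng(3000 + seed)
            feats = correlated_word_features(5732, seed=seed)
            X = _standardize(feats[list(FEATURE_ORDER)].to_numpy())
            y = -0.17 * X[:, 0] - 0.07 * X[:, 1] - 0.04 * X[:, 3] + r.standard_normal(5732)
            res = stepwise_hierarchical(X, _standardize(y))
            t = res.table
            ok = (
                t["coeff"].iloc[0] < 0
                and t["coeff"].iloc[1] < 0
                and t["p_fdr"].iloc[0] < 0.05
                and t["p_fdr"].iloc[1] < 0.05
            )
            hits += ok
        assert hits >= 9

    def test_outlier_screen_changes_little_on_clean_data(self, rng):
        """With clean Gaussian data the isolation-forest step barely moves
        the coefficients and leaves every significance call unchanged."""
        feats = pd.DataFrame(
            _standardize(rng.standard_normal((4000, 7))), columns=FEATURE_ORDER
        )
        y = feats.to_numpy() @ np.array([-0.2, 0.1, 0, 0, 0, 0.05, 0]) + rng.standard_normal(4000)
        with_screen = StepwiseHierarchicalModel(feats, y, outlier_config=OutlierConfig(n_trees=200, seed=0)).fit()
        without = StepwiseHierarchicalModel(feats, y, outlier_config=None).fit()
        diff = np.abs(with_screen.table["coeff"].to_numpy() - without.table["coeff"].to_numpy())
        # the auto threshold trims a few percent even of clean data, so
        # allow two standard errors; the inferential conclusions must agree
        assert np.all(diff < 2 * without.table["se"].to_numpy())
        assert np.array_equal(
            with_screen.table["p_fdr"] < 0.05, without.table["p_fdr"] < 0.05
        )

    def test_summary_formats_table(self, rng):
        feats = pd.DataFrame(rng.standard_normal((500, 7)), columns=FEATURE_ORDER)
        res = StepwiseHierarchicalModel(feats, rng.standard_normal(500), outlier_config=None).fit()
        text = res.summary()
        assert "Coeff." in text and "p (FDR)" in text
        for name in FEATURE_ORDER:
            assert name in text
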