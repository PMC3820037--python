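"""Logistic fits, BCa bootstrap, AUC machinery — against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from frailcast import stats


def _data_from_2x2(a, b, c, d):
    """exposed cases a, exposed noncases b, unexposed cases c, unexposed noncases d."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x, y


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = stats.fit_logistic(np.empty((100, 0)), y)
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    @pytest.mark.parametrize("a,b,c,d", [
        (122, 969, 119, 1497),   # incident diabetes by dichotomized frailty status
        (10, 20, 30, 40),
        (5, 45, 12, 38),
    ])
    def test_single_binary_predictor_matches_crossproduct_oracle(self, a, b, c, d):
        x, y = _data_from_2x2(a, b, c, d)
        fit = stats.fit_logistic(x.reshape(-1, 1), y)
        beta = fit.params.iloc[1]
        assert beta == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)
        assert fit.se.iloc[1] == pytest.approx(
            np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-8)

    def test_frailty_diabetes_contingency_or(self):
        """The printed incident-diabetes counts give the hand 2x2 odds ratio."""
        x, y = _data_from_2x2(122, 969, 119, 1497)
        fit = stats.fit_logistic(x.reshape(-1, 1), y)
        assert np.exp(fit.params.iloc[1]) == pytest.approx(
            (122 * 1497) / (969 * 119), rel=1e-8)

    def test_matches_reference_implementation(self):
        """Agreement with an independent ML fit on 50 random small datasets."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(40, 90))
            X = rng.normal(size=(n, 2))
            eta = -0.3 + X @ np.array([0.8, -0.5])
            y = (rng.random(n) < expit(eta)).astype(float)
            if y.min() == y.max():
                continue
            ours = stats.fit_logistic(X, y)
            ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit(tol=1e-12)
            assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-6)
            assert np.allclose(ours.cov.to_numpy(), ref.cov_params(), rtol=1e-4, atol=1e-8)

    def test_convergence_metadata(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(x)).astype(float)
        fit = stats.fit_logistic(x.reshape(-1, 1), y)
        assert fit.converged and fit.score_norm < 1e-8 and fit.iterations <= 100
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(stats.ConvergenceError):
            stats.fit_logistic(x.reshape(-1, 1), y)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": np.arange(30.0), "b": 2 * np.arange(30.0)})
        y = (np.arange(30) % 2).astype(float)
        with pytest.raises(stats.RankDeficiencyError, match="a|b"):
            stats.fit_logistic(X, y)


class TestStandardizedOr:
    def test_null_case_covers_one(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(10_000)
        y = (rng.random(10_000) < 0.3).astype(float)
        res = stats.standardized_or(z, y)
        assert res.ci_low < 1 < res.ci_high
        assert abs(res.odds_ratio - 1) < 0.1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(20_000)
        y = (rng.random(20_000) < expit(-0.5 + np.log(1.4) * z)).astype(float)
        res = stats.standardized_or(z, y)
        assert res.ci_low < 1.4 < res.ci_high

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(3, 2, 3000)
        y = (rng.random(3000) < expit(-1 + 0.3 * raw)).astype(float)
        z1 = (raw - raw.mean()) / raw.std(ddof=1)
        raw2 = 2 * raw
        z2 = (raw2 - raw2.mean()) / raw2.std(ddof=1)
        r1 = stats.standardized_or(z1, y)
        r2 = stats.standardized_or(z2, y)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-10)


class TestBCa:
    def test_symmetric_statistic_close_to_percentile(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(120)
        res = stats.bca_ci(lambda d: d.mean(axis=-1), x, B=5000, seed=3, vectorized=True)
        assert abs(res.z0) < 0.08
        lo_pct, hi_pct = np.quantile(
            x[np.random.default_rng(99).integers(0, 120, (5000, 120))].mean(axis=1),
            [0.025, 0.975])
        scale = x.std() / np.sqrt(120)
        assert abs(res.low - lo_pct) < 0.5 * scale
        assert abs(res.high - hi_pct) < 0.5 * scale

    def test_adjusted_levels_reduce_to_percentile(self):
        assert stats.adjusted_quantile_levels(0.0, 0.0, 0.05) == pytest.approx((0.025, 0.975))

    def test_seed_reproducibility(self):
        x = np.random.default_rng(2).exponential(size=80)
        r1 = stats.bca_ci(np.mean, x, B=400, seed=5)
        r2 = stats.bca_ci(np.mean, x, B=400, seed=5)
        assert (r1.low, r1.high) == (r2.low, r2.high)

    def test_degenerate_distribution_collapses_with_warning(self):
        x = np.ones(50)
        with pytest.warns(UserWarning, match="degenerate"):
            res = stats.bca_ci(np.mean, x, B=300, seed=1)
        assert res.low == res.high == 1.0

    def test_agrees_with_independent_bca_implementation(self):
        from scipy.stats import bootstrap

        rng = np.random.default_rng(17)
        x = rng.exponential(size=150)
        ours = stats.bca_ci(lambda d: d.mean(axis=-1), x, B=4000, seed=8, vectorized=True)
        ref = bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                        random_state=np.random.default_rng(8))
        scale = x.std() / np.sqrt(150)
        assert abs(ours.low - ref.confidence_interval.low) < 0.3 * scale
        assert abs(ours.high - ref.confidence_interval.high) < 0.3 * scale

    def test_rejects_tiny_B(self):
        with pytest.raises(ValueError):
            stats.bca_ci(np.mean, np.arange(10.0), B=50)


@pytest.fixture(scope="module")
def paired_scores():
    rng = np.random.default_rng(21)
    n = 1200
    u = rng.standard_normal(n)
    a = u + rng.standard_normal(n)
    b = u + 0.5 * rng.standard_normal(n)
    y = (rng.random(n) < expit(-0.5 + 0.5 * u)).astype(float)
    return a, b, y


class TestOrDifference:
    def test_self_comparison_is_null(self, paired_scores):
        a, _, y = paired_scores
        with pytest.warns(UserWarning, match="degenerate"):
            d = stats.or_difference(a, a, y, B=300, seed=4)
        assert d.delta == 0 and d.ci_low <= 0 <= d.ci_high

    def test_antisymmetry_under_swap(self, paired_scores):
        a, b, y = paired_scores
        d1 = stats.or_difference(a, b, y, B=400, seed=9)
        d2 = stats.or_difference(b, a, y, B=400, seed=9)
        assert d1.delta == pytest.approx(-d2.delta, rel=1e-10)
        assert d1.ci_low == pytest.approx(-d2.ci_high, rel=1e-6)
        assert d1.ci_high == pytest.approx(-d2.ci_low, rel=1e-6)

    def test_sign_recovery_with_distinct_effects(self):
        """Stronger true effect for score b gives a positive delta."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 6
        for _ in range(reps):
            n = 2500
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            y = (rng.random(n) < expit(-0.4 + 0.05 * a + 0.5 * b)).astype(float)
            d = stats.or_difference(a, b, y, B=300, seed=int(rng.integers(2**31)))
            hits += d.delta > 0
        assert hits >= reps * 0.95


class TestAuc:
    def test_worked_examples(self):
        assert stats.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert stats.auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_null_score(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(10_000)
        y = (rng.random(10_000) < 0.4).astype(float)
        assert abs(stats.auc(s, y) - 0.5) < 0.02

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            stats.auc([1, 2, 3], [1, 1, 1])

    def test_equals_bruteforce_concordance_with_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            s = rng.integers(0, 8, n).astype(float)   # heavy ties
            y = (rng.random(n) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            pos, neg = s[y == 1], s[y == 0]
            brute = np.mean((pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :]))
            assert stats.auc(s, y) == pytest.approx(brute, abs=1e-12)


class TestAucDifference:
    def test_self_difference_zero(self):
        rng = np.random.default_rng(23)
        s = rng.standard_normal(300)
        y = (rng.random(300) < 0.5).astype(float)
        d = stats.auc_difference(s, s, y, method="delong")
        assert d.delta == 0.0

    def test_delong_and_bootstrap_agree(self):
        rng = np.random.default_rng(29)
        n = 800
        u = rng.standard_normal(n)
        y = (rng.random(n) < expit(u)).astype(float)
        a = u + 1.2 * rng.standard_normal(n)
        b = u + 0.6 * rng.standard_normal(n)
        dl = stats.auc_difference(a, b, y, method="delong")
        bs = stats.auc_difference(a, b, y, method="paired_bootstrap_bca", B=2000, seed=5)
        w_dl = dl.ci_high - dl.ci_low
        w_bs = bs.ci_high - bs.ci_low
        assert dl.delta == pytest.approx(bs.delta, abs=1e-12)
        assert abs(w_dl - w_bs) / w_dl < 0.10
        assert dl.ci_low < dl.delta < dl.ci_high

    def test_binormal_coverage_spot_check(self):
        """CI covers the closed-form binormal AUC difference in most replicates."""
        rng = np.random.default_rng(37)
        from scipy.special import ndtr
        mu_a, mu_b = 0.6, 1.2
        true_auc = lambda mu: ndtr(mu / np.sqrt(2))
        true_delta = true_auc(mu_b) - true_auc(mu_a)
        cover = 0
        reps = 30
        for _ in range(reps):
            n = 500
            y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
            noise = rng.standard_normal((2, n))
            a = noise[0] + mu_a * y
            b = noise[1] + mu_b * y
            d = stats.auc_difference(a, b, y, method="delong")
            cover += d.ci_low <= true_delta <= d.ci_high
        assert cover >= 0.85 * reps


class TestSexInteraction:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(41)
        n = 3000
        z = rng.standard_normal(n)
        sex = np.where(rng.random(n) < 0.4, "female", "male")
        y = (rng.random(n) < expit(-0.5 + 0.3 * z)).astype(float)
        p1 = stats.sex_interaction_test(z, sex, y)
        swapped = np.where(sex == "female", "male", "female")
        p2 = stats.sex_interaction_test(z, swapped, y)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_power_for_opposite_effects(self):
        rng = np.random.default_rng(43)
        sig = 0
        for _ in range(10):
            n = 5000
            z = rng.standard_normal(n)
            female = rng.random(n) < 0.5
            beta = np.where(female, 0.4, -0.4)
            y = (rng.random(n) < expit(-0.3 + beta * z)).astype(float)
            sex = np.where(female, "female", "male")
            sig += stats.sex_interaction_test(z, sex, y) < 0.01
        assert sig >= 9

    def test_null_calibration(self):
        """Under a common effect across sexes, interaction p-values are uniform."""
        from scipy.stats import kstest

        rng = np.random.default_rng(47)
        pvals = []
        for _ in range(300):
            n = 500
            z = rng.standard_normal(n)
            female = rng.random(n) < 0.5
            y = (rng.random(n) < expit(-0.2 + 0.3 * z)).astype(float)
            sex = np.where(female, "female", "male")
            pvals.append(stats.sex_interaction_test(z, sex, y))
        assert kstest(pvals, "uniform").pvalue > 0.01
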