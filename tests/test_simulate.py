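"""Synthetic cohort generator: determinism, marginal fidelity, calibration."""

import numpy as np
import pandas as pd
import pytest

from frailcast import frailty, simulate
from frailcast.cohort import derive_features


def test_full_determinism_under_fixed_seed():
    cfg = simulate.SyntheticConfig(n=500, seed=77)
    df1 = simulate.generate_cohort(cfg)
    df2 = simulate.generate_cohort(simulate.SyntheticConfig(n=500, seed=77))
    pd.testing.assert_frame_equal(df1, df2)


def test_config_validation():
    with pytest.raises(ValueError):
        simulate.SyntheticConfig(n=0).validate()
    bad = simulate.SyntheticConfig()
    bad.marginals["smoking"] = {"non": 0.7, "former": 0.7, "current": -0.4}
    with pytest.raises(ValueError):
        bad.validate()


def test_marginal_fidelity(cohort_df):
    """Configured categorical marginals are reproduced within 3 Monte-Carlo SEs
    on the diabetes-free subsample the Table-1 margins describe."""
    df = cohort_df[~cohort_df["prevalent_diabetes"]]
    n = len(df)

    def check(observed, target):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(observed - target) < 3 * se + 1e-9, (observed, target)

    check((df["sex"] == "female").mean(), simulate._p("female"))
    check(df["family_history_diabetes"].mean(), simulate._p("family_history_diabetes"))
    check((~df["physical_activity_4h"]).mean(), simulate._p("low_physical_activity"))
    check(df["daily_fruit_veg"].mean(), simulate._p("daily_fruit_veg"))
    for cat, p in simulate._p("bmi_category").items():
        check((df["bmi_category"] == cat).mean(), p)
    for cat, p in simulate._p("smoking").items():
        check((df["smoking"] == cat).mean(), p)
    # derived flags recomputed from the continuous realisations
    rd = derive_features(df)
    check(rd["ifg"].mean(), simulate._p("ifg"))
    check(rd["hdl_low"].mean(), simulate._p("hdl_low"))
    check(rd["elevated_bp"].mean(), simulate._p("elevated_bp"))
    check(rd["tg_high_100"].mean(), simulate._p("tg_high_100"))


def test_age_distribution_truncated(cohort_df):
    assert cohort_df["age"].min() >= 45 and cohort_df["age"].max() <= 69
    # truncation to [45, 69] trims more of the lower tail, lifting the mean ~0.5 y
    assert cohort_df["age"].mean() == pytest.approx(55.46, abs=0.5)


class TestFrailtyCalibration:
    def test_targets_reproduced_by_solver(self):
        p, rho = simulate.calibrate_frailty(0.597, 0.028)
        dist = simulate.score_distribution(p, rho)
        assert dist[0] == pytest.approx(0.597, abs=1e-3)
        assert dist[3:].sum() == pytest.approx(0.028, abs=1e-3)
        # prefrail follows by complementarity
        assert dist[1:3].sum() == pytest.approx(0.375, abs=2e-3)

    def test_independence_cannot_reach_both_targets(self):
        """With rho=0 and P(score=0)=0.597, P(score>=3) stays below 1%."""
        p0 = 1 - 0.597 ** (1 / 5)
        dist = simulate.score_distribution(p0, 0.0)
        assert dist[0] == pytest.approx(0.597, abs=1e-9)
        assert dist[3:].sum() < 0.01

    def test_near_independent_targets_give_small_rho(self):
        p0 = 1 - 0.597 ** (1 / 5)
        dist0 = simulate.score_distribution(p0, 0.0)
        p, rho = simulate.calibrate_frailty(dist0[0], dist0[3:].sum() + 1e-6)
        assert rho < 0.02

    def test_frail_mass_increasing_in_rho(self):
        p = 0.11
        masses = [simulate.score_distribution(p, r)[3:].sum() for r in (0.0, 0.2, 0.4, 0.6)]
        assert all(b > a for a, b in zip(masses, masses[1:]))

    def test_comonotone_limit_concentrates_on_extremes(self):
        rng = np.random.default_rng(55)
        comp = simulate.generate_fried_components(20_000, 0.11, 0.9999, rng)
        scores = comp.sum(axis=1).to_numpy()
        assert np.isin(scores, (0, 5)).mean() > 0.99

    def test_infeasible_targets_error(self):
        with pytest.raises(ValueError):
            simulate.calibrate_frailty(0.7, 0.4)


def test_component_marginals_and_roundtrip():
    p, rho = simulate.calibrate_frailty()
    rng = np.random.default_rng(123)
    comp = simulate.generate_fried_components(100_000, p, rho, rng)
    prev = comp.mean()
    assert np.all(np.abs(prev - p) < 0.005)
    scores = comp.sum(axis=1).to_numpy()
    status = frailty.status_from_scores(scores)
    assert abs((status == "nonfrail").mean() - 0.597) < 0.006
    assert abs((status == "frail").mean() - 0.028) < 0.003


def test_raw_fried_measures_recover_indicators(cohort_df):
    """Classifying the back-filled raw measures reproduces the indicators."""
    raw = cohort_df.drop(columns=list(frailty.COMPONENTS))
    assessed = frailty.assess(raw)
    for c in frailty.COMPONENTS:
        assert (assessed[c].astype(bool) == cohort_df[c].astype(bool)).all()


class TestOutcomes:
    def test_null_effect_prevalence_matches_intercept(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(50_000)
        y = simulate.generate_outcomes(z, per_sd_or=1.0, target_prevalence=0.25, rng=rng)
        assert abs(y.mean() - 0.25) < 0.01

    def test_prevalence_calibration_with_effect(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(100_000)
        y = simulate.generate_outcomes(z, per_sd_or=1.27, target_prevalence=0.089, rng=rng)
        assert abs(y.mean() - 0.089) < 0.003

    def test_parameter_recovery(self):
        from frailcast.stats import standardized_or

        rng = np.random.default_rng(11)
        z = rng.standard_normal(100_000)
        z = (z - z.mean()) / z.std(ddof=1)
        y = simulate.generate_outcomes(z, per_sd_or=1.27, target_prevalence=0.4, rng=rng)
        res = standardized_or(z, y.astype(float))
        assert res.ci_low < 1.27 < res.ci_high


class TestMissingness:
    def test_zero_rate_is_identity(self, cohort_df):
        out = simulate.inject_missingness(cohort_df, "MCAR", {"bmi": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, cohort_df)

    def test_mcar_rate(self):
        df = pd.DataFrame({"a": np.zeros(10_000), "b": np.ones(10_000)})
        out = simulate.inject_missingness(df, "MCAR", {"a": 0.2}, seed=2)
        assert abs(out["a"].isna().mean() - 0.2) < 0.01

    def test_mar_mask_depends_on_covariates_mcar_does_not(self):
        from frailcast.stats import fit_logistic

        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=8000), "v": rng.normal(size=8000)})
        mar = simulate.inject_missingness(df, "MAR", {"v": 0.3}, seed=4, mar_predictors=["x"])
        mcar = simulate.inject_missingness(df, "MCAR", {"v": 0.3}, seed=4)
        for masked, should_depend in ((mar, True), (mcar, False)):
            mask = masked["v"].isna().to_numpy(dtype=float)
            fit = fit_logistic(df[["x"]], mask)
            p = fit.wald_p("x")
            assert (p < 0.01) is should_depend

    def test_rate_validation_and_reproducibility(self, cohort_df):
        with pytest.raises(ValueError):
            simulate.inject_missingness(cohort_df, "MCAR", {"bmi": 1.0}, seed=1)
        a = simulate.inject_missingness(cohort_df, "MCAR", {"bmi": 0.3}, seed=9)
        b = simulate.inject_missingness(cohort_df, "MCAR", {"bmi": 0.3}, seed=9)
        pd.testing.assert_frame_equal(a, b)
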