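"""Fried frailty phenotype: component rules, score/status mapping, boundaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailcast import frailty

EPS = 1e-6


class TestExhaustion:
    def test_negative_responses(self):
        assert frailty.classify_exhaustion("rarely_or_none", "rarely_or_none") is False
        assert frailty.classify_exhaustion("some_or_little", "some_or_little") is False

    def test_one_positive_item_suffices(self):
        assert frailty.classify_exhaustion("occasionally_or_moderate", "rarely_or_none") is True
        assert frailty.classify_exhaustion(None, "most_or_all") is True

    def test_both_missing(self):
        assert frailty.classify_exhaustion(None, None) is None

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            frailty.classify_exhaustion("sometimes", "rarely_or_none")


class TestEnergyExpenditure:
    def test_definitional_cases(self):
        assert frailty.energy_expenditure([], 70) == 0
        assert frailty.energy_expenditure([(1, 1)], 70) == 70

    def test_hand_sum(self):
        # 8 MET x 0.5 h x 60 kg + 3 MET x 2 h x 60 kg
        assert frailty.energy_expenditure([(8, 0.5), (3, 2)], 60) == pytest.approx(600)

    def test_reference_mass_switch(self):
        assert frailty.energy_expenditure([(2, 1)], 80, reference_mass_kg=60) == 120

    def test_negative_hours_error(self):
        with pytest.raises(ValueError):
            frailty.energy_expenditure([(2, -1)], 70)


# every printed threshold exercised at value, value - eps, value + eps
LOW_ACTIVITY_GRID = [
    (383.0, "male"), (270.0, "female"),
]
WALK_GRID = [
    # (time threshold, sex, height) at the stratum the threshold applies to
    (3.73, "male", 173.0), (3.20, "male", 173.0 + 1), (3.73, "female", 159.0), (3.20, "female", 159.0 + 1),
]
GRIP_GRID = [
    (29.0, "male", 24.0), (30.0, "male", 28.0), (32.0, "male", 28.1),
    (17.0, "female", 23.0), (17.3, "female", 26.0), (18.0, "female", 29.0), (21.0, "female", 29.1),
]


@pytest.mark.parametrize("cut, sex", LOW_ACTIVITY_GRID)
def test_low_activity_boundary(cut, sex):
    assert frailty.classify_low_activity(cut - EPS, sex) is True   # strictly below
    assert frailty.classify_low_activity(cut, sex) is False
    assert frailty.classify_low_activity(cut + EPS, sex) is False


@pytest.mark.parametrize("cut, sex, height", WALK_GRID)
def test_slow_walk_boundary(cut, sex, height):
    assert frailty.classify_slow_walk(cut, sex, height) is True    # inclusive at the cut
    assert frailty.classify_slow_walk(cut - EPS, sex, height) is False
    assert frailty.classify_slow_walk(cut + EPS, sex, height) is True


def test_slow_walk_height_stratum_boundary():
    # at exactly the height bound the short-stature threshold applies
    assert frailty.classify_slow_walk(3.5, "male", 173.0) is False
    assert frailty.classify_slow_walk(3.5, "male", 173.0 + EPS) is True
    assert frailty.classify_slow_walk(3.5, "female", 159.0) is False
    assert frailty.classify_slow_walk(3.5, "female", 159.0 + EPS) is True


@pytest.mark.parametrize("cut, sex, bmi", GRIP_GRID)
def test_weak_grip_boundary(cut, sex, bmi):
    assert frailty.classify_weak_grip(cut, sex, bmi) is True       # inclusive at the cut
    assert frailty.classify_weak_grip(cut - EPS, sex, bmi) is True
    assert frailty.classify_weak_grip(cut + EPS, sex, bmi) is False


def test_weak_grip_bmi_stratum_half_open():
    # BMI 24 belongs to the low stratum (cut 29), just above to the middle (cut 30)
    assert frailty.classify_weak_grip(29.5, "male", 24.0) is False
    assert frailty.classify_weak_grip(29.5, "male", 24.0 + EPS) is True


def test_weight_loss_boundary():
    assert frailty.classify_weight_loss(100, 89.9) is True         # 10.1% loss
    assert frailty.classify_weight_loss(100, 90.0) is False        # exactly 10% is not frail
    assert frailty.classify_weight_loss(100, 90.0 - EPS) is True
    assert frailty.classify_weight_loss(80, 85) is False           # gain


class TestStatus:
    def test_three_level_mapping(self):
        assert frailty.frailty_status((False,) * 5).status == "nonfrail"
        a = frailty.frailty_status((True, True, False, False, False))
        assert (a.score, a.status) == (2, "prefrail")
        assert frailty.frailty_status((True,) * 3 + (False,) * 2).status == "frail"
        assert frailty.frailty_status((True,) * 5).score == 5

    def test_forced_status_with_missing(self):
        # three positives already decide frailty
        assert frailty.frailty_status((True, True, True, False, None)).status == "frail"
        # one positive, one missing: cannot reach 3, must be prefrail
        a = frailty.frailty_status((True, False, False, False, None))
        assert a.status == "prefrail" and a.score is None
        # all-negative observed with a missing component stays undetermined
        assert frailty.frailty_status((False, False, False, False, None)).status is None
        assert frailty.frailty_status((None,) * 5).status is None

    def test_no_physical_activity_mode_scores_out_of_four(self):
        comp = dict(exhaustion=True, low_activity=True, slow_walk=True,
                    weak_grip=False, weight_loss=False)
        assert frailty.frailty_status(comp).status == "frail"
        a = frailty.frailty_status(comp, mode="no_physical_activity")
        assert (a.score, a.status) == (2, "prefrail")

    @given(st.lists(st.booleans(), min_size=5, max_size=5), st.integers(0, 4))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_components(self, comps, flip):
        """Flipping any component to positive never moves status toward nonfrail."""
        order = {"nonfrail": 0, "prefrail": 1, "frail": 2}
        before = frailty.frailty_status(tuple(comps)).status
        comps2 = list(comps)
        comps2[flip] = True
        after = frailty.frailty_status(tuple(comps2)).status
        assert order[after] >= order[before]

    @given(st.lists(st.booleans(), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_fully_observed_partition(self, comps):
        a = frailty.frailty_status(tuple(comps))
        assert a.score == sum(comps) and 0 <= a.score <= 5
        assert a.status in frailty.STATUS_LEVELS


def test_assess_appends_columns(cohort_df):
    out = frailty.assess(cohort_df)
    assert {"frailty_score", "frailty_status"} <= set(out.columns)
    assert set(out["frailty_status"].unique()) <= set(frailty.STATUS_LEVELS)
    scores = out["frailty_score"].to_numpy()
    comp = out[list(frailty.COMPONENTS)].astype(bool).sum(axis=1).to_numpy()
    assert (scores == comp).all()


def test_assess_handles_missing_components(cohort_df):
    df = cohort_df.head(50).copy()
    df.loc[df.index[:10], "walk_time_8ft"] = np.nan
    df = df.drop(columns=["slow_walk"])
    out = frailty.assess(df)
    assert out["frailty_score"].isna().sum() <= 10
    assert out["frailty_score"].notna().sum() >= 40
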