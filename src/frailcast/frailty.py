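"""Fried frailty phenotype: five binary components, 0-5 score, 3-level status.

The phenotype is operationalised with the cohort's published cut-offs:

* exhaustion — either of two CES-D items endorsed at "occasionally or a
  moderate amount of the time (3-4 days)" or "most or all of the time
  (5-7 days)";
* low physical activity — leisure-time energy expenditure below 383 kcal/wk
  (men) or 270 kcal/wk (women), with expenditure computed as
  MET x hours x body mass (1 MET = 1 kcal/kg/h);
* slow walking — 8-foot walk time at or above a height-stratified threshold
  (3.73 s for men <=173 cm / women <=159 cm, else 3.20 s);
* weak grip — maximum dynamometer grip at or below a sex- and BMI-stratified
  cut-off;
* weight loss — more than 10% loss between the two most recent weighings
  (~5 years apart).

Score = number of positive components; 0 -> nonfrail, 1-2 -> prefrail,
>=3 -> frail. With partially missing components the status is forced only
when it is already determined (>=3 positives -> frail; >=1 positive and no
path to 3 -> prefrail); otherwise it is missing, matching a pipeline that
excludes participants with incomplete frailty data by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPONENTS = ("exhaustion", "low_activity", "slow_walk", "weak_grip", "weight_loss")

#: CES-D frequency-of-symptom categories, in increasing order. Responses are
#: rejected, not coerced, when outside this taxonomy.
CESD_RESPONSES = (
    "rarely_or_none",          # <1 day
    "some_or_little",          # 1-2 days
    "occasionally_or_moderate",  # 3-4 days
    "most_or_all",             # 5-7 days
)
_CESD_POSITIVE = frozenset({"occasionally_or_moderate", "most_or_all"})

KCAL_CUTOFF = {"male": 383.0, "female": 270.0}
WALK_HEIGHT_CUTOFF_CM = {"male": 173.0, "female": 159.0}
WALK_SLOW_SHORT_S = 3.73   # height at or below the sex-specific cut-off
WALK_SLOW_TALL_S = 3.20
# grip cut-offs (kg) by sex within half-open BMI strata (lo, hi]
GRIP_STRATA = {
    "male": ((-np.inf, 24.0, 29.0), (24.0, 28.0, 30.0), (28.0, np.inf, 32.0)),
    "female": ((-np.inf, 23.0, 17.0), (23.0, 26.0, 17.3), (26.0, 29.0, 18.0), (29.0, np.inf, 21.0)),
}
WEIGHT_LOSS_FRACTION = 0.10

STATUS_LEVELS = ("nonfrail", "prefrail", "frail")
FRAILTY_MODES = ("full", "no_physical_activity")


@dataclass
class FrailtyAssessment:
    """Component indicators, 0-5 score and 3-level status (None = missing)."""

    exhaustion: bool | None
    low_activity: bool | None
    slow_walk: bool | None
    weak_grip: bool | None
    weight_loss: bool | None
    score: int | None
    status: str | None


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def classify_exhaustion(resp1, resp2):
    """Exhaustion from the two CES-D items; one positive response suffices.

    Both missing -> missing. Unknown response strings raise ValueError.
    """
    responses = []
    for r in (resp1, resp2):
        if _is_missing(r):
            continue
        if r not in CESD_RESPONSES:
            raise ValueError(f"unknown CES-D response {r!r}; expected one of {CESD_RESPONSES}")
        responses.append(r)
    if not responses:
        return None
    return any(r in _CESD_POSITIVE for r in responses)


def energy_expenditure(activities, weight_kg, reference_mass_kg=None):
    """Weekly energy expenditure, kcal/wk: sum of MET x hours x body mass.

    ``activities`` is an iterable of ``(met_value, hours_per_week)``. With
    ``reference_mass_kg`` set (e.g. 60), that mass is used instead of the
    participant's weight, supporting weight-free questionnaire pipelines.
    """
    mass = reference_mass_kg if reference_mass_kg is not None else weight_kg
    if _is_missing(mass):
        return None
    if mass <= 0:
        raise ValueError("body mass must be positive")
    total = 0.0
    for met, hours in activities:
        if met < 1:
            raise ValueError(f"MET value {met} below resting level 1")
        if hours < 0:
            raise ValueError(f"negative hours per week: {hours}")
        total += met * hours * mass
    return total


def classify_low_activity(kcal_per_week, sex):
    """Low activity: expenditure strictly below 383 (men) / 270 (women) kcal/wk."""
    if sex not in KCAL_CUTOFF:
        raise ValueError(f"unknown sex {sex!r}")
    if _is_missing(kcal_per_week):
        return None
    if kcal_per_week < 0:
        raise ValueError("energy expenditure cannot be negative")
    return kcal_per_week < KCAL_CUTOFF[sex]


def classify_slow_walk(time_s, sex, height_cm):
    """Slow walking: 8-ft time >=3.73 s (short stratum) or >=3.20 s (tall).

    The height stratum bound is 173 cm for men and 159 cm for women,
    inclusive on the short side.
    """
    if _is_missing(time_s) or _is_missing(height_cm) or _is_missing(sex):
        return None
    if sex not in WALK_HEIGHT_CUTOFF_CM:
        raise ValueError(f"unknown sex {sex!r}")
    if time_s <= 0:
        raise ValueError("walk time must be positive")
    threshold = WALK_SLOW_SHORT_S if height_cm <= WALK_HEIGHT_CUTOFF_CM[sex] else WALK_SLOW_TALL_S
    return time_s >= threshold


def classify_weak_grip(grip_kg, sex, bmi):
    """Weak grip: maximum grip at or below the sex/BMI-stratified cut-off.

    Strata are half-open on the BMI axis ((24, 28] etc.) so every BMI value
    falls in exactly one stratum.
    """
    if _is_missing(grip_kg) or _is_missing(bmi) or _is_missing(sex):
        return None
    if sex not in GRIP_STRATA:
        raise ValueError(f"unknown sex {sex!r}")
    if grip_kg < 0:
        raise ValueError("grip strength cannot be negative")
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    for lo, hi, cutoff in GRIP_STRATA[sex]:
        if lo < bmi <= hi:
            return grip_kg <= cutoff
    raise AssertionError("unreachable: grip strata cover the positive line")


def classify_weight_loss(weight_prev, weight_followup):
    """Weight loss: strictly more than 10% decrease between the two weighings."""
    if _is_missing(weight_prev) or _is_missing(weight_followup):
        return None
    if weight_prev <= 0 or weight_followup <= 0:
        raise ValueError("weights must be positive")
    return (weight_prev - weight_followup) / weight_prev > WEIGHT_LOSS_FRACTION


def frailty_status(components, mode: str = "full") -> FrailtyAssessment:
    """Score and 3-level status from the five component indicators.

    ``components`` maps component names to True/False/None (or is a sequence
    in :data:`COMPONENTS` order). ``mode='no_physical_activity'`` drops the
    low-activity component and scores out of 4 with the same 0 / 1-2 / >=3
    mapping (for the sensitivity analysis that removes the overlap between
    the frailty scale and activity-based risk scores).

    With missing components, score is missing and status is forced only when
    already determined by the observed components.
    """
    if mode not in FRAILTY_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {FRAILTY_MODES}")
    if not isinstance(components, dict):
        components = dict(zip(COMPONENTS, components, strict=True))
    used = [c for c in COMPONENTS if mode == "full" or c != "low_activity"]
    values = {c: (None if _is_missing(components.get(c)) else bool(components[c])) for c in COMPONENTS}
    obs = [values[c] for c in used if values[c] is not None]
    n_pos = sum(obs)
    n_missing = len(used) - len(obs)

    score = n_pos if n_missing == 0 else None
    if len(obs) == 0:
        status = None
    elif n_pos >= 3:
        status = "frail"
    elif n_missing == 0:
        status = "prefrail" if n_pos >= 1 else "nonfrail"
    elif n_pos >= 1 and n_pos + n_missing <= 2:
        status = "prefrail"  # at least one positive and no path to three
    else:
        status = None
    return FrailtyAssessment(
        exhaustion=values["exhaustion"],
        low_activity=values["low_activity"],
        slow_walk=values["slow_walk"],
        weak_grip=values["weak_grip"],
        weight_loss=values["weight_loss"],
        score=score,
        status=status,
    )


def status_from_scores(scores: np.ndarray, mode: str = "full") -> np.ndarray:
    """Vectorised 0 / 1-2 / >=3 status mapping for fully observed scores."""
    if mode not in FRAILTY_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    s = np.asarray(scores)
    return np.select([s == 0, s <= 2], ["nonfrail", "prefrail"], default="frail")


def assess(df: pd.DataFrame, mode: str = "full") -> pd.DataFrame:
    """Append component indicators, score and status columns to a cohort table.

    Component columns already present (e.g. simulated indicators) are kept;
    otherwise they are derived from the raw follow-up measures. Rows with any
    missing component get a missing score, and a status only when forced.
    """
    out = df.copy()
    if "exhaustion" not in out:
        out["exhaustion"] = [
            classify_exhaustion(a, b)
            for a, b in zip(out["cesd_effort_response"], out["cesd_getgoing_response"])
        ]
    if "low_activity" not in out:
        out["low_activity"] = [
            classify_low_activity(k, s) if not _is_missing(k) else None
            for k, s in zip(out["energy_kcal_week"], out["sex"])
        ]
    if "slow_walk" not in out:
        out["slow_walk"] = [
            classify_slow_walk(t, s, h)
            for t, s, h in zip(out["walk_time_8ft"], out["sex"], out["height"])
        ]
    if "weak_grip" not in out:
        out["weak_grip"] = [
            classify_weak_grip(g, s, b)
            for g, s, b in zip(out["grip_kg"], out["sex"], out["bmi"])
        ]
    if "weight_loss" not in out:
        out["weight_loss"] = [
            classify_weight_loss(p, f)
            for p, f in zip(out["weight_prev"], out["weight_followup"])
        ]

    comp = out[list(COMPONENTS)]
    if comp.notna().all().all():
        used = [c for c in COMPONENTS if mode == "full" or c != "low_activity"]
        scores = comp[used].astype(bool).sum(axis=1).to_numpy()
        out["frailty_score"] = scores
        out["frailty_status"] = status_from_scores(scores, mode=mode)
    else:
        assessments = [
            frailty_status(dict(zip(COMPONENTS, row)), mode=mode)
            for row in comp.itertuples(index=False)
        ]
        out["frailty_score"] = [a.score for a in assessments]
        out["frailty_status"] = [a.status for a in assessments]
    return out
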