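"""Participant data model: units, risk-factor categorisation, diabetes status, eligibility.

The canonical participant table is a pandas DataFrame with one row per
participant and the columns listed in :data:`COLUMN_DICTIONARY`. Canonical
units are mmol/L for glucose and mg/dL for lipids; files recorded in other
units are converted on read (see :func:`read_cohort`). Missing values are
``NaN`` and propagate through every categorisation — nothing is silently
defaulted, so imputation is an explicit pipeline stage.

All categorisation functions accept scalars or numpy/pandas vectors and
return the same shape; missing inputs yield missing outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L for glucose, fixed exactly so that the 7.0 mmol/L
#: diabetes cut-off coincides with 126 mg/dL and the impaired-fasting-glucose
#: band 100–<126 mg/dL is consistent with it.
GLUCOSE_MGDL_PER_MMOL = 18.0

#: Column dictionary for the participant table. Values are short
#: human-readable descriptions with units.
COLUMN_DICTIONARY = {
    "id": "participant identifier (opaque string)",
    "age": "age at baseline, years",
    "sex": "'male' or 'female'",
    "family_history_diabetes": "parent or sibling with diabetes (bool)",
    "height": "height, cm",
    "weight_baseline": "weight at baseline, kg",
    "weight_prev": "weight ~5 y before follow-up, kg",
    "weight_followup": "weight at follow-up, kg",
    "bmi": "body mass index, kg/m^2",
    "waist": "waist circumference, cm",
    "sbp": "systolic blood pressure, mm Hg",
    "dbp": "diastolic blood pressure, mm Hg",
    "antihypertensive_rx": "on antihypertensive medication (bool)",
    "corticosteroid_rx": "on corticosteroid medication (bool)",
    "history_high_glucose": "history of high blood glucose (bool)",
    "smoking": "'non', 'former' or 'current'",
    "physical_activity_4h": ">=4 h/wk physical activity (bool)",
    "daily_fruit_veg": "daily fruit and vegetable consumption (bool)",
    "fasting_glucose": "fasting glucose, mmol/L",
    "postload_2h_glucose": "2-h post-load glucose, mmol/L (optional)",
    "hdl": "HDL cholesterol, mg/dL",
    "triglycerides": "triglycerides, mg/dL",
    "physician_dx_diabetes": "physician-diagnosed diabetes (bool)",
    "diabetes_medication": "on diabetes medication (bool)",
    "prevalent_diabetes": "diabetes present at baseline (bool)",
    "incident_diabetes": "new diabetes during follow-up (bool)",
    # raw inputs for the frailty assessment at follow-up
    "cesd_effort_response": "CES-D 'everything was an effort' frequency category",
    "cesd_getgoing_response": "CES-D 'could not get going' frequency category",
    "energy_kcal_week": "leisure-time energy expenditure, kcal/wk",
    "walk_time_8ft": "time to walk 8 feet, seconds",
    "grip_kg": "maximum grip strength over trials, kg",
    # derived columns (see derive_features)
    "elevated_bp": "BP >=130/85 mm Hg or antihypertensive therapy (bool)",
    "ifg": "fasting glucose 100 to <126 mg/dL (bool)",
    "hdl_low": "HDL <40 mg/dL (men) / <50 (women) (bool)",
    "tg_high_100": "triglycerides >=100 mg/dL (bool)",
    "tg_high_150": "triglycerides >=150 mg/dL (bool)",
    "bmi_category": "'<25', '25-30' or '>=30'",
    "waist_category": "'small', 'intermediate' or 'high' (sex-specific)",
}

BMI_CATEGORIES = ("<25", "25-30", ">=30")
WAIST_CATEGORIES = ("small", "intermediate", "high")

# sex-specific waist bounds, cm: (lower, upper) of the intermediate band
_WAIST_BOUNDS = {"male": (94.0, 102.0), "female": (80.0, 88.0)}
# sex-specific low-HDL thresholds, mg/dL
_HDL_LOW = {"male": 40.0, "female": 50.0}


class UnitError(ValueError):
    """Raised for unknown unit declarations."""


def mgdl_to_mmol(value):
    """Convert glucose mg/dL -> mmol/L (exact factor 18.0)."""
    return np.asarray(value, dtype=float) / GLUCOSE_MGDL_PER_MMOL if np.ndim(value) else float(value) / GLUCOSE_MGDL_PER_MMOL


def mmol_to_mgdl(value):
    """Convert glucose mmol/L -> mg/dL (exact factor 18.0)."""
    return np.asarray(value, dtype=float) * GLUCOSE_MGDL_PER_MMOL if np.ndim(value) else float(value) * GLUCOSE_MGDL_PER_MMOL


def _as_float(x):
    return np.asarray(x, dtype=float)


def _scalar_in(*xs) -> bool:
    return all(np.ndim(x) == 0 for x in xs)


def _maybe_item(arr, scalar: bool):
    return arr.item() if scalar else arr


def _maybe_bool(arr, scalar: bool):
    """Return python bool/None for scalar calls, float 1/0/NaN arrays otherwise."""
    if not scalar:
        return arr
    v = np.asarray(arr).item()
    return None if np.isnan(v) else bool(v)


def categorize_bmi(bmi):
    """Categorise BMI into '<25', '25-30' (i.e. [25, 30)) or '>=30'.

    Missing BMI yields a missing category (None for scalars, NaN in arrays).
    """
    scalar = _scalar_in(bmi)
    b = _as_float(bmi)
    if np.any(b[~np.isnan(np.atleast_1d(b))] <= 0) if not scalar else (not np.isnan(b) and b <= 0):
        raise ValueError("bmi must be positive")
    out = np.select(
        [b < 25, (b >= 25) & (b < 30), b >= 30],
        BMI_CATEGORIES,
        default=None,
    )
    if scalar:
        return out.item()
    return out


def categorize_waist(waist, sex):
    """Categorise waist circumference into small / intermediate / high.

    Bounds are sex-specific: men <94 / [94, 102) / >=102 cm; women
    <80 / [80, 88) / >=88 cm. A missing sex is an error because the stratum
    is undefined; a missing waist propagates as missing.
    """
    scalar = _scalar_in(waist, sex)
    w = _as_float(waist)
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    bad = ~np.isin(sex_arr, ("male", "female"))
    if bad.any():
        raise ValueError(f"unknown sex value(s): {set(sex_arr[bad])}")
    lo = np.where(np.atleast_1d(sex_arr) == "male", 94.0, 80.0)
    hi = np.where(np.atleast_1d(sex_arr) == "male", 102.0, 88.0)
    w1 = np.atleast_1d(w)
    out = np.select(
        [w1 < lo, (w1 >= lo) & (w1 < hi), w1 >= hi],
        WAIST_CATEGORIES,
        default=None,
    )
    return _maybe_item(out, scalar) if scalar else out


def elevated_bp(sbp, dbp, antihypertensive_rx):
    """True iff SBP >=130, DBP >=85, or on antihypertensive therapy.

    With every input missing the result is missing; a single positive
    criterion suffices even when the others are unobserved.
    """
    scalar = _scalar_in(sbp, dbp, antihypertensive_rx)
    s, d = np.atleast_1d(_as_float(sbp)), np.atleast_1d(_as_float(dbp))
    rx = np.atleast_1d(_as_float(np.where(pd.isna(antihypertensive_rx), np.nan,
                                          np.asarray(antihypertensive_rx, dtype=object))).astype(float))
    pos = (s >= 130) | (d >= 85) | (rx == 1)
    all_missing = np.isnan(s) & np.isnan(d) & np.isnan(rx)
    out = np.where(all_missing, np.nan, pos.astype(float))
    return _maybe_bool(out, scalar)


def ifg_category(fasting_glucose_mmol):
    """Impaired fasting glucose: 100 mg/dL <= fasting glucose < 126 mg/dL.

    Input is in canonical mmol/L; the band is converted with the exact
    factor 18.0, so the open upper end coincides with the 7.0 mmol/L
    diabetes threshold. The converted value is compared at integer mg/dL
    precision (a value recorded as 5.55 mmol/L is clinically 100 mg/dL, not
    99.9), so band membership follows the mg/dL scale the band is printed on.
    """
    scalar = _scalar_in(fasting_glucose_mmol)
    fg = np.rint(np.atleast_1d(_as_float(fasting_glucose_mmol)) * GLUCOSE_MGDL_PER_MMOL)
    out = np.where(np.isnan(fg), np.nan, ((fg >= 100.0) & (fg < 126.0)).astype(float))
    return _maybe_bool(out, scalar)


def classify_diabetes(fasting_glucose, postload_2h_glucose, physician_dx, diabetes_medication):
    """Diabetes: fasting glucose >=7.0 mmol/L, 2-h post-load >=11.1 mmol/L,
    or physician diagnosis (medication counts only alongside a diagnosis).

    Monotone in both glucose values. All criteria missing -> missing.
    """
    scalar = _scalar_in(fasting_glucose, postload_2h_glucose, physician_dx, diabetes_medication)

    def _bool_as_float(x):
        x1 = np.atleast_1d(np.asarray(x, dtype=object))
        return np.where(pd.isna(x1), np.nan, x1 == True).astype(float)  # noqa: E712

    fg = np.atleast_1d(_as_float(fasting_glucose))
    pg = np.atleast_1d(_as_float(postload_2h_glucose))
    dx = _bool_as_float(physician_dx)
    med = _bool_as_float(diabetes_medication)
    pos = (fg >= 7.0) | (pg >= 11.1) | (dx == 1) | ((med == 1) & (dx == 1))
    all_missing = np.isnan(fg) & np.isnan(pg) & np.isnan(dx)
    out = np.where(all_missing, np.nan, pos.astype(float))
    return _maybe_bool(out, scalar)


ELIGIBILITY_MODES = ("main", "sens1_drop_incident", "sens2_keep_prevalent")


def eligibility_filter(records: pd.DataFrame, mode: str = "main") -> pd.DataFrame:
    """Apply the analytic-sample exclusions.

    main
        drop participants with prevalent (baseline) diabetes;
    sens1_drop_incident
        additionally drop incident diabetes cases;
    sens2_keep_prevalent
        retain prevalent cases.

    The number of dropped records is logged and recorded in
    ``result.attrs["n_dropped"]``.
    """
    if mode not in ELIGIBILITY_MODES:
        raise ValueError(f"unknown eligibility mode {mode!r}; expected one of {ELIGIBILITY_MODES}")
    keep = pd.Series(True, index=records.index)
    if mode in ("main", "sens1_drop_incident"):
        keep &= ~records["prevalent_diabetes"].fillna(False).astype(bool)
    if mode == "sens1_drop_incident":
        keep &= ~records["incident_diabetes"].fillna(False).astype(bool)
    out = records.loc[keep].copy()
    n_dropped = len(records) - len(out)
    logger.info("eligibility_filter mode=%s dropped=%d retained=%d", mode, n_dropped, len(out))
    out.attrs["n_dropped"] = n_dropped
    out.attrs["eligibility_mode"] = mode
    return out


def derive_features(df: pd.DataFrame) -> pd.DataFrame:
    """Append the derived risk-factor columns used by tables and score engines.

    Adds: bmi (from height/weight when absent), bmi_category, waist_category,
    elevated_bp, ifg, hdl_low, tg_high_100, tg_high_150.
    """
    out = df.copy()
    if "bmi" not in out or out["bmi"].isna().any():
        computed = out["weight_baseline"] / (out["height"] / 100.0) ** 2
        out["bmi"] = out.get("bmi", pd.Series(np.nan, index=out.index)).fillna(computed)
    out["bmi_category"] = categorize_bmi(out["bmi"].to_numpy())
    out["waist_category"] = categorize_waist(out["waist"].to_numpy(), out["sex"].to_numpy())
    out["elevated_bp"] = elevated_bp(
        out["sbp"].to_numpy(), out["dbp"].to_numpy(), out["antihypertensive_rx"].to_numpy()
    )
    out["ifg"] = ifg_category(out["fasting_glucose"].to_numpy())
    hdl_thr = out["sex"].map(_HDL_LOW).to_numpy(dtype=float)
    hdl = out["hdl"].to_numpy(dtype=float)
    out["hdl_low"] = np.where(np.isnan(hdl), np.nan, (hdl < hdl_thr).astype(float))
    tg = out["triglycerides"].to_numpy(dtype=float)
    out["tg_high_100"] = np.where(np.isnan(tg), np.nan, (tg >= 100.0).astype(float))
    out["tg_high_150"] = np.where(np.isnan(tg), np.nan, (tg >= 150.0).astype(float))
    return out


def read_cohort(path, units: dict | str | None = None) -> pd.DataFrame:
    """Read a participant table from delimited text (comma default).

    ``units`` may be a mapping (e.g. ``{"glucose_units": "mg/dL"}``) or the
    path of a YAML file declaring the units of the glucose columns; values
    are converted to the canonical mmol/L on read.
    """
    df = pd.read_csv(path)
    if isinstance(units, str):
        with open(units) as fh:
            units = yaml.safe_load(fh)
    units = units or {}
    glucose_units = units.get("glucose_units", "mmol/L")
    if glucose_units not in ("mmol/L", "mg/dL"):
        raise UnitError(f"unknown glucose units {glucose_units!r}")
    if glucose_units == "mg/dL":
        for col in ("fasting_glucose", "postload_2h_glucose"):
            if col in df:
                df[col] = df[col] / GLUCOSE_MGDL_PER_MMOL
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a participant table as CSV in canonical units."""
    df.to_csv(path, index=False)
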