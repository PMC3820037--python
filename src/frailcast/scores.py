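"""Config-driven diabetes risk-score engines and per-1-SD standardisation.

Two score families are supported:

``weighted_logistic``
    the score is the linear predictor of a published logistic model,
    intercept + sum of coefficient x transformed input. The linear predictor
    (not the probability) is used because per-SD odds ratios are invariant
    to monotone rescaling and the predictor avoids probability-scale
    compression near 0/1.
``categorical_points``
    the score is an integer sum of category points.

Definitions are declarative (:class:`ScoreDefinition`), loadable from YAML,
and validated against the cohort column dictionary. Three definitions ship
with the package — the Framingham Offspring simple clinical model, the
Cambridge risk score and the Finnish risk score (FINDRISC) — as editable,
versioned config data; see each file's provenance note.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import COLUMN_DICTIONARY, GLUCOSE_MGDL_PER_MMOL

FAMILIES = ("weighted_logistic", "categorical_points")
BUILTIN_DEFINITIONS = ("framingham_offspring", "cambridge", "findrisc")

#: canonical units of the convertible columns in the participant table
_CANONICAL_UNITS = {
    "fasting_glucose": "mmol/L",
    "postload_2h_glucose": "mmol/L",
    "hdl": "mg/dL",
    "triglycerides": "mg/dL",
}


class SchemaError(ValueError):
    """Definition/data-dictionary mismatch or malformed definition."""


@dataclass
class Term:
    """One additive term of a score definition.

    type:
      * ``linear`` — coefficient x value;
      * ``flag`` — value_true if the boolean field is true else value_false;
      * ``categorical`` — mapping from category label to value;
      * ``cut`` — half-open numeric bins ``[lo, hi, value]`` (lo <= x < hi);
      * ``cut_by_sex`` — per-sex bins, for sex-specific thresholds.
    """

    field: str
    type: str
    coefficient: float | None = None
    value_true: float = 0.0
    value_false: float = 0.0
    mapping: dict | None = None
    bins: list | None = None
    bins_by_sex: dict | None = None
    units: str | None = None


@dataclass
class ScoreDefinition:
    name: str
    family: str
    terms: list[Term]
    intercept: float = 0.0
    provenance: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        terms = [Term(**t) for t in d["terms"]]
        return cls(
            name=d["name"],
            family=d["family"],
            terms=terms,
            intercept=float(d.get("intercept", 0.0)),
            provenance=d.get("provenance", ""),
        )


@dataclass
class ScoreResult:
    """Raw and standardised scores over an analytic sample."""

    name: str
    raw: pd.Series
    z: pd.Series | None
    sd: float | None
    mean: float | None
    n_used: int
    missing_report: dict = field(default_factory=dict)


def load_definition(path) -> ScoreDefinition:
    """Load a score definition from a YAML file."""
    with open(path) as fh:
        return ScoreDefinition.from_dict(yaml.safe_load(fh))


def builtin_definition(name: str) -> ScoreDefinition:
    """Load one of the shipped definitions by name."""
    if name not in BUILTIN_DEFINITIONS:
        raise KeyError(f"unknown builtin definition {name!r}; available: {BUILTIN_DEFINITIONS}")
    ref = importlib.resources.files("frailcast.data") / f"{name}.yaml"
    return ScoreDefinition.from_dict(yaml.safe_load(ref.read_text()))


def builtin_definitions() -> dict[str, ScoreDefinition]:
    return {name: builtin_definition(name) for name in BUILTIN_DEFINITIONS}


def _convert_units(x, col: str, declared: str | None):
    """Coerce a canonical-unit column to the definition's declared units."""
    if declared is None or col not in _CANONICAL_UNITS or declared == _CANONICAL_UNITS[col]:
        return x
    if col in ("fasting_glucose", "postload_2h_glucose"):
        if declared == "mg/dL":
            return x * GLUCOSE_MGDL_PER_MMOL
        if declared == "mmol/L":
            return x / GLUCOSE_MGDL_PER_MMOL
    raise SchemaError(f"cannot convert column {col!r} to units {declared!r}")


def _eval_term(term: Term, df: pd.DataFrame) -> np.ndarray:
    x = df[term.field]
    if term.type == "linear":
        vals = _convert_units(x.astype(float), term.field, term.units)
        return term.coefficient * vals.to_numpy()
    if term.type == "flag":
        out = np.where(pd.isna(x), np.nan, np.where(x.astype("boolean").fillna(False), term.value_true, term.value_false))
        return np.where(pd.isna(x), np.nan, out).astype(float)
    if term.type == "categorical":
        mapped = x.map(term.mapping)
        bad = x.notna() & mapped.isna()
        if bad.any():
            raise SchemaError(
                f"term {term.field!r}: value(s) {sorted(set(x[bad]))} not in category mapping"
            )
        return mapped.to_numpy(dtype=float)
    if term.type in ("cut", "cut_by_sex"):
        vals = _convert_units(x.astype(float), term.field, term.units).to_numpy()
        out = np.full(len(df), np.nan)
        if term.type == "cut":
            sex_masks = [(None, np.ones(len(df), dtype=bool), term.bins)]
        else:
            sex = df["sex"].to_numpy()
            sex_masks = [(s, sex == s, bins) for s, bins in term.bins_by_sex.items()]
        for _, mask, bins in sex_masks:
            hit = np.zeros(len(df), dtype=bool)
            for lo, hi, value in bins:
                lo, hi = float(lo), float(hi)
                sel = mask & (vals >= lo) & (vals < hi)
                out[sel] = value
                hit |= sel
            uncovered = mask & ~np.isnan(vals) & ~hit
            if uncovered.any():
                raise SchemaError(
                    f"term {term.field!r}: value(s) {vals[uncovered][:5]} fall in no bin"
                )
        return out
    raise SchemaError(f"unknown term type {term.type!r}")


def _evaluate(df: pd.DataFrame, definition: ScoreDefinition) -> tuple[pd.Series, dict]:
    contributions = np.zeros(len(df))
    missing_by_field: dict[str, int] = {}
    for term in definition.terms:
        if term.field not in df.columns:
            raise SchemaError(f"definition {definition.name!r} needs column {term.field!r} absent from data")
        vals = _eval_term(term, df)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            missing_by_field[term.field] = n_missing
        contributions = contributions + vals
    raw = pd.Series(definition.intercept + contributions, index=df.index, name=definition.name)
    return raw, missing_by_field


def score_weighted_logistic(record, definition: ScoreDefinition):
    """Linear predictor of a weighted-logistic definition for one record.

    Returns NaN when any required input is missing.
    """
    if definition.family != "weighted_logistic":
        raise SchemaError(f"{definition.name!r} is not a weighted_logistic definition")
    df = pd.DataFrame([record]) if not isinstance(record, pd.DataFrame) else record
    raw, _ = _evaluate(df, definition)
    return float(raw.iloc[0]) if len(df) == 1 else raw


def score_categorical_points(record, definition: ScoreDefinition):
    """Integer point total of a categorical-points definition for one record."""
    if definition.family != "categorical_points":
        raise SchemaError(f"{definition.name!r} is not a categorical_points definition")
    df = pd.DataFrame([record]) if not isinstance(record, pd.DataFrame) else record
    raw, _ = _evaluate(df, definition)
    val = raw.iloc[0] if len(df) == 1 else raw
    if np.ndim(val) == 0:
        return int(val) if not np.isnan(val) else float("nan")
    return val


def standardize_scores(raw) -> tuple[pd.Series, float, float]:
    """Standardise raw scores over the analytic sample: z = (x - mean) / SD.

    SD is the sample standard deviation (n-1 denominator); both moments are
    returned for the audit log. Missing raws yield missing z. Raises on
    constant scores.
    """
    x = pd.Series(raw, dtype=float)
    obs = x.dropna()
    if obs.nunique() < 2:
        raise ValueError("scores are constant (or fewer than 2 observed); SD undefined")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    return (x - mean) / sd, sd, mean


def apply_score(df: pd.DataFrame, definition: ScoreDefinition, standardize: bool = True) -> ScoreResult:
    """Score every row of a cohort table with one definition.

    Rows missing any required input get a missing raw score and are reported
    per field in ``missing_report``; ``n_used`` counts fully scored rows.
    """
    raw, missing_report = _evaluate(df, definition)
    n_used = int(raw.notna().sum())
    z = sd = mean = None
    if standardize and n_used >= 2 and raw.dropna().nunique() >= 2:
        z, sd, mean = standardize_scores(raw)
    return ScoreResult(
        name=definition.name, raw=raw, z=z, sd=sd, mean=mean,
        n_used=n_used, missing_report=missing_report,
    )


def validate_definition(definition: ScoreDefinition, data_dictionary=None) -> list[str]:
    """Structural validation; returns a list of human-readable problems.

    Checks: known family; fields exist in the data dictionary; categorical
    bins are non-overlapping and (for points) exhaustive over the real line
    where declared with infinite end bins; integer points for the points
    family.
    """
    if data_dictionary is None:
        data_dictionary = COLUMN_DICTIONARY
    problems: list[str] = []
    if definition.family not in FAMILIES:
        problems.append(f"family: unknown family {definition.family!r}")
    for i, term in enumerate(definition.terms):
        where = f"terms[{i}] ({term.field})"
        if term.field not in data_dictionary:
            problems.append(f"{where}: unknown field {term.field!r}")
        if term.type == "linear" and term.coefficient is None:
            problems.append(f"{where}: linear term missing coefficient")
        if term.type == "categorical" and not term.mapping:
            problems.append(f"{where}: categorical term missing mapping")
        bin_sets = []
        if term.type == "cut":
            bin_sets = [term.bins or []]
        elif term.type == "cut_by_sex":
            bin_sets = list((term.bins_by_sex or {}).values())
        for bins in bin_sets:
            ordered = sorted((float(lo), float(hi)) for lo, hi, _ in bins)
            for (lo1, hi1), (lo2, _) in zip(ordered, ordered[1:]):
                if lo2 < hi1:
                    problems.append(f"{where}: overlapping bins at {lo2}")
                elif lo2 > hi1:
                    problems.append(f"{where}: gap between bins at {hi1}")
            if ordered and (not np.isneginf(ordered[0][0]) or not np.isposinf(ordered[-1][1])):
                problems.append(f"{where}: bins do not cover the real line")
        if definition.family == "categorical_points":
            values = []
            if term.type == "flag":
                values = [term.value_true, term.value_false]
            elif term.type == "categorical":
                values = list((term.mapping or {}).values())
            elif term.type in ("cut", "cut_by_sex"):
                for bins in bin_sets:
                    values += [v for _, _, v in bins]
            for v in values:
                if float(v) != int(v):
                    problems.append(f"{where}: non-integer points value {v}")
    return problems
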