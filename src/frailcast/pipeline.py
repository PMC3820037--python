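"""End-to-end orchestration: main analysis and sensitivity analyses 1-4.

``run_study`` executes the whole chain on a participant table (read from
disk or simulated): eligibility filtering -> Fried classification -> risk
scoring -> per-SD standardization -> associations (crude and fully
adjusted) -> pairwise score comparisons (OR differences with BCa CIs, AUCs
with paired comparisons) -> optional multiple-imputation branch. It emits
tidy CSV reports shaped like the study's Tables 1-3 plus a JSON run log
recording every seed, the standardisation SDs, and exclusion counts.

The pipeline is a pure function of (input, config, seed): identical inputs
give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as cohort_mod
from . import frailty as frailty_mod
from . import impute as impute_mod
from . import scores as scores_mod
from . import stats as stats_mod
from .simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

ANALYSIS_MODES = ("main", "sens1", "sens2", "sens3_no_pa", "sens4_mi")

_ELIGIBILITY_FOR_MODE = {
    "main": "main",
    "sens1": "sens1_drop_incident",
    "sens2": "sens2_keep_prevalent",
    "sens3_no_pa": "main",
    "sens4_mi": "main",
}

#: fully adjusted model covariates (the complete risk-factor list), with the
#: coding recorded here: continuous terms entered linearly, smoking as
#: indicator contrasts against never-smoking.
ADJUSTMENT_CONTINUOUS = ("age", "bmi", "waist", "sbp", "dbp", "fasting_glucose", "hdl", "triglycerides")
ADJUSTMENT_BINARY = (
    "family_history_diabetes", "antihypertensive_rx", "corticosteroid_rx",
    "physical_activity_4h", "daily_fruit_veg",
)

TABLE1_FACTORS = (
    ("Sex", "sex"),
    ("Parental or sibling history of diabetes", "family_history_diabetes"),
    ("Body mass index", "bmi_category"),
    ("Waist circumference", "waist_category"),
    ("Blood pressure >=130/85 mm Hg or hypertension therapy", "elevated_bp"),
    ("Corticosteroid treatment", "corticosteroid_rx"),
    ("Smoking status", "smoking"),
    ("Low physical activity <4 h/wk", "low_physical_activity"),
    ("Daily consumption of fruits and vegetables", "daily_fruit_veg"),
    ("Fasting glucose 100-126 mg/dL", "ifg"),
    ("Low HDL cholesterol", "hdl_low"),
    ("Triglycerides >=100 mg/dL", "tg_high_100"),
    ("Incident diabetes at follow-up", "incident_diabetes"),
)


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, independent mode flags."""

    input_path: str | None = None
    simulate: SyntheticConfig | None = None
    mode: str = "main"
    bootstrap_B: int = 2000
    seed: int = 0
    output_dir: str | None = None
    score_names: tuple = ("framingham_offspring", "cambridge", "findrisc")
    reference_score: str = "findrisc"

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path or simulate must be given")
        if self.mode not in ANALYSIS_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {ANALYSIS_MODES}")


def build_table1(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by dichotomized frailty status.

    Counts and column percentages for each categorical factor in the two
    strata (nonfrail vs prefrail/frail) plus the whole sample, with a
    chi-square heterogeneity p per factor; age is summarised as mean (SD)
    and compared with the rank-sum test. Empty strata yield missing
    percentages and are flagged in the ``note`` column.
    """
    if "frailty_status" not in df:
        raise ValueError("frailty status must be assigned before building Table 1")
    work = df.copy()
    work["low_physical_activity"] = ~work["physical_activity_4h"].astype(bool)
    pf = work["frailty_status"].isin(["prefrail", "frail"])
    groups = {"all": work, "nonfrail": work[~pf], "prefrail_frail": work[pf]}

    rows = []
    a = work["age"].astype(float)
    p_age = (
        sps.mannwhitneyu(groups["nonfrail"]["age"], groups["prefrail_frail"]["age"]).pvalue
        if len(groups["nonfrail"]) and len(groups["prefrail_frail"]) else np.nan
    )
    row = {"factor": "Age, y (mean (SD))", "category": "", "p_value": p_age, "note": ""}
    for gname, g in groups.items():
        row[f"n_{gname}"] = len(g)
        row[f"pct_{gname}"] = np.nan
        row[f"mean_{gname}"] = float(g["age"].mean()) if len(g) else np.nan
        row[f"sd_{gname}"] = float(g["age"].std(ddof=1)) if len(g) > 1 else np.nan
    rows.append(row)

    for label, col in TABLE1_FACTORS:
        if col not in work:
            continue
        series = work[col]
        if series.dropna().dtype.kind in "bf" or set(series.dropna().unique()) <= {0, 1, True, False}:
            cats = [False, True]
            fmt = {False: "No", True: "Yes"}
        else:
            cats = list(pd.unique(series.dropna()))
            fmt = {c: str(c) for c in cats}
        tab = np.array([
            [(groups[g][col].astype(object) == c).sum() for g in ("nonfrail", "prefrail_frail")]
            for c in cats
        ], dtype=float)
        note = ""
        if tab.sum(axis=0).min() == 0:
            p_val = np.nan
            note = "empty stratum"
        else:
            keep = tab.sum(axis=1) > 0
            p_val = sps.chi2_contingency(tab[keep], correction=False).pvalue if keep.sum() > 1 else np.nan
        for i, c in enumerate(cats):
            r = {"factor": label, "category": fmt[c],
                 "p_value": p_val if i == 0 else np.nan, "note": note}
            for gname, g in groups.items():
                n_cat = int((g[col].astype(object) == c).sum())
                denom = int(g[col].notna().sum())
                r[f"n_{gname}"] = n_cat
                r[f"pct_{gname}"] = 100.0 * n_cat / denom if denom else np.nan
            rows.append(r)
    return pd.DataFrame(rows)


def _adjustment_matrix(df: pd.DataFrame) -> pd.DataFrame:
    X = {}
    for c in ADJUSTMENT_CONTINUOUS:
        X[c] = df[c].astype(float)
    X["female"] = (df["sex"] == "female").astype(float)
    for c in ADJUSTMENT_BINARY:
        X[c] = df[c].astype(bool).astype(float)
    X["smoking_former"] = (df["smoking"] == "former").astype(float)
    X["smoking_current"] = (df["smoking"] == "current").astype(float)
    return pd.DataFrame(X).reset_index(drop=True)


def _score_table(df: pd.DataFrame, names) -> tuple[pd.DataFrame, dict]:
    scored = df.reset_index(drop=True).copy()
    sds = {}
    for name in names:
        res = scores_mod.apply_score(scored, scores_mod.builtin_definition(name))
        scored[f"{name}_raw"] = res.raw
        scored[f"{name}_z"] = res.z
        sds[name] = {"sd": res.sd, "mean": res.mean, "n_used": res.n_used,
                     "missing": res.missing_report}
    return scored, sds


def _mi_branch(df: pd.DataFrame, config: RunConfig, outcome: np.ndarray) -> pd.DataFrame:
    """Sensitivity analysis 4: impute score inputs, pool per-SD log-ORs."""
    needed = set()
    for name in config.score_names:
        needed |= {t.field for t in scores_mod.builtin_definition(name).terms}
    needed &= set(df.columns)
    cols = sorted(needed)
    sub = df[cols].reset_index(drop=True).copy()
    models = {}
    for c in cols:
        if not sub[c].isna().any():
            continue
        if sub[c].dtype.kind == "f":
            models[c] = "linear_pmm"
        elif sub[c].dtype.kind == "b" or set(sub[c].dropna().unique()) <= {0, 1, True, False}:
            models[c] = "logistic"
        else:
            models[c] = "multinomial"
    if not models:
        return pd.DataFrame()
    spec = impute_mod.ImputationSpec(models=models, m=20, iterations=5,
                                     seed=config.seed + 101)
    base = df.reset_index(drop=True).copy()
    completed = mice_completed = impute_mod.mice_impute(sub, spec)
    rows = []
    for name in config.score_names:
        ests, variances = [], []
        for comp in mice_completed:
            filled = base.copy()
            filled[cols] = comp[cols]
            filled = cohort_mod.derive_features(filled)
            res = scores_mod.apply_score(filled, scores_mod.builtin_definition(name))
            fit = stats_mod.fit_logistic(res.z.to_frame("z"), outcome)
            ests.append(float(fit.params["z"]))
            variances.append(float(fit.cov.loc["z", "z"]))
        pooled = impute_mod.rubin_pool(ests, variances, df_complete=len(df) - 2)
        rows.append({
            "score": name, "odds_ratio": np.exp(pooled.estimate),
            "ci_low": np.exp(pooled.ci_low), "ci_high": np.exp(pooled.ci_high),
            "m": pooled.m, "method": "mice+rubin",
        })
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns a report bundle.

    The bundle maps report names (table1, table2_or, table2_diff,
    table3_auc, sex_interaction, run_log, and optionally table_mi) to
    DataFrames / dicts, and is also written as CSV + JSON under
    ``config.output_dir`` when set.
    """
    rng_seed = config.seed
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed is None:
            from dataclasses import replace
            sim = replace(sim, seed=rng_seed)
        df = generate_cohort(sim)
    else:
        df = cohort_mod.read_cohort(config.input_path)

    df = cohort_mod.derive_features(df)
    if "incident_diabetes" not in df:
        inc = cohort_mod.classify_diabetes(
            df["fasting_glucose"].to_numpy(), df["postload_2h_glucose"].to_numpy(),
            df["physician_dx_diabetes"].to_numpy(), df["diabetes_medication"].to_numpy(),
        )
        df["incident_diabetes"] = pd.Series(inc).astype("boolean").to_numpy()

    df = cohort_mod.eligibility_filter(df, _ELIGIBILITY_FOR_MODE[config.mode])
    n_dropped = df.attrs["n_dropped"]

    frailty_mode = "no_physical_activity" if config.mode == "sens3_no_pa" else "full"
    df = frailty_mod.assess(df, mode=frailty_mode)
    n_before = len(df)
    df = df[df["frailty_status"].notna()].reset_index(drop=True)
    n_missing_frailty = n_before - len(df)

    scored, sds = _score_table(df, config.score_names)
    y_frail = scored["frailty_status"].isin(["prefrail", "frail"]).to_numpy(dtype=float)
    y_diab = scored["incident_diabetes"].fillna(False).to_numpy(dtype=float)

    # the diabetes reference panel is dropped when the eligibility mode leaves
    # a single outcome class (sensitivity analysis 1 removes all incident cases)
    outcomes = [("frail_prefrail", y_frail)]
    if 0 < y_diab.sum() < len(y_diab):
        outcomes.append(("incident_diabetes", y_diab))

    adjust = _adjustment_matrix(scored)
    adjust_complete = adjust.notna().all(axis=1).to_numpy()
    or_rows = []
    interaction_rows = []
    for name in config.score_names:
        z_all = scored[f"{name}_z"].to_numpy()
        obs = ~np.isnan(z_all)   # complete-case analyses; MI is sensitivity 4
        for outcome_name, y in outcomes:
            crude = stats_mod.standardized_or(z_all[obs], y[obs])
            or_rows.append({"score": name, "outcome": outcome_name, "model": "crude",
                            "odds_ratio": crude.odds_ratio, "ci_low": crude.ci_low,
                            "ci_high": crude.ci_high, "n": crude.n})
            if outcome_name == "frail_prefrail":
                m = obs & adjust_complete
                adj = stats_mod.standardized_or(z_all[m], y[m], covariates=adjust.loc[m])
                or_rows.append({"score": name, "outcome": outcome_name, "model": "adjusted",
                                "odds_ratio": adj.odds_ratio, "ci_low": adj.ci_low,
                                "ci_high": adj.ci_high, "n": adj.n})
        interaction_rows.append({
            "score": name,
            "p_sex_interaction": stats_mod.sex_interaction_test(
                z_all[obs], scored["sex"].to_numpy()[obs], y_frail[obs]),
        })
    table2_or = pd.DataFrame(or_rows)

    diff_rows = []
    names = list(config.score_names)
    paired = ~np.isnan(
        np.column_stack([scored[f"{n}_raw"].to_numpy() for n in names])
    ).any(axis=1)
    for outcome_name, y in outcomes:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = stats_mod.or_difference(
                    scored[f"{a}_raw"].to_numpy()[paired],
                    scored[f"{b}_raw"].to_numpy()[paired], y[paired],
                    B=config.bootstrap_B, seed=config.seed + 7,
                )
                diff_rows.append({"outcome": outcome_name, "score_a": a, "score_b": b,
                                  "delta_or": d.delta, "ci_low": d.ci_low, "ci_high": d.ci_high,
                                  "or_a": d.or_a, "or_b": d.or_b, "B": d.B,
                                  "method": "bca_bootstrap"})
    table2_diff = pd.DataFrame(diff_rows)

    auc_rows = []
    ref = config.reference_score
    for outcome_name, y in outcomes:
        for name in names:
            a = stats_mod.auc(scored[f"{name}_raw"].to_numpy()[paired], y[paired])
            row = {"outcome": outcome_name, "score": name, "auc": a}
            if name != ref:
                cmp_ = stats_mod.auc_difference(
                    scored[f"{name}_raw"].to_numpy()[paired],
                    scored[f"{ref}_raw"].to_numpy()[paired], y[paired],
                    method="delong",
                )
                row.update({"delta_vs_ref": cmp_.delta, "delta_ci_low": cmp_.ci_low,
                            "delta_ci_high": cmp_.ci_high, "reference": ref})
            auc_rows.append(row)
    table3_auc = pd.DataFrame(auc_rows)

    table1 = build_table1(scored)

    run_log = {
        "mode": config.mode,
        "seed": config.seed,
        "bootstrap_B": config.bootstrap_B,
        "bootstrap_seed": config.seed + 7,
        "n_input": int(n_before + n_dropped),
        "n_dropped_eligibility": int(n_dropped),
        "n_dropped_missing_frailty": int(n_missing_frailty),
        "n_analytic": int(len(scored)),
        "standardization": {
            k: {kk: vv for kk, vv in v.items() if kk != "missing"} for k, v in sds.items()
        },
    }

    bundle = {
        "table1": table1,
        "table2_or": table2_or,
        "table2_diff": table2_diff,
        "table3_auc": table3_auc,
        "sex_interaction": pd.DataFrame(interaction_rows),
        "run_log": run_log,
    }
    if config.mode == "sens4_mi":
        bundle["table_mi"] = _mi_branch(df, config, y_frail)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2)
        _write_readable_report(bundle, outdir / "report.txt")
    return bundle


def _write_readable_report(bundle: dict, path: Path) -> None:
    """Presentation layer: ORs to 2 dp, percentages to 1 dp."""
    lines = ["Risk scores and future frailty - run report", "=" * 44, ""]
    log = bundle["run_log"]
    lines.append(f"mode={log['mode']} seed={log['seed']} analytic n={log['n_analytic']} "
                 f"(dropped: {log['n_dropped_eligibility']} ineligible, "
                 f"{log['n_dropped_missing_frailty']} missing frailty)")
    lines.append("")
    lines.append("Standardized ORs (per 1 SD of score):")
    for _, r in bundle["table2_or"].iterrows():
        lines.append(f"  {r['score']:>22s} {r['outcome']:>17s} {r['model']:>8s} "
                     f"OR={r['odds_ratio']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
    lines.append("")
    lines.append("OR differences (BCa bootstrap):")
    for _, r in bundle["table2_diff"].iterrows():
        lines.append(f"  {r['outcome']:>17s} {r['score_b']} - {r['score_a']}: "
                     f"d={r['delta_or']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})")
    lines.append("")
    lines.append("AUCs:")
    for _, r in bundle["table3_auc"].iterrows():
        lines.append(f"  {r['outcome']:>17s} {r['score']:>22s} AUC={r['auc']:.3f}")
    path.write_text("\n".join(lines) + "\n")
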