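"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator stands in for a middle-aged occupational cohort whose raw data
are not redistributable. It emulates:

* the printed marginal distributions of every baseline risk factor
  (category draws from a Gaussian copula with configurable exchangeable
  latent correlation, then a continuous value drawn within the category's
  numeric band, so derived categories reproduce the marginals exactly);
* Fried components as five exchangeable binaries sharing one latent factor,
  with (p, rho) solved so the frail / prefrail / nonfrail split matches the
  study's printed prevalences; an optional loading couples the shared
  factor to a standardized risk score so component-derived status and the
  scores are positively associated in end-to-end runs;
* logistic outcome models (frail/prefrail flag, incident diabetes flag)
  with configurable per-1-SD effects and prevalence-calibrated intercepts,
  for parameter-recovery tests;
* injectable MCAR/MAR missingness.

Everything is driven by one numpy Generator, so a fixed seed reproduces the
cohort bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr, ndtri
from scipy.stats import truncnorm

from . import frailty as frailty_mod

# Marginal category probabilities of the baseline factors, defaulting to the
# study's printed "All"-column counts out of n=2707.
TABLE1_ALL_COUNTS = {
    "n": 2707,
    "female": 755,
    "family_history_diabetes": 288,
    "bmi_category": {"<25": 1199, "25-30": 1145, ">=30": 363},
    "waist_category": {"small": 1414, "intermediate": 719, "high": 574},
    "elevated_bp": 1078,
    "corticosteroid_rx": 99,
    "smoking": {"non": 1514, "former": 967, "current": 226},
    "low_physical_activity": 1739,
    "daily_fruit_veg": 1998,
    "ifg": 415,
    "hdl_low": 421,
    "tg_high_100": 598,
    "incident_diabetes": 241,
    "nonfrail": 1616,
    "prefrail_frail": 1091,
}


def _p(key):
    v = TABLE1_ALL_COUNTS[key]
    n = TABLE1_ALL_COUNTS["n"]
    if isinstance(v, dict):
        return {k: c / n for k, c in v.items()}
    return v / n


@dataclass
class OutcomeModel:
    """Logistic outcome layer: Bernoulli(logit^-1(alpha + beta z))."""

    driver_score: str
    per_sd_or: float
    target_prevalence: float


@dataclass
class SyntheticConfig:
    n: int = 2707
    seed: int | None = None
    age_mean: float = 55.0
    age_sd: float = 5.9
    age_range: tuple = (45.0, 69.0)
    p_female: float = _p("female")
    marginals: dict = field(default_factory=lambda: {
        "family_history_diabetes": _p("family_history_diabetes"),
        "bmi_category": _p("bmi_category"),
        "waist_category": _p("waist_category"),
        "elevated_bp": _p("elevated_bp"),
        "corticosteroid_rx": _p("corticosteroid_rx"),
        "smoking": _p("smoking"),
        "low_physical_activity": _p("low_physical_activity"),
        "daily_fruit_veg": _p("daily_fruit_veg"),
        "ifg": _p("ifg"),
        "hdl_low": _p("hdl_low"),
        "tg_high_100": _p("tg_high_100"),
        "history_high_glucose": 0.15,   # not printed; chosen near the IFG rate
    })
    #: exchangeable latent correlation among the risk-factor copula latents
    rho_covariates: float = 0.15
    #: Fried component marginal probability and latent correlation; None means
    #: "calibrate to the study prevalences on first use"
    fried_p: float | None = None
    fried_rho: float | None = None
    #: loading of the shared Fried factor on the standardized driver composite
    fried_score_loading: float = 0.3
    #: weights of the standardized scores inside the driver composite,
    #: solved from the scores' correlation structure so each score's marginal
    #: loading is proportional to its printed frailty log-OR
    #: (1.05 : 1.18 : 1.27); the small negative Framingham weight is what
    #: that ordering requires given the weak inter-score correlations
    fried_driver_weights: dict = field(default_factory=lambda: {
        "findrisc": 0.882, "cambridge": 0.401, "framingham_offspring": -0.113})
    frailty_targets: tuple = (0.597, 0.028)   # (nonfrail, frail)
    prevalent_diabetes_rate: float = 450 / 3157
    frailty_outcome: OutcomeModel = field(default_factory=lambda: OutcomeModel(
        driver_score="findrisc", per_sd_or=1.27, target_prevalence=_p("prefrail_frail")))
    diabetes_outcome: OutcomeModel = field(default_factory=lambda: OutcomeModel(
        driver_score="framingham_offspring", per_sd_or=1.72,
        target_prevalence=_p("incident_diabetes")))

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must lie in [0, 1]")
        for name, m in self.marginals.items():
            probs = list(m.values()) if isinstance(m, dict) else [m, 1 - m]
            if any(not 0 <= q <= 1 for q in probs):
                raise ValueError(f"marginal {name!r} has probabilities outside [0, 1]")
            if isinstance(m, dict) and abs(sum(probs) - 1) > 1e-6:
                raise ValueError(f"marginal {name!r} does not sum to 1")
        if not 0 <= self.rho_covariates < 1:
            raise ValueError("rho_covariates must lie in [0, 1)")


# ---------------------------------------------------------------------------
# covariates

_CONTINUOUS_BANDS = {
    # numeric band (lo, hi) realised uniformly within each category
    "bmi_category": {"<25": (19.0, 25.0), "25-30": (25.0, 30.0), ">=30": (30.0, 42.0)},
    "waist_category": {
        "male": {"small": (75.0, 94.0), "intermediate": (94.0, 102.0), "high": (102.0, 125.0)},
        "female": {"small": (62.0, 80.0), "intermediate": (80.0, 88.0), "high": (88.0, 115.0)},
    },
    # fasting glucose bands in mg/dL (converted to mmol/L on output); kept
    # clear of the integer-rounded band edges used by the IFG classifier
    "fasting_glucose": {"normal": (72.0, 99.4), "ifg": (100.0, 125.4)},
    "triglycerides": {"low": (45.0, 100.0), "high": (100.0, 300.0)},
}
_HDL_THRESHOLD = {"male": 40.0, "female": 50.0}


def _copula_categories(rng, n, marginals: dict, rho: float) -> dict:
    """Draw correlated categoricals by thresholding an exchangeable Gaussian copula."""
    if not 0 <= rho < 1:
        raise ValueError("infeasible exchangeable correlation for the copula")
    names = list(marginals)
    shared = rng.standard_normal(n)
    out = {}
    for name in names:
        latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
        u = ndtr(latent)
        m = marginals[name]
        if isinstance(m, dict):
            labels = list(m)
            cum = np.cumsum([m[k] for k in labels])
            out[name] = np.asarray(labels, dtype=object)[np.searchsorted(cum, u, side="right").clip(max=len(labels) - 1)]
        else:
            out[name] = u < m
    return out


def generate_covariates(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Generate the baseline participant table (no frailty, no outcomes)."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < config.p_female, "female", "male").astype(object)
    cats = _copula_categories(rng, n, config.marginals, config.rho_covariates)

    height = np.where(sex == "male", rng.normal(175.0, 6.5, n), rng.normal(162.0, 6.0, n))

    bands = _CONTINUOUS_BANDS
    bmi = np.empty(n)
    for cat, (blo, bhi) in bands["bmi_category"].items():
        m = cats["bmi_category"] == cat
        bmi[m] = rng.uniform(blo, bhi, m.sum())
    waist = np.empty(n)
    for s in ("male", "female"):
        for cat, (wlo, whi) in bands["waist_category"][s].items():
            m = (sex == s) & (cats["waist_category"] == cat)
            waist[m] = rng.uniform(wlo, whi, m.sum())

    elevated = cats["elevated_bp"]
    rx = elevated & (rng.random(n) < 0.45)
    sbp = np.where(elevated, rng.uniform(130.0, 170.0, n), rng.uniform(100.0, 129.5, n))
    dbp = np.where(elevated, rng.uniform(70.0, 100.0, n), rng.uniform(60.0, 84.5, n))

    fg_mgdl = np.where(
        cats["ifg"],
        rng.uniform(*bands["fasting_glucose"]["ifg"], n),
        rng.uniform(*bands["fasting_glucose"]["normal"], n),
    )
    prevalent = rng.random(n) < config.prevalent_diabetes_rate
    fg_mgdl = np.where(prevalent, rng.uniform(126.0, 190.0, n), fg_mgdl)

    hdl_thr = np.where(sex == "male", _HDL_THRESHOLD["male"], _HDL_THRESHOLD["female"])
    hdl = np.where(
        cats["hdl_low"],
        hdl_thr - rng.uniform(2.0, 15.0, n),
        hdl_thr + rng.uniform(0.0, 40.0, n),
    )
    tg = np.where(
        cats["tg_high_100"],
        rng.uniform(*bands["triglycerides"]["high"], n),
        rng.uniform(*bands["triglycerides"]["low"], n),
    )

    weight = bmi * (height / 100.0) ** 2
    weight_prev = weight * (1 + rng.normal(0.0, 0.03, n))

    df = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "family_history_diabetes": cats["family_history_diabetes"],
        "height": height,
        "weight_baseline": weight,
        "weight_prev": weight_prev,
        "bmi": bmi,
        "waist": waist,
        "sbp": sbp,
        "dbp": dbp,
        "antihypertensive_rx": rx,
        "corticosteroid_rx": cats["corticosteroid_rx"],
        "history_high_glucose": cats["history_high_glucose"],
        "smoking": cats["smoking"],
        "physical_activity_4h": ~cats["low_physical_activity"],
        "daily_fruit_veg": cats["daily_fruit_veg"],
        "fasting_glucose": fg_mgdl / 18.0,
        "postload_2h_glucose": np.where(prevalent, rng.uniform(11.1, 16.0, n), rng.uniform(4.0, 9.0, n)),
        "hdl": hdl,
        "triglycerides": tg,
        "physician_dx_diabetes": prevalent,
        "diabetes_medication": prevalent & (rng.random(n) < 0.5),
        "prevalent_diabetes": prevalent,
    })
    return df


# ---------------------------------------------------------------------------
# Fried components and calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)
_GH_Z = np.sqrt(2.0) * _GH_NODES
_GH_W = _GH_WEIGHTS / np.sqrt(np.pi)
_BINOM5 = np.array([1, 5, 10, 10, 5, 1], dtype=float)


def score_distribution(p: float, rho: float) -> np.ndarray:
    """P(component score = k), k=0..5, under the exchangeable latent model.

    Components are 1{sqrt(rho) G + sqrt(1-rho) e_j < ndtri(p)} with shared
    G; the score is conditionally binomial given G and the marginal is a
    Gauss–Hermite quadrature over G.
    """
    tau = ndtri(p)
    if rho == 0:
        q = np.full(1, p)
        w = np.ones(1)
    else:
        q = ndtr((tau - np.sqrt(rho) * _GH_Z) / np.sqrt(1 - rho))
        w = _GH_W
    k = np.arange(6)
    pk = _BINOM5[None, :] * q[:, None] ** k * (1 - q[:, None]) ** (5 - k)
    return w @ pk


def calibrate_frailty(target_nonfrail: float = 0.597, target_frail: float = 0.028
                      ) -> tuple[float, float]:
    """Solve (p, rho) so P(score=0) and P(score>=3) match the targets.

    For each candidate rho, p is solved from the nonfrail moment (monotone),
    then rho from the frail moment. Residuals are below 1e-3; raises when no
    solution exists in (0,1) x [0,1) — e.g. under independence the frail
    moment is unreachable at the study's nonfrail level.
    """
    if not (0 < target_nonfrail < 1 and 0 < target_frail < 1):
        raise ValueError("targets must lie in (0, 1)")
    if target_nonfrail + target_frail >= 1:
        raise ValueError("incompatible targets: nonfrail + frail must be < 1")

    def p_for(rho):
        return optimize.brentq(
            lambda p: score_distribution(p, rho)[0] - target_nonfrail, 1e-6, 1 - 1e-6,
            xtol=1e-12,
        )

    def frail_resid(rho):
        p = p_for(rho)
        return score_distribution(p, rho)[3:].sum() - target_frail

    lo, hi = 0.0, 0.97
    f_lo, f_hi = frail_resid(lo), frail_resid(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            "no exchangeable-model solution: frail target unreachable for any rho in [0, 0.97]"
        )
    rho = optimize.brentq(frail_resid, lo, hi, xtol=1e-10)
    p = p_for(rho)
    dist = score_distribution(p, rho)
    assert abs(dist[0] - target_nonfrail) < 1e-3 and abs(dist[3:].sum() - target_frail) < 1e-3
    return float(p), float(rho)


def generate_fried_components(n_or_covariates, p: float, rho: float, rng=None,
                              driver_z: np.ndarray | None = None,
                              score_loading: float = 0.0) -> pd.DataFrame:
    """Five exchangeable binary Fried components from a shared latent factor.

    With ``driver_z`` (a standardized score) and a nonzero ``score_loading``
    lambda, the shared factor is lambda * z + sqrt(1 - lambda^2) * noise, so
    higher-risk participants accumulate more components while the marginal
    structure is (approximately) preserved.
    """
    if not (0 < p < 1 and 0 <= rho < 1):
        raise ValueError("need p in (0,1) and rho in [0,1); run calibrate_frailty first")
    rng = np.random.default_rng() if rng is None else rng
    n = n_or_covariates if np.ndim(n_or_covariates) == 0 else len(n_or_covariates)
    if driver_z is not None and score_loading:
        # components fire when the latent falls BELOW the threshold, so the
        # shared factor loads negatively on the score: higher risk -> more
        # components
        lam = float(score_loading)
        shared = -lam * np.asarray(driver_z, dtype=float) + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
    else:
        shared = rng.standard_normal(n)
    tau = ndtri(p)
    eps = rng.standard_normal((n, 5))
    latent = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * eps
    comp = latent < tau
    return pd.DataFrame(comp, columns=list(frailty_mod.COMPONENTS))


def realize_fried_raw(df: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Back-fill raw follow-up measures consistent with the component indicators.

    Each raw measure is drawn from the positive or negative side of its
    published threshold, so re-classifying the raw measures recovers the
    indicators exactly. Used so end-to-end runs exercise the real
    classification rules.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = df.copy()
    n = len(out)
    pos = out["exhaustion"].to_numpy(dtype=bool)
    out["cesd_effort_response"] = np.where(
        pos,
        np.where(rng.random(n) < 0.5, "occasionally_or_moderate", "most_or_all"),
        np.where(rng.random(n) < 0.5, "rarely_or_none", "some_or_little"),
    ).astype(object)
    out["cesd_getgoing_response"] = np.where(
        rng.random(n) < 0.3, out["cesd_effort_response"], "rarely_or_none"
    ).astype(object)

    cut = np.where(out["sex"].to_numpy() == "male",
                   frailty_mod.KCAL_CUTOFF["male"], frailty_mod.KCAL_CUTOFF["female"])
    low = out["low_activity"].to_numpy(dtype=bool)
    out["energy_kcal_week"] = np.where(
        low, cut * rng.uniform(0.0, 0.999, n), cut + rng.uniform(1.0, 2500.0, n)
    )

    short = np.where(
        out["sex"].to_numpy() == "male",
        out["height"].to_numpy() <= frailty_mod.WALK_HEIGHT_CUTOFF_CM["male"],
        out["height"].to_numpy() <= frailty_mod.WALK_HEIGHT_CUTOFF_CM["female"],
    )
    thr = np.where(short, frailty_mod.WALK_SLOW_SHORT_S, frailty_mod.WALK_SLOW_TALL_S)
    slow = out["slow_walk"].to_numpy(dtype=bool)
    out["walk_time_8ft"] = np.where(
        slow, thr + rng.uniform(0.0, 2.0, n), rng.uniform(1.2, 1.0 * thr - 1e-3, n)
    )

    grip_cut = np.empty(n)
    sexes = out["sex"].to_numpy()
    bmis = out["bmi"].to_numpy(dtype=float)
    for s, strata in frailty_mod.GRIP_STRATA.items():
        for blo, bhi, c in strata:
            m = (sexes == s) & (bmis > blo) & (bmis <= bhi)
            grip_cut[m] = c
    weak = out["weak_grip"].to_numpy(dtype=bool)
    out["grip_kg"] = np.where(
        weak,
        np.maximum(grip_cut - rng.uniform(0.0, 12.0, n), 1.0),
        grip_cut + rng.uniform(0.5, 25.0, n),
    )

    lossers = out["weight_loss"].to_numpy(dtype=bool)
    frac = np.where(lossers, rng.uniform(0.101, 0.25, n), rng.uniform(-0.05, 0.0995, n))
    out["weight_followup"] = out["weight_prev"].to_numpy() * (1 - frac)
    return out


# ---------------------------------------------------------------------------
# outcomes and missingness


def calibrate_intercept(z: np.ndarray, beta: float, target_prevalence: float) -> float:
    """Solve alpha so mean(expit(alpha + beta z)) equals the target prevalence."""
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    z = np.asarray(z, dtype=float)
    return float(optimize.brentq(
        lambda a: expit(a + beta * z).mean() - target_prevalence, -30.0, 30.0, xtol=1e-12
    ))


def generate_outcomes(z, per_sd_or: float, target_prevalence: float, rng=None,
                      alpha: float | None = None) -> np.ndarray:
    """Bernoulli outcome flags from logit^-1(alpha + beta z), beta = log(OR).

    ``alpha`` defaults to the prevalence-calibrated intercept for the given
    score vector.
    """
    rng = np.random.default_rng() if rng is None else rng
    z = np.asarray(z, dtype=float)
    beta = float(np.log(per_sd_or))
    if alpha is None:
        alpha = calibrate_intercept(z, beta, target_prevalence)
    p = expit(alpha + beta * z)
    return rng.random(len(z)) < p


def inject_missingness(df: pd.DataFrame, mechanism: str = "MCAR", rates: dict | None = None,
                       seed=None, mar_predictors: list[str] | None = None) -> pd.DataFrame:
    """Blank cells at the given per-column rates.

    MCAR deletes iid; MAR makes the deletion probability logistic in fully
    observed covariates (``mar_predictors``, standardized, unit slopes) with
    an intercept calibrated to the requested marginal rate. The mask is
    reproducible from ``seed``.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rates = rates or {}
    for col, rate in rates.items():
        if not 0 <= rate < 1:
            raise ValueError(f"rate for {col!r} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = df.copy()
    n = len(out)
    if mechanism == "MAR":
        if not mar_predictors:
            raise ValueError("MAR requires mar_predictors")
        P = out[mar_predictors].to_numpy(dtype=float)
        P = (P - P.mean(axis=0)) / P.std(axis=0, ddof=0)
        eta = P.sum(axis=1)
    for col, rate in rates.items():
        if rate == 0:
            continue
        if mechanism == "MCAR":
            mask = rng.random(n) < rate
        else:
            alpha = calibrate_intercept(eta, 1.0, rate)
            mask = rng.random(n) < expit(alpha + eta)
        out.loc[mask, col] = np.nan if out[col].dtype.kind in "fiu" else None
    return out


# ---------------------------------------------------------------------------
# whole-cohort orchestration

_calibration_cache: dict[tuple, tuple] = {}


def default_fried_params(config: SyntheticConfig) -> tuple[float, float]:
    """(p, rho), calibrating to the configured status targets when unset."""
    if config.fried_p is not None and config.fried_rho is not None:
        return config.fried_p, config.fried_rho
    key = config.frailty_targets
    if key not in _calibration_cache:
        _calibration_cache[key] = calibrate_frailty(*key)
    return _calibration_cache[key]


def generate_cohort(config: SyntheticConfig | None = None, rng=None) -> pd.DataFrame:
    """Full synthetic cohort: covariates, scores' driver outcomes, Fried raws.

    Produces the baseline table plus component indicators, raw follow-up
    frailty measures consistent with them, and an incident-diabetes flag
    from the configured outcome model. Frailty status itself is left to the
    classifier.
    """
    from .scores import apply_score, builtin_definition
    from .cohort import derive_features

    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    df = generate_covariates(config, rng)
    df = derive_features(df)

    p, rho = default_fried_params(config)
    composite = np.zeros(len(df))
    for name, w in config.fried_driver_weights.items():
        composite = composite + w * apply_score(df, builtin_definition(name)).z.to_numpy()
    composite = (composite - composite.mean()) / composite.std(ddof=1)
    comp = generate_fried_components(
        len(df), p, rho, rng,
        driver_z=composite,
        score_loading=config.fried_score_loading,
    )
    df = pd.concat([df, comp], axis=1)
    df = realize_fried_raw(df, rng)

    dm = config.diabetes_outcome
    zd = apply_score(df, builtin_definition(dm.driver_score)).z.to_numpy()
    incident = generate_outcomes(zd, dm.per_sd_or, dm.target_prevalence, rng)
    df["incident_diabetes"] = incident & ~df["prevalent_diabetes"].to_numpy()
    return df
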