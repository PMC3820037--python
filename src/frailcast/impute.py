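"""Multiple imputation by chained equations (MICE) and Rubin's-rules pooling.

The chained sampler sweeps the variables with missing values in declared
order, refitting one conditional model per variable per sweep:

``linear_pmm``
    Bayesian linear regression (sigma^2 drawn from its scaled inverse
    chi-square posterior, beta from its normal posterior) followed by
    predictive mean matching with k=5 donors, so imputed values are always
    observed values;
``logistic``
    logistic regression with coefficients drawn from their asymptotic
    normal, then a Bernoulli draw;
``multinomial``
    multinomial logistic regression with a categorical draw at the MLE
    (no parameter draw; a documented approximation).

Every draw comes from one seeded generator, so identical spec + seed gives
bitwise-identical imputations. Analyses run per completed dataset are
combined with Rubin's rules, including the Barnard–Rubin small-sample
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .stats import fit_logistic

CONDITIONAL_MODELS = ("linear_pmm", "logistic", "multinomial")


@dataclass
class ImputationSpec:
    """Configuration of one chained-equations run.

    models maps each variable with missingness to its conditional model;
    predictors maps a variable to the list of predictor columns (default:
    every other modelled-or-complete column). m >= 2 is required for
    pooling.
    """

    models: dict
    m: int = 20
    iterations: int = 10
    predictors: dict = field(default_factory=dict)
    k_pmm: int = 5
    seed: int | None = None

    def validate(self, df: pd.DataFrame) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2 for Rubin pooling")
        for var, model in self.models.items():
            if model not in CONDITIONAL_MODELS:
                raise ValueError(f"unknown conditional model {model!r} for {var!r}")
            if var not in df.columns:
                raise ValueError(f"modelled variable {var!r} not in table")
        for var in df.columns[df.isna().any()]:
            if var not in self.models:
                raise ValueError(f"variable {var!r} has missing values but no conditional model")
        for var, preds in self.predictors.items():
            if var in preds:
                raise ValueError(f"variable {var!r} predicts itself")


def _design_matrix(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design with intercept; categorical predictors one-hot encoded."""
    cols = [np.ones(len(df))]
    for p in predictors:
        col = df[p]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _draw_linear_pmm(X_obs, y_obs, X_mis, k, rng):
    n, p = X_obs.shape
    beta_hat, _, _, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / rng.chisquare(dof)
    XtX_inv = np.linalg.pinv(X_obs.T @ X_obs)
    beta_star = rng.multivariate_normal(beta_hat, sigma2_star * XtX_inv, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    # k nearest observed predictions donate their observed value
    order = np.argsort(pred_obs, kind="stable")
    pred_sorted = pred_obs[order]
    pos = np.searchsorted(pred_sorted, pred_mis)
    out = np.empty(len(pred_mis))
    for j, (pm, ip) in enumerate(zip(pred_mis, pos)):
        lo = max(0, ip - k)
        hi = min(n, ip + k)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist, kind="stable")[:k]]
        out[j] = y_obs[donors[rng.integers(len(donors))]]
    return out


def _draw_logistic(X_obs, y_obs, X_mis, rng):
    fit = fit_logistic(pd.DataFrame(X_obs[:, 1:]), y_obs, add_intercept=True)
    beta_star = rng.multivariate_normal(
        fit.params.to_numpy(), fit.cov.to_numpy(), method="cholesky"
    )
    p = expit(X_mis @ beta_star)
    return (rng.random(len(X_mis)) < p).astype(float)


def _draw_multinomial(X_obs, y_obs, X_mis, rng):
    from sklearn.linear_model import LogisticRegression

    levels, y_codes = np.unique(y_obs, return_inverse=True)
    if len(levels) == 1:
        return np.repeat(levels, len(X_mis))
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X_obs[:, 1:], y_codes)
    probs = clf.predict_proba(X_mis[:, 1:])
    cum = probs.cumsum(axis=1)
    u = rng.random(len(X_mis))
    picks = (u[:, None] < cum).argmax(axis=1)
    return levels[picks]


def mice_impute(df: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed copies of ``df``.

    A table with no missing values returns m identical copies. Variables
    that are 100% missing are an error (no basis for any conditional
    model).
    """
    spec.validate(df)
    missing_vars = [v for v in spec.models if df[v].isna().any()]
    for v in missing_vars:
        if df[v].isna().all():
            raise ValueError(f"variable {v!r} is 100% missing; no donors or model basis")
    if not missing_vars:
        return [df.copy() for _ in range(spec.m)]

    rng = np.random.default_rng(spec.seed)
    masks = {v: df[v].isna().to_numpy() for v in missing_vars}
    completed = []
    for _ in range(spec.m):
        work = df.copy()
        # initial fill: random draw from the observed margin
        for v in missing_vars:
            obs = work.loc[~masks[v], v].to_numpy()
            work.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum(), replace=True)
        for _sweep in range(spec.iterations):
            for v in missing_vars:
                preds = spec.predictors.get(v) or [c for c in df.columns if c != v]
                X = _design_matrix(work, preds)
                obs_mask = ~masks[v]
                y_obs = work.loc[obs_mask, v].to_numpy()
                X_obs, X_mis = X[obs_mask], X[masks[v]]
                model = spec.models[v]
                if model == "linear_pmm":
                    drawn = _draw_linear_pmm(X_obs, y_obs.astype(float), X_mis, spec.k_pmm, rng)
                elif model == "logistic":
                    drawn = _draw_logistic(X_obs, y_obs.astype(float), X_mis, rng)
                else:
                    drawn = _draw_multinomial(X_obs, y_obs, X_mis, rng)
                work.loc[masks[v], v] = drawn
        completed.append(work)
    return completed


def to_long(completed: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack completed datasets with an ``imp_id`` column (long format)."""
    return pd.concat(
        [d.assign(imp_id=i + 1) for i, d in enumerate(completed)], ignore_index=True
    )


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m repeated-analysis estimates."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(estimates, variances, df_complete: float | None = None,
               level: float = 0.95) -> PooledEstimate:
    """Pool per-imputation estimates and variances with Rubin's rules.

    T = W + (1 + 1/m) B. Degrees of freedom follow Barnard–Rubin when the
    complete-data degrees of freedom are supplied, otherwise the classic
    large-sample formula; the CI uses the t quantile on those df.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have matching lengths")
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if B == 0:
        dof = np.inf
    else:
        r = (1 + 1 / m) * B / W if W > 0 else np.inf
        dof_old = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1.0
        if df_complete is None:
            dof = dof_old
        else:
            lam = (1 + 1 / m) * B / T
            dof_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            dof = 1 / (1 / dof_old + 1 / dof_obs)
    tq = sps.t.ppf(0.5 + level / 2, dof) if np.isfinite(dof) else sps.norm.ppf(0.5 + level / 2)
    half = float(tq * np.sqrt(T))
    return PooledEstimate(qbar, W, B, T, float(dof), qbar - half, qbar + half, m)
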