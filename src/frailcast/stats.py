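"""Association and comparison statistics for standardized risk scores.

* maximum-likelihood logistic regression by iteratively reweighted least
  squares (IRLS), with Wald confidence intervals;
* standardized odds ratios (per 1-SD score increase), optionally
  covariate-adjusted;
* bias-corrected and accelerated (BCa) bootstrap intervals, used for
  differences between standardized ORs of competing scores (paired
  resampling of whole records);
* ROC area under the curve with paired comparisons (BCa bootstrap by
  default, DeLong correlated-curves variance as an option);
* a Wald test for score-by-sex interaction.

The logistic solver is authored here because downstream bootstrap loops
need a fast, dependency-light fit with explicit convergence metadata; it is
cross-checked against an independent reference implementation in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, ndtr, ndtri
from sklearn.metrics import roc_auc_score

Z_975 = float(ndtri(0.975))


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (possible complete separation)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; message names the offending columns."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald machinery."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    converged: bool
    iterations: int
    score_norm: float

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = float(ndtri(0.5 + level / 2))
        b, s = self.params[name], self.se[name]
        return b - z * s, b + z * s

    def wald_p(self, name: str) -> float:
        z = abs(self.params[name] / self.se[name])
        return float(2 * (1 - ndtr(z)))


@dataclass
class AssociationResult:
    """Odds ratio with 95% CI on the printed (OR) scale."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    scale: str
    method: str
    n: int
    b_resamples: int | None = None


def _design(X, add_intercept: bool) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    X = X.astype(float)
    if add_intercept and "const" not in X.columns:
        X = pd.concat([pd.Series(1.0, index=X.index, name="const"), X], axis=1)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [X.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"linearly dependent or constant column(s): {bad}"
        )


def fit_logistic(X, y, add_intercept: bool = True, tol: float = 1e-8,
                 maxiter: int = 100) -> LogisticFit:
    """Fit a binary logistic model by IRLS.

    Converges when the score (gradient) norm falls below ``tol``; raises
    :class:`ConvergenceError` on non-convergence or diverging coefficients
    (the signature of complete separation) and
    :class:`RankDeficiencyError` on collinear designs, naming the columns.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("design matrix and outcome must be fully observed")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    _check_rank(X)
    A = X.to_numpy()
    n, p = A.shape
    beta = np.zeros(p)
    score_norm = np.inf
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = A @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        score = A.T @ (y - mu)
        score_norm = float(np.linalg.norm(score))
        if score_norm < tol:
            converged = True
            break
        H = (A * w[:, None]).T @ A
        try:
            step = linalg.solve(H, score, assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 30); data are likely completely separated"
            )
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations (score norm {score_norm:.3g})"
        )
    if np.max(np.abs(beta)) > 30:
        # a vanishing score at huge coefficients is the signature of separation,
        # not of a finite maximum
        raise ConvergenceError("perfectly fitted outcome at |beta| > 30; complete separation")
    mu = expit(A @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = linalg.inv((A * w[:, None]).T @ A)
    cov = (cov + cov.T) / 2
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        n=n, converged=converged, iterations=it, score_norm=score_norm,
    )


def standardized_or(z, outcome, covariates=None, term: str = "z") -> AssociationResult:
    """Per-1-SD odds ratio from a logistic fit on a standardized score.

    ``covariates`` (optional DataFrame) are entered additively, giving the
    adjusted model; the reported OR is always for the score term.
    """
    z = pd.Series(np.asarray(z, dtype=float), name=term).reset_index(drop=True)
    X = z.to_frame()
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    fit = fit_logistic(X, np.asarray(outcome, dtype=float))
    lo, hi = fit.wald_ci(term)
    return AssociationResult(
        odds_ratio=float(np.exp(fit.params[term])),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        scale="per 1 SD", method="wald", n=fit.n,
    )


# ---------------------------------------------------------------------------
# BCa bootstrap


@dataclass
class BCaResult:
    low: float
    high: float
    estimate: float
    z0: float
    accel: float
    B: int

    def __iter__(self):
        return iter((self.low, self.high))


def _fast_logit_beta(z: np.ndarray, y: np.ndarray, maxiter: int = 50) -> float:
    """Slope of an intercept+slope logistic fit; Newton, tuned for bootstrap loops."""
    n = len(z)
    beta = np.zeros(2)
    for _ in range(maxiter):
        eta = beta[0] + beta[1] * z
        mu = expit(eta)
        r = y - mu
        g0, g1 = r.sum(), r @ z
        if g0 * g0 + g1 * g1 < 1e-18:
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        sw, swz = w.sum(), w @ z
        swzz = w @ (z * z)
        det = sw * swzz - swz * swz
        beta[0] += (swzz * g0 - swz * g1) / det
        beta[1] += (sw * g1 - swz * g0) / det
        if abs(beta[1]) > 50 or abs(beta[0]) > 50:
            raise ConvergenceError("separation in bootstrap logistic fit")
    return beta[1]


def bca_ci(statistic, data, B: int = 2000, seed=None, alpha: float = 0.05,
           vectorized: bool = False, jackknife: bool = True) -> BCaResult:
    """Bias-corrected and accelerated bootstrap interval for one statistic.

    ``data`` is an array or a tuple of same-length arrays resampled jointly
    (paired resampling of whole records). The bias constant is
    z0 = ndtri((#{theta* < theta_hat} + 0.5 #{theta* = theta_hat}) / B) and
    the acceleration comes from the jackknife third-moment formula. With a
    ``vectorized`` statistic it is called as ``statistic(*cols)`` on arrays
    whose last axis indexes observations, returning one value per row.

    A degenerate bootstrap distribution (all resample values equal) collapses
    the interval to a point with a warning; ``seed`` makes output
    reproducible.
    """
    if B < 200:
        raise ValueError("B must be at least 200 for a BCa interval")
    arrays = data if isinstance(data, (tuple, list)) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(*arrays))

    idx = rng.integers(0, n, size=(B, n))
    if vectorized:
        theta_star = np.asarray(statistic(*(a[idx] for a in arrays)), dtype=float)
    else:
        theta_star = np.array(
            [statistic(*(arr[ix] for arr in arrays)) for ix in idx], dtype=float
        )

    if np.all(theta_star == theta_star[0]):
        warnings.warn("degenerate bootstrap distribution; interval collapsed to a point")
        return BCaResult(theta_star[0], theta_star[0], theta_hat, 0.0, 0.0, B)

    prop = (np.sum(theta_star < theta_hat) + 0.5 * np.sum(theta_star == theta_hat)) / B
    prop = min(max(prop, 0.5 / B), 1 - 0.5 / B)  # keep z0 finite on one-sided draws
    z0 = float(ndtri(prop))

    a = 0.0
    if jackknife:
        if vectorized:
            mask = ~np.eye(n, dtype=bool)
            jack_idx = np.broadcast_to(np.arange(n), (n, n))[mask].reshape(n, n - 1)
            theta_jack = np.asarray(statistic(*(arr[jack_idx] for arr in arrays)), dtype=float)
        else:
            theta_jack = np.array([
                statistic(*(np.delete(arr, i) for arr in arrays)) for i in range(n)
            ], dtype=float)
        d = theta_jack.mean() - theta_jack
        denom = (d @ d) ** 1.5
        if denom > 0:
            a = float((d ** 3).sum() / (6 * denom))

    a1, a2 = adjusted_quantile_levels(z0, a, alpha)
    lo = float(np.quantile(theta_star, a1))
    hi = float(np.quantile(theta_star, a2))
    return BCaResult(lo, hi, theta_hat, z0, a, B)


def adjusted_quantile_levels(z0: float, accel: float, alpha: float = 0.05) -> tuple[float, float]:
    """BCa-adjusted bootstrap quantile levels.

    With z0 = accel = 0 this reduces exactly to the percentile interval's
    (alpha/2, 1 - alpha/2).
    """
    def _adj(z):
        num = z0 + z
        return float(ndtr(z0 + num / (1 - accel * num)))
    return _adj(float(ndtri(alpha / 2))), _adj(float(ndtri(1 - alpha / 2)))


@dataclass
class OrDifference:
    """Difference of per-1-SD ORs (b minus a) with a BCa bootstrap CI."""

    delta: float
    ci_low: float
    ci_high: float
    or_a: float
    or_b: float
    B: int
    seed: object = None


def or_difference(z_a, z_b, outcome, B: int = 2000, seed=None) -> OrDifference:
    """Δ = OR_b − OR_a on the OR scale, CI by paired BCa bootstrap.

    Whole records are resampled jointly and scores are re-standardized
    within each resample, so the interval reflects the sampling variability
    of the standardisation as well as the fit.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    y = np.asarray(outcome, dtype=float)

    def stat(a, b, yy):
        sa = a.std(ddof=1)
        sb = b.std(ddof=1)
        or_a = np.exp(_fast_logit_beta((a - a.mean()) / sa, yy))
        or_b = np.exp(_fast_logit_beta((b - b.mean()) / sb, yy))
        return or_b - or_a

    res = bca_ci(stat, (z_a, z_b, y), B=B, seed=seed)
    or_a = np.exp(_fast_logit_beta((z_a - z_a.mean()) / z_a.std(ddof=1), y))
    or_b = np.exp(_fast_logit_beta((z_b - z_b.mean()) / z_b.std(ddof=1), y))
    return OrDifference(res.estimate, res.low, res.high, float(or_a), float(or_b), B, seed)


# ---------------------------------------------------------------------------
# ROC / AUC


def auc(score, outcome) -> float:
    """Mann–Whitney AUC (ties counted 1/2); equals the trapezoidal ROC area."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present to compute an AUC")
    return float(roc_auc_score(y, np.asarray(score, dtype=float)))


def _delong_variance(score_a, score_b, y):
    """DeLong covariance machinery for two paired ROC curves.

    Returns (auc_a, auc_b, var of the difference).
    """
    from scipy.stats import rankdata

    y = np.asarray(y, dtype=bool)
    aucs, v10, v01 = [], [], []
    for s in (np.asarray(score_a, float), np.asarray(score_b, float)):
        pos, neg = s[y], s[~y]
        m, n = len(pos), len(neg)
        r_all = rankdata(np.concatenate([pos, neg]))
        r_pos, r_neg = rankdata(pos), rankdata(neg)
        auc_s = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
        aucs.append(auc_s)
        v10.append((r_all[:m] - r_pos) / n)          # structural components, cases
        v01.append(1.0 - (r_all[m:] - r_neg) / m)    # structural components, controls
    v10 = np.vstack(v10)
    v01 = np.vstack(v01)
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    m, n = v10.shape[1], v01.shape[1]
    cov_delta = s10 / m + s01 / n
    var_diff = float(cov_delta[0, 0] + cov_delta[1, 1] - 2 * cov_delta[0, 1])
    return float(aucs[0]), float(aucs[1]), var_diff


@dataclass
class AucComparison:
    delta: float
    ci_low: float
    ci_high: float
    auc_a: float
    auc_b: float
    method: str
    B: int | None = None


def auc_difference(score_a, score_b, outcome, method: str = "paired_bootstrap_bca",
                   B: int = 2000, seed=None, level: float = 0.95) -> AucComparison:
    """ΔAUC = AUC_b − AUC_a for paired scores, with a 95% CI.

    Default CI is the paired BCa bootstrap (consistent with the OR-difference
    procedure); ``method='delong'`` uses the DeLong correlated-curves
    variance instead.
    """
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    auc_a, auc_b = auc(sa, y), auc(sb, y)
    delta = auc_b - auc_a
    if method == "delong":
        a_, b_, var = _delong_variance(sa, sb, y)
        z = float(ndtri(0.5 + level / 2))
        half = z * np.sqrt(var)
        return AucComparison(b_ - a_, b_ - a_ - half, b_ - a_ + half, a_, b_, "delong")
    if method != "paired_bootstrap_bca":
        raise ValueError(f"unknown method {method!r}")

    def stat(a, b, yy):
        # vectorized over resample rows: Mann-Whitney via rank sums per row
        from scipy.stats import rankdata
        if a.ndim == 1:
            return auc(b, yy) - auc(a, yy)
        out = np.empty(a.shape[0])
        for i in range(a.shape[0]):
            yi = yy[i]
            if yi.min() == yi.max():
                out[i] = np.nan
                continue
            out[i] = _mw_auc(b[i], yi) - _mw_auc(a[i], yi)
        return out

    res = bca_ci(stat, (sa, sb, y), B=B, seed=seed, vectorized=True)
    return AucComparison(delta, res.low, res.high, auc_a, auc_b, "paired_bootstrap_bca", B)


def _mw_auc(s: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata
    r = rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return (r[y == 1].sum() - m * (m + 1) / 2) / (m * n)


def sex_interaction_test(z, sex, outcome) -> float:
    """Wald p-value for the score-by-sex product term.

    The model contains the score, a female indicator and their product; the
    returned p-value tests whether the per-SD association differs by sex.
    Invariant to which sex is coded 1.
    """
    z = np.asarray(z, dtype=float)
    sex = np.asarray(sex)
    female = (sex == "female").astype(float) if sex.dtype.kind in "OUS" else sex.astype(float)
    if len(np.unique(female)) < 2:
        raise ValueError("both sexes must be present for an interaction test")
    X = pd.DataFrame({"z": z, "female": female, "z_x_female": z * female})
    fit = fit_logistic(X, np.asarray(outcome, dtype=float))
    return fit.wald_p("z_x_female")
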