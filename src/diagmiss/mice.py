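"""Multiple imputation of the binary index test with Rubin's-rules pooling.

Only the index test ``Y`` is ever missing, so the chained-equations scheme
collapses to a single univariate step per imputation: fit the logistic
imputation model

    P(Y=1 | X1, X2, X3, R) = expit(b0 + b1*X1 + b2*X2 + b3*X3 + b4*R)

on the complete rows, draw coefficients from the large-sample normal
approximation of their posterior (mean = MLE, covariance = inverse observed
information — "proper" imputation), and impute each missing ``Y`` as a
Bernoulli draw from its fitted probability.  No Gibbs cycling is needed.

Each of the ``m`` completed datasets yields a sensitivity/specificity
estimate on the logit scale; these are pooled with Rubin's rules
(within/between/total variance, Barnard–Rubin degrees of freedom) and
back-transformed.  Pooling on the logit scale matches the logit confidence
intervals used for the single-dataset methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .errors import HandlerFailure
from .estimation import EstimateCI, confusion_counts, margin_logit

__all__ = [
    "ImputationDraw",
    "PooledEstimate",
    "draw_imputation",
    "mice_impute",
    "pool_rubin",
    "mice_sens_spec",
]

PREDICTORS = ("X1", "X2", "X3")  # plus intercept and reference standard R (=D)
RIDGE_PENALTY = 1e-4


@dataclass
class ImputationDraw:
    coefficients: np.ndarray  # (b0, b1, b2, b3, b4)
    completed_table: pd.DataFrame


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    within_var: float  # logit scale
    between_var: float
    total_var: float
    df: float
    ci_lower: float
    ci_upper: float
    m: int


def _design(table: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(table))]
    cols += [table[c].to_numpy(dtype=float) for c in PREDICTORS]
    cols.append(table["D"].to_numpy(dtype=float))  # reference standard R
    return np.column_stack(cols)


def _ridge_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """IRLS logistic fit with a small ridge penalty on non-intercept terms;
    used when the unpenalized MLE fails (separation, non-convergence)."""
    p = X.shape[1]
    pen = RIDGE_PENALTY * np.diag([0.0] + [1.0] * (p - 1))
    beta = np.zeros(p)
    for _ in range(100):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        hess = X.T @ (w[:, None] * X) + pen
        grad = X.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            cov = np.linalg.inv(hess)
            return beta, cov
    raise HandlerFailure("ridge-penalized imputation model did not converge")


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MLE fit via statsmodels; ridge fallback on separation/non-convergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=0)
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if (
            res.mle_retvals.get("converged", False)
            and np.isfinite(beta).all()
            and np.isfinite(cov).all()
            and np.abs(beta).max() < 30.0
        ):
            return beta, cov
    except Exception:
        pass
    warnings.warn("logistic MLE failed; using ridge-penalized fit", stacklevel=3)
    return _ridge_logistic(X, y)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def draw_imputation(
    table: pd.DataFrame, seed: int, posterior_scale: float = 1.0
) -> ImputationDraw:
    """One proper imputation of the missing index-test values.

    ``posterior_scale`` scales the posterior covariance of the coefficient
    draw; 0 degenerates to imputing from the MLE fitted probabilities.
    """
    missing = table["Y"].isna()
    if not missing.any():
        return ImputationDraw(
            coefficients=np.full(5, np.nan), completed_table=table.copy()
        )
    observed = ~missing
    if not observed.any():
        raise HandlerFailure("no observed index-test values to fit on")
    rng = np.random.default_rng(seed)
    X_obs = _design(table[observed])
    y_obs = table.loc[observed, "Y"].to_numpy(dtype=float)
    beta_hat, cov = _fit_logistic(X_obs, y_obs)
    beta = beta_hat + posterior_scale * (_psd_factor(cov) @ rng.standard_normal(5))
    X_mis = _design(table[missing])
    p_mis = expit(X_mis @ beta)
    out = table.copy()
    out["Y"] = out["Y"].astype(float)
    out.loc[missing, "Y"] = (rng.random(p_mis.shape[0]) < p_mis).astype(float)
    return ImputationDraw(coefficients=beta, completed_table=out)


def mice_impute(table: pd.DataFrame, m: int, seed: int) -> list[pd.DataFrame]:
    """``m`` independently drawn completed datasets (sub-seeds derived from
    ``seed``); all agree with the input on observed entries."""
    if m < 2:
        raise ValueError("multiple imputation requires m >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(m)
    return [
        draw_imputation(table, int(s)).completed_table for s in seeds
    ]


def pool_rubin(
    estimates: list[tuple[float, float]],
    level: float = 0.95,
    df_complete: float = np.inf,
) -> PooledEstimate:
    """Pool ``(point, logit_se)`` pairs from the m completed datasets.

    Variance components follow Rubin's rules on the logit scale; degrees of
    freedom use the Barnard–Rubin small-sample adjustment bounded by the
    complete-data df, and the interval is ``qbar +/- t_{df} * sqrt(T)``
    back-transformed to the probability scale.
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("pooling requires at least two estimates")
    q = np.array([logit(p) for p, _ in estimates])
    se = np.array([s for _, s in estimates])
    qbar = float(np.mean(q))
    within = float(np.mean(se**2))
    between = float(np.var(q, ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    lam = (1.0 + 1.0 / m) * between / total if total > 0 else 0.0
    if lam <= 0.0:
        df = df_complete if np.isfinite(df_complete) else np.inf
    else:
        df_old = (m - 1) / lam**2
        if np.isfinite(df_complete):
            nu = df_complete
            df_obs = (nu + 1.0) / (nu + 3.0) * nu * (1.0 - lam)
            df = df_old * df_obs / (df_old + df_obs)
        else:
            df = df_old
    tq = t_dist.ppf(0.5 + level / 2.0, df) if np.isfinite(df) else float(
        t_dist.ppf(0.5 + level / 2.0, 1e9)
    )
    half = tq * np.sqrt(total)
    return PooledEstimate(
        point=float(expit(qbar)),
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        ci_lower=float(expit(qbar - half)),
        ci_upper=float(expit(qbar + half)),
        m=m,
    )


def _pooled_to_ci(
    estimand: str, pooled: PooledEstimate, n_group: float, level: float, flag: bool
) -> EstimateCI:
    return EstimateCI(
        estimand=estimand,
        point=pooled.point,
        lower=pooled.ci_lower,
        upper=pooled.ci_upper,
        n_group=n_group,
        level=level,
        degenerate_flag=flag,
    )


def mice_sens_spec(
    table: pd.DataFrame, m: int = 5, seed: int = 0, level: float = 0.95
) -> tuple[EstimateCI, EstimateCI]:
    """End-to-end MICE estimate: impute m datasets, estimate each margin on
    the logit scale, pool with Rubin's rules."""
    completed = mice_impute(table, m, seed)
    sens_parts: list[tuple[float, float]] = []
    spec_parts: list[tuple[float, float]] = []
    flags = {"sensitivity": False, "specificity": False}
    n_sens = n_spec = 0.0
    for tab in completed:
        c = confusion_counts(tab)
        p, s, deg = margin_logit(c.tp, c.tp + c.fn)
        sens_parts.append((p, s))
        flags["sensitivity"] |= deg
        n_sens = c.tp + c.fn
        p, s, deg = margin_logit(c.tn, c.tn + c.fp)
        spec_parts.append((p, s))
        flags["specificity"] |= deg
        n_spec = c.tn + c.fp
    sens = pool_rubin(sens_parts, level=level, df_complete=max(n_sens - 1.0, 1.0))
    spec = pool_rubin(spec_parts, level=level, df_complete=max(n_spec - 1.0, 1.0))
    return (
        _pooled_to_ci("sensitivity", sens, n_sens, level, flags["sensitivity"]),
        _pooled_to_ci("specificity", spec, n_spec, level, flags["specificity"]),
    )
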