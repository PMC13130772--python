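"""Monte Carlo performance measures and their standard errors.

Per scenario x method x estimand, repetition-level estimates are summarized
into bias, MSE, empirical standard error, coverage of the 95% interval and
(optionally) power against a null value theta0, each with its Monte Carlo
standard error.  Excluded or failed repetitions are dropped from the
denominator and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "bias",
    "mse",
    "empse",
    "coverage",
    "power",
    "mcse_bias",
    "mcse_mse",
    "mcse_empse",
    "mcse_coverage",
    "mcse_power",
    "mcse_all",
    "PerformanceSummary",
    "summarize",
]


def _arr(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValueError("empty estimate vector")
    return a


def bias(estimates, theta: float) -> float:
    """Mean of (theta_hat_i - theta)."""
    return float(np.mean(_arr(estimates) - theta))


def mse(estimates, theta: float) -> float:
    """Mean of (theta_hat_i - theta)^2."""
    return float(np.mean((_arr(estimates) - theta) ** 2))


def empse(estimates) -> float:
    """Empirical SD of the estimates (ddof=1); 0 for a single repetition."""
    a = _arr(estimates)
    return float(np.std(a, ddof=1)) if a.size > 1 else 0.0


def coverage(lowers, uppers, theta: float) -> float:
    """Fraction of intervals [lower_i, upper_i] containing theta."""
    lo, hi = _arr(lowers), _arr(uppers)
    return float(np.mean((lo <= theta) & (theta <= hi)))


def power(lowers, theta0: float) -> float:
    """Fraction of repetitions whose lower bound excludes theta0 from below."""
    return float(np.mean(theta0 <= _arr(lowers)))


def mcse_bias(estimates) -> float:
    a = _arr(estimates)
    if a.size < 2:
        return float("nan")
    return float(np.sqrt(np.sum((a - a.mean()) ** 2) / (a.size * (a.size - 1))))


def mcse_mse(estimates, theta: float) -> float:
    a = _arr(estimates)
    if a.size < 2:
        return float("nan")
    sq = (a - theta) ** 2
    return float(np.sqrt(np.sum((sq - sq.mean()) ** 2) / (a.size * (a.size - 1))))


def mcse_empse(estimates) -> float:
    a = _arr(estimates)
    if a.size < 2:
        return float("nan")
    return float(empse(a) / np.sqrt(2.0 * (a.size - 1)))


def _binomial_mcse(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def mcse_coverage(cov: float, n_sim: int) -> float:
    return _binomial_mcse(cov, n_sim)


def mcse_power(pwr: float, n_sim: int) -> float:
    return _binomial_mcse(pwr, n_sim)


def mcse_all(estimates, lowers, uppers, theta: float, theta0: float | None = None):
    """(mcse_bias, mcse_mse, mcse_empse, mcse_coverage, mcse_power)."""
    a = _arr(estimates)
    cov = coverage(lowers, uppers, theta)
    m_pow = (
        mcse_power(power(lowers, theta0), a.size) if theta0 is not None else float("nan")
    )
    return (
        mcse_bias(a),
        mcse_mse(a, theta),
        mcse_empse(a),
        mcse_coverage(cov, a.size),
        m_pow,
    )


@dataclass(frozen=True)
class PerformanceSummary:
    n_sim_total: int
    n_excluded: int
    n_failed: int
    n_sim_effective: int
    theta_true: float
    bias: float
    mse: float
    empse: float
    coverage: float
    power: float
    mcse_bias: float
    mcse_mse: float
    mcse_empse: float
    mcse_coverage: float
    mcse_power: float
    theta0: float
    ci_len_min: float
    ci_len_median: float
    ci_len_max: float
    n_degenerate: int


SCENARIO_COLS = [
    "true_sens",
    "true_spec",
    "mechanism",
    "miss_prop",
    "prevalence",
    "n",
]


def summarize(reps: pd.DataFrame, theta0=None) -> pd.DataFrame:
    """Aggregate a long-form repetition table into performance summaries.

    ``reps`` needs columns scenario_id, the scenario factors, method,
    estimand, point, lower, upper, excluded, failed, degenerate, theta_true.
    ``theta0`` may be a float or a {"sensitivity": ..., "specificity": ...}
    mapping; power is NaN when absent.
    """
    rows = []
    keys = ["scenario_id", "method", "estimand"]
    for (sid, method, estimand), grp in reps.groupby(keys, sort=True):
        valid = grp[~grp["excluded"] & ~grp["failed"]]
        theta = float(grp["theta_true"].iloc[0])
        t0 = theta0.get(estimand) if isinstance(theta0, dict) else theta0
        n_eff = len(valid)
        if n_eff > 0:
            est = valid["point"].to_numpy()
            lo = valid["lower"].to_numpy()
            hi = valid["upper"].to_numpy()
            widths = hi - lo
            summary = PerformanceSummary(
                n_sim_total=len(grp),
                n_excluded=int(grp["excluded"].sum()),
                n_failed=int(grp["failed"].sum()),
                n_sim_effective=n_eff,
                theta_true=theta,
                bias=bias(est, theta),
                mse=mse(est, theta),
                empse=empse(est),
                coverage=coverage(lo, hi, theta),
                power=power(lo, t0) if t0 is not None else float("nan"),
                mcse_bias=mcse_bias(est),
                mcse_mse=mcse_mse(est, theta),
                mcse_empse=mcse_empse(est),
                mcse_coverage=mcse_coverage(coverage(lo, hi, theta), n_eff),
                mcse_power=(
                    mcse_power(power(lo, t0), n_eff)
                    if t0 is not None
                    else float("nan")
                ),
                theta0=float(t0) if t0 is not None else float("nan"),
                ci_len_min=float(widths.min()),
                ci_len_median=float(np.median(widths)),
                ci_len_max=float(widths.max()),
                n_degenerate=int(valid["degenerate"].sum()),
            )
        else:
            summary = PerformanceSummary(
                n_sim_total=len(grp),
                n_excluded=int(grp["excluded"].sum()),
                n_failed=int(grp["failed"].sum()),
                n_sim_effective=0,
                theta_true=theta,
                bias=float("nan"),
                mse=float("nan"),
                empse=float("nan"),
                coverage=float("nan"),
                power=float("nan"),
                mcse_bias=float("nan"),
                mcse_mse=float("nan"),
                mcse_empse=float("nan"),
                mcse_coverage=float("nan"),
                mcse_power=float("nan"),
                theta0=float(t0) if t0 is not None else float("nan"),
                ci_len_min=float("nan"),
                ci_len_median=float("nan"),
                ci_len_max=float("nan"),
                n_degenerate=0,
            )
        row = {"scenario_id": sid, "method": method, "estimand": estimand}
        for col in SCENARIO_COLS:
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        row.update(asdict(summary))
        rows.append(row)
    return pd.DataFrame(rows)
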