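"""Amputation: introducing missing values into the index test.

There is a single missingness pattern — only ``Y`` is ever set missing; the
reference standard and covariates stay fully observed.  Under MCAR every
subject has the same missingness probability.  Under MAR/MNAR each subject's
probability is driven by a weighted sum score

    wss_i = w_Y * Y_i + w_X1 * X1_i + w_X2 * X2_i + w_X3 * X3_i + w_R * R_i

with default weights (0, 1, 1, 1, 1) for MAR (missingness depends only on
observed variables) and (1, 0, 0, 0, 0) for MNAR (missingness depends on the
unobserved value itself).  Scores are standardized and mapped through a
logistic CDF shifted so the mean missingness probability equals the requested
proportion — higher scores are more likely to be missing (a "RIGHT"-type
allocation).  Amputation is stochastic (independent Bernoulli draws), so the
realized missing fraction varies around the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, ConvergenceError, IncompleteDataError

__all__ = [
    "AmputationConfig",
    "MAR_WEIGHTS",
    "MNAR_WEIGHTS",
    "default_weights",
    "compute_wss",
    "solve_probability_shift",
    "ampute",
]

WSS_VARIABLES = ("Y", "X1", "X2", "X3", "R")

MAR_WEIGHTS = {"Y": 0.0, "X1": 1.0, "X2": 1.0, "X3": 1.0, "R": 1.0}
MNAR_WEIGHTS = {"Y": 1.0, "X1": 0.0, "X2": 0.0, "X3": 0.0, "R": 0.0}


def default_weights(mechanism: str) -> dict[str, float]:
    if mechanism == "MAR":
        return dict(MAR_WEIGHTS)
    if mechanism == "MNAR":
        return dict(MNAR_WEIGHTS)
    if mechanism == "MCAR":
        return {v: 0.0 for v in WSS_VARIABLES}  # ignored
    raise ConfigurationError(f"unknown mechanism {mechanism!r}")


@dataclass
class AmputationConfig:
    mechanism: str
    miss_prop: float
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.miss_prop < 1.0):
            raise ConfigurationError(
                f"miss_prop must lie in [0, 1), got {self.miss_prop!r}"
            )
        if self.weights is None:
            self.weights = default_weights(self.mechanism)
        else:
            unknown = set(self.weights) - set(WSS_VARIABLES)
            if unknown:
                raise ConfigurationError(f"unknown weight variables: {sorted(unknown)}")


def compute_wss(table: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    """Weighted sum score per subject.  ``R`` refers to the reference-standard
    column ``D`` (the reference standard is error-free here)."""
    if table["Y"].isna().any():
        raise IncompleteDataError("weighted sum scores require a complete table")
    wss = np.zeros(len(table))
    for var, w in weights.items():
        if w == 0.0:
            continue
        col = table["D"] if var == "R" else table[var]
        wss += w * col.to_numpy(dtype=float)
    return wss


def solve_probability_shift(
    wss: np.ndarray, miss_prop: float, tol: float = 1e-9, max_iter: int = 200
) -> float:
    """Shift ``c`` such that ``mean(expit(z + c)) == miss_prop`` where ``z``
    are the standardized scores; solved by bisection.

    Degenerate (constant) scores fall back to the constant-probability shift
    ``logit(miss_prop)``.
    """
    if not (0.0 < miss_prop < 1.0):
        raise ConfigurationError(f"miss_prop must be in (0, 1), got {miss_prop!r}")
    sd = float(np.std(wss))
    if sd == 0.0:
        return float(logit(miss_prop))
    z = (wss - np.mean(wss)) / sd
    lo, hi = -60.0, 60.0
    for _ in range(max_iter):
        c = 0.5 * (lo + hi)
        m = float(np.mean(expit(z + c)))
        if abs(m - miss_prop) < tol:
            return c
        if m < miss_prop:
            lo = c
        else:
            hi = c
    raise ConvergenceError("probability-shift bisection did not converge")


def ampute(table: pd.DataFrame, config: AmputationConfig, seed: int) -> pd.DataFrame:
    """Return a copy of ``table`` with index-test values set missing.

    MCAR: each ``Y`` is independently missing with probability ``miss_prop``.
    MAR/MNAR: subject ``i`` is missing with probability ``expit(z_i + c)``,
    monotone increasing in the weighted sum score.  Only ``Y`` is amputed.
    """
    if table["Y"].isna().any():
        raise IncompleteDataError("ampute expects a complete table")
    out = table.copy()
    out["Y"] = out["Y"].astype(float)
    if config.miss_prop == 0.0:
        return out
    if config.mechanism == "MCAR":
        probs = np.full(len(out), config.miss_prop)
    else:
        wss = compute_wss(table, config.weights)
        sd = float(np.std(wss))
        if sd == 0.0:
            probs = np.full(len(out), config.miss_prop)
        else:
            z = (wss - np.mean(wss)) / sd
            c = solve_probability_shift(wss, config.miss_prop)
            probs = expit(z + c)
    rng = np.random.default_rng(seed)
    mask = rng.random(len(out)) < probs
    out.loc[mask, "Y"] = np.nan
    return out
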