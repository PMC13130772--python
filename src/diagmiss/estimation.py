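"""Sensitivity and specificity with logit Wald confidence intervals.

Point estimates are the usual binomial proportions
``sens = TP/(TP+FN)``, ``spec = TN/(TN+FP)``; the 95% interval is computed on
the logit scale, ``logit(p) +/- z * sqrt(1/x + 1/(n-x))``, and
back-transformed, which keeps the endpoints inside [0, 1].  Counts may be
fractional (allocation-based handlers produce real-valued pseudo-counts); the
same formulas apply unchanged.

A degenerate margin (x = 0 or x = n successes) has an undefined logit; the
margin's two cells then receive a 0.5 continuity correction (x + 0.5 out of
n + 1) for both the point estimate and the interval, and the estimate is
flagged so downstream summaries can count how often this happened.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import EstimationError, IncompleteDataError

__all__ = ["ConfusionCounts", "EstimateCI", "confusion_counts", "sens_spec_ci"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table of index test vs reference standard; fractional counts allowed."""

    tp: float
    fn: float
    tn: float
    fp: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise EstimationError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class EstimateCI:
    estimand: str  # "sensitivity" | "specificity"
    point: float
    lower: float
    upper: float
    n_group: float
    level: float = 0.95
    degenerate_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise EstimationError(
                f"invalid interval ordering for {self.estimand}: "
                f"({self.lower}, {self.point}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def confusion_counts(table: pd.DataFrame) -> ConfusionCounts:
    """Tally a (pseudo-)complete subject table into a 2x2 count table."""
    if table["Y"].isna().any():
        raise IncompleteDataError("confusion counts require a complete table")
    d = table["D"].to_numpy()
    y = table["Y"].to_numpy()
    return ConfusionCounts(
        tp=float(((d == 1) & (y == 1)).sum()),
        fn=float(((d == 1) & (y == 0)).sum()),
        tn=float(((d == 0) & (y == 0)).sum()),
        fp=float(((d == 0) & (y == 1)).sum()),
    )


def margin_logit(x: float, n: float) -> tuple[float, float, bool]:
    """Point estimate, logit-scale standard error and degeneracy flag for a
    binomial margin with ``x`` successes out of ``n`` (fractional allowed)."""
    if n <= 0:
        raise EstimationError("empty reference group: cannot estimate this margin")
    degenerate = x <= 0 or x >= n
    if degenerate:
        x = x + 0.5
        n = n + 1.0
    p = x / n
    se = math.sqrt(1.0 / x + 1.0 / (n - x))
    return p, se, degenerate


def _margin_ci(estimand: str, x: float, n: float, level: float) -> EstimateCI:
    p, se, degenerate = margin_logit(x, n)
    z = norm.ppf(0.5 + level / 2.0)
    lo = float(expit(logit(p) - z * se))
    hi = float(expit(logit(p) + z * se))
    return EstimateCI(
        estimand=estimand,
        point=float(p),
        lower=lo,
        upper=hi,
        n_group=float(n),
        level=level,
        degenerate_flag=degenerate,
    )


def sens_spec_ci(
    counts: ConfusionCounts, level: float = 0.95
) -> tuple[EstimateCI, EstimateCI]:
    """Sensitivity and specificity estimates with logit Wald intervals."""
    sens = _margin_ci("sensitivity", counts.tp, counts.tp + counts.fn, level)
    spec = _margin_ci("specificity", counts.tn, counts.tn + counts.fp, level)
    return sens, spec
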