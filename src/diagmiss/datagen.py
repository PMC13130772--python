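"""Synthetic single-test diagnostic-study data.

Subjects carry an error-free reference standard ``D`` (1 = target condition
present), a binary index test ``Y`` and three binary covariates ``X1``--``X3``
(think sex, a dichotomized biomarker, age group). Data are generated from a
latent multivariate normal model, one model per reference-standard group, and
dichotomized:

* the latent index test has mean 0 in the non-diseased group and mean
  ``Phi^{-1}(spec) - Phi^{-1}(1 - sens)`` in the diseased group, with the
  dichotomization cutoff at ``Phi^{-1}(spec)``.  This calibration makes the
  expected complete-data sensitivity and specificity equal to the scenario's
  true values exactly;
* covariates have latent means (0, 5, 35), unit variance, and are median-split
  at their means, so each is Bernoulli(1/2);
* latent correlations are chosen so that the phi coefficient (Pearson
  correlation of the dichotomized variables) hits a target value, 0.4 by
  default, for every pair.  The attenuation caused by dichotomization is
  undone by inverting the bivariate-normal orthant probability
  (the tetrachoric <-> phi relation).

For extreme index margins the target phi of 0.4 can be unattainable (the phi
coefficient of binary variables is bounded by their margins); those pairs fall
back to the median-split adjustment ``rho = sin(pi * phi / 2)`` with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm
from statsmodels.stats.correlation_tools import corr_nearest

from .errors import ConfigurationError, InfeasibleCorrelationError

__all__ = [
    "ScenarioSpec",
    "LatentModel",
    "COVARIATE_MEANS",
    "diseased_mean",
    "solve_latent_correlation",
    "build_latent_model",
    "generate_complete",
]

COVARIATE_MEANS = (0.0, 5.0, 35.0)

MECHANISMS = ("MCAR", "MAR", "MNAR")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ConfigurationError(f"{name} must lie strictly in (0, 1), got {value!r}")


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero (``round(40.5) -> 41``), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial simulation design."""

    true_sens: float
    true_spec: float
    mechanism: str
    miss_prop: float
    prevalence: float
    n: int

    def __post_init__(self) -> None:
        _check_prob("true_sens", self.true_sens)
        _check_prob("true_spec", self.true_spec)
        _check_prob("miss_prop", self.miss_prop)
        _check_prob("prevalence", self.prevalence)
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if int(self.n) != self.n or self.n < 4:
            raise ConfigurationError(f"n must be an integer >= 4, got {self.n!r}")
        if self.n_diseased < 1:
            raise ConfigurationError(
                f"round(n * prevalence) must be >= 1 (n={self.n}, "
                f"prevalence={self.prevalence})"
            )

    @property
    def n_diseased(self) -> int:
        """Deterministic diseased-group size, round-half-away-from-zero."""
        return _round_half_away(self.n * self.prevalence)

    @property
    def n_nondiseased(self) -> int:
        return int(self.n) - self.n_diseased

    def label(self) -> str:
        return (
            f"sens{self.true_sens:g}_spec{self.true_spec:g}_{self.mechanism}"
            f"_miss{self.miss_prop:g}_prev{self.prevalence:g}_n{self.n}"
        )


@dataclass(frozen=True)
class LatentModel:
    """Latent-normal model behind one scenario.

    The two reference-standard groups share covariate means and cutoffs but
    differ in the latent index-test mean and, because correlations are solved
    against the group-specific index cutpoint, in the latent correlation
    matrix.
    """

    mean_nondiseased: np.ndarray
    mean_diseased: np.ndarray
    corr_nondiseased: np.ndarray
    corr_diseased: np.ndarray
    cutoffs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("corr_nondiseased", "corr_diseased"):
            c = getattr(self, name)
            if c.shape != (4, 4) or not np.allclose(c, c.T):
                raise ConfigurationError(f"{name} must be a symmetric 4x4 matrix")
            if not np.allclose(np.diag(c), 1.0):
                raise ConfigurationError(f"{name} must have a unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigurationError(f"{name} is not positive semi-definite")


def diseased_mean(true_sens: float, true_spec: float) -> float:
    """Latent index-test mean in the diseased group.

    With the dichotomization cutoff at ``Phi^{-1}(spec)`` and unit variance,
    a diseased mean of ``Phi^{-1}(spec) - Phi^{-1}(1 - sens)`` makes
    ``P(Y=1 | D=1) = sens`` and ``P(Y=0 | D=0) = spec`` exactly.
    """
    _check_prob("true_sens", true_sens)
    _check_prob("true_spec", true_spec)
    return float(norm.ppf(true_spec) - norm.ppf(1.0 - true_sens))


def _phi_of_latent(rho: float, cut_a: float, cut_b: float) -> float:
    """Phi coefficient of two standard normals with correlation ``rho``
    dichotomized at ``cut_a`` and ``cut_b`` (value > cut -> 1)."""
    p1 = norm.sf(cut_a)
    p2 = norm.sf(cut_b)
    if rho >= 1.0 - 1e-12:
        p11 = norm.sf(max(cut_a, cut_b))
    elif rho <= -1.0 + 1e-12:
        p11 = max(0.0, norm.cdf(-cut_b) - norm.cdf(cut_a))
    else:
        cdf = multivariate_normal.cdf(
            [cut_a, cut_b], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        p11 = 1.0 - norm.cdf(cut_a) - norm.cdf(cut_b) + cdf
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (p11 - p1 * p2) / denom


def solve_latent_correlation(
    target_phi: float, cut_a: float, cut_b: float, tol: float = 1e-6
) -> float:
    """Latent correlation whose dichotomization yields ``target_phi``.

    Inverts the orthant probability of the standard bivariate normal by
    root-finding on rho.  For two median splits this reduces to the closed
    form ``rho = sin(pi * phi / 2)``.

    Raises
    ------
    InfeasibleCorrelationError
        If ``target_phi`` exceeds the bound imposed by the binary margins.
    """
    if not (-1.0 < target_phi < 1.0):
        raise ConfigurationError(f"target_phi must be in (-1, 1), got {target_phi!r}")
    if target_phi == 0.0:
        return 0.0  # independence survives dichotomization
    hi = 1.0 - 1e-9
    phi_lo = _phi_of_latent(-hi, cut_a, cut_b)
    phi_hi = _phi_of_latent(hi, cut_a, cut_b)
    if not (phi_lo + tol < target_phi < phi_hi - tol):
        raise InfeasibleCorrelationError(target_phi, phi_lo, phi_hi)
    rho = brentq(
        lambda r: _phi_of_latent(r, cut_a, cut_b) - target_phi,
        -hi,
        hi,
        xtol=1e-12,
        maxiter=200,
    )
    assert abs(_phi_of_latent(rho, cut_a, cut_b) - target_phi) < tol
    return float(rho)


def _group_correlation(index_cut: float, target_phi: float) -> np.ndarray:
    """4x4 latent correlation for one group; index variable first."""
    try:
        r = solve_latent_correlation(target_phi, index_cut, 0.0)
    except InfeasibleCorrelationError as err:
        r = math.sin(math.pi * target_phi / 2.0)
        warnings.warn(
            f"phi={target_phi} unattainable for index cutpoint {index_cut:.3f} "
            f"(bounds {err.bounds[0]:.3f}..{err.bounds[1]:.3f}); falling back to "
            f"the median-split latent adjustment rho={r:.4f}",
            stacklevel=3,
        )
    s = solve_latent_correlation(target_phi, 0.0, 0.0)
    corr = np.array(
        [
            [1.0, r, r, r],
            [r, 1.0, s, s],
            [r, s, 1.0, s],
            [r, s, s, 1.0],
        ]
    )
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        warnings.warn(
            "latent correlation matrix not positive semi-definite; projecting "
            "to the nearest correlation matrix",
            stacklevel=3,
        )
        corr = corr_nearest(corr, threshold=1e-10)
        corr = (corr + corr.T) / 2.0
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("nearest-correlation repair failed")
    return corr


def build_latent_model(scenario: ScenarioSpec, target_phi: float = 0.4) -> LatentModel:
    """Construct the calibrated latent model for a scenario.

    The index cutpoint on the standardized latent scale is
    ``Phi^{-1}(spec)`` in the non-diseased group and ``Phi^{-1}(1 - sens)``
    in the diseased group; correlations are solved per group against that
    cutpoint (covariates are median splits, cutpoint 0).
    """
    mu_d = diseased_mean(scenario.true_sens, scenario.true_spec)
    cut_index = float(norm.ppf(scenario.true_spec))
    means_nd = np.array([0.0, *COVARIATE_MEANS])
    means_d = np.array([mu_d, *COVARIATE_MEANS])
    cutoffs = np.array([cut_index, *COVARIATE_MEANS])
    corr_nd = _group_correlation(cut_index, target_phi)
    corr_d = _group_correlation(cut_index - mu_d, target_phi)
    return LatentModel(
        mean_nondiseased=means_nd,
        mean_diseased=means_d,
        corr_nondiseased=corr_nd,
        corr_diseased=corr_d,
        cutoffs=cutoffs,
    )


def _chol_psd(corr: np.ndarray) -> np.ndarray:
    """Cholesky factor with a tiny diagonal jitter for PSD-but-singular input."""
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(corr.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
    raise ConfigurationError("correlation matrix is not positive semi-definite")


def generate_complete(
    scenario: ScenarioSpec, model: LatentModel, seed: int
) -> pd.DataFrame:
    """Draw one complete (pre-amputation) dataset.

    Exactly ``round(n * prevalence)`` diseased subjects are drawn from the
    diseased latent model and the rest from the non-diseased model
    (conditional-on-prevalence sampling); each latent variable is
    dichotomized at its cutoff with strict inequality (value > cutoff -> 1).
    Identical seeds give byte-identical tables.
    """
    n_d, n_nd = scenario.n_diseased, scenario.n_nondiseased
    if n_nd < 1:
        raise ConfigurationError("non-diseased group is empty for this scenario")
    rng = np.random.default_rng(seed)
    blocks = []
    for n_g, mean, corr in (
        (n_d, model.mean_diseased, model.corr_diseased),
        (n_nd, model.mean_nondiseased, model.corr_nondiseased),
    ):
        z = rng.standard_normal((n_g, 4))
        blocks.append(mean + z @ _chol_psd(corr).T)
    latent = np.vstack(blocks)
    binary = (latent > model.cutoffs).astype(np.int64)
    d = np.concatenate([np.ones(n_d, dtype=np.int64), np.zeros(n_nd, dtype=np.int64)])
    return pd.DataFrame(
        {
            "D": d,
            "Y": binary[:, 0],
            "X1": binary[:, 1],
            "X2": binary[:, 2],
            "X3": binary[:, 3],
        }
    )
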