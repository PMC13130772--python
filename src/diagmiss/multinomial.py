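"""Product-multinomial handlers for incomplete contingency tables.

A subject table with missing index-test values is equivalently a frequency
table with one cell per *full classification* (stratum x index result) plus
one cell per *partial classification* (stratum with the index result
missing), where a stratum is a combination of the reference standard and the
covariates.  Allocating each partial count across the two index-test levels
of its stratum is equivalent to imputation; the allocated ("pseudo-complete")
table is then analysed like complete data.

Three allocation rules are provided:

* ``ml_mar_allocate`` — maximum likelihood under MAR via EM for the saturated
  multinomial: the E-step splits each partial count proportionally to the
  current conditional probabilities P(Y | stratum), the M-step re-estimates
  the cell probabilities from the augmented counts.
* ``ml_mcar_allocate`` — the constrained EM with a single missingness
  probability shared by all strata.  For the saturated cell-probability
  model the mechanism likelihood factorizes out, so the allocation provably
  coincides with the MAR fit; the implementation still carries the
  constraint (and its parameter) through the iterations.
* ``wls_mcar_allocate`` — an iterated generalized-least-squares (minimum
  chi-square) fit of the 48-category product-multinomial proportion vector
  under MCAR, asymptotically equivalent to maximum likelihood.

Zero full-classification cells are replaced by a tiny frequency (1e-6 by
default) before EM, which otherwise sticks at the boundary.  A stratum with
partial counts but no complete counts leaves the conditional undefined and
raises :class:`HandlerFailure`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, HandlerFailure, IncompleteDataError
from .estimation import ConfusionCounts

__all__ = [
    "CatTable",
    "to_catdata",
    "substitute_zero_cells",
    "ml_mar_allocate",
    "ml_mcar_allocate",
    "mcar_missingness_rate",
    "wls_mcar_allocate",
    "from_catdata",
    "observed_loglik",
]

DEFAULT_STRATA = ("D", "X1", "X2", "X3")


@dataclass
class CatTable:
    """Frequency representation: ``full[s, y]`` counts complete rows of
    stratum ``s`` with index result ``y``; ``partial[s]`` counts rows of
    stratum ``s`` whose index result is missing."""

    stratum_cols: tuple[str, ...]
    strata: np.ndarray  # (S, k) binary stratum labels, lexicographic order
    full: np.ndarray  # (S, 2), column y
    partial: np.ndarray  # (S,)

    @property
    def n_total(self) -> float:
        return float(self.full.sum() + self.partial.sum())

    def copy(self) -> "CatTable":
        return CatTable(
            stratum_cols=self.stratum_cols,
            strata=self.strata.copy(),
            full=self.full.astype(float).copy(),
            partial=self.partial.astype(float).copy(),
        )


def to_catdata(
    table: pd.DataFrame, stratum_cols: tuple[str, ...] = DEFAULT_STRATA
) -> CatTable:
    """Tally a subject table (missing values in ``Y`` only) into a
    :class:`CatTable` over the full binary stratum grid."""
    k = len(stratum_cols)
    strata = np.array(list(itertools.product((0, 1), repeat=k)), dtype=np.int64)
    weights = 2 ** np.arange(k - 1, -1, -1)
    codes = (table[list(stratum_cols)].to_numpy(dtype=np.int64) * weights).sum(axis=1)
    y = table["Y"].to_numpy(dtype=float)
    missing = np.isnan(y)
    full = np.zeros((2**k, 2))
    partial = np.zeros(2**k)
    np.add.at(partial, codes[missing], 1.0)
    obs_codes = codes[~missing]
    obs_y = y[~missing].astype(np.int64)
    np.add.at(full, (obs_codes, obs_y), 1.0)
    return CatTable(stratum_cols=tuple(stratum_cols), strata=strata, full=full,
                    partial=partial)


def substitute_zero_cells(table: CatTable, epsilon: float = 1e-6) -> CatTable:
    """Replace zero full-classification cells by ``epsilon`` (partial cells
    untouched); returns a new table."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = table.copy()
    out.full[out.full == 0.0] = epsilon
    return out


def _check_allocatable(table: CatTable) -> None:
    # On a zero-substituted table every cell carries at least epsilon mass and
    # an empty stratum's partials are split 0.5/0.5; only a raw table with a
    # truly massless stratum cannot be allocated.
    bad = (table.partial > 0) & (table.full.sum(axis=1) == 0.0)
    if bad.any():
        labels = table.strata[bad].tolist()
        raise HandlerFailure(
            f"strata with partial but no complete counts: {labels}"
        )


def observed_loglik(full: np.ndarray, partial: np.ndarray, pi: np.ndarray) -> float:
    """Observed-data log-likelihood of cell probabilities ``pi`` under MAR."""
    ll = 0.0
    mask = full > 0
    ll += float(np.sum(full[mask] * np.log(pi[mask])))
    pi_s = pi.sum(axis=1)
    pmask = partial > 0
    ll += float(np.sum(partial[pmask] * np.log(pi_s[pmask])))
    return ll


def _em_allocate(
    table: CatTable,
    tol: float,
    max_iter: int,
    mcar: bool,
    loglik_trace: list | None,
) -> CatTable:
    out = table.copy()
    if out.partial.sum() == 0.0:
        return out
    _check_allocatable(out)
    n = out.n_total
    pi = out.full / out.full.sum()
    n_partial = out.partial.sum()
    for _ in range(max_iter):
        if loglik_trace is not None:
            ll = observed_loglik(out.full, out.partial, pi)
            if mcar:
                phi = n_partial / n  # MLE each M-step; constant across iterations
                ll += float(
                    (n - n_partial) * np.log1p(-phi) + n_partial * np.log(phi)
                )
            loglik_trace.append(ll)
        pi_s = pi.sum(axis=1, keepdims=True)
        cond = np.divide(pi, pi_s, out=np.full_like(pi, 0.5), where=pi_s > 0)
        aug = out.full + out.partial[:, None] * cond
        pi_new = aug / aug.sum()
        delta = float(np.max(np.abs(pi_new - pi)))
        pi = pi_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"EM did not reach tol={tol} within {max_iter} iterations "
            f"(last change {delta:.3e})"
        )
    pi_s = pi.sum(axis=1, keepdims=True)
    cond = np.divide(pi, pi_s, out=np.full_like(pi, 0.5), where=pi_s > 0)
    out.full = out.full + out.partial[:, None] * cond
    out.partial = np.zeros_like(out.partial)
    return out


def ml_mar_allocate(
    table: CatTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
    loglik_trace: list | None = None,
) -> CatTable:
    """EM allocation under MAR for the saturated multinomial.  The fixed
    point allocates ``partial(s) * full(y, s) / full_total(s)`` to each cell."""
    return _em_allocate(table, tol, max_iter, mcar=False, loglik_trace=loglik_trace)


def ml_mcar_allocate(
    table: CatTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
    loglik_trace: list | None = None,
) -> CatTable:
    """Constrained EM under MCAR (stratum-independent missingness
    probability); the allocation coincides with :func:`ml_mar_allocate`
    because the mechanism likelihood factorizes for the saturated model."""
    return _em_allocate(table, tol, max_iter, mcar=True, loglik_trace=loglik_trace)


def mcar_missingness_rate(table: CatTable) -> float:
    """MLE of the constant missingness probability: total partial / N."""
    n = table.n_total
    if n == 0:
        raise ValueError("empty table")
    return float(table.partial.sum() / n)


def wls_mcar_allocate(
    table: CatTable,
    ridge: float = 1e-10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CatTable:
    """Iterated GLS (minimum chi-square) fit under MCAR.

    The observation vector stacks the complete-pattern cell proportions and
    the partial-pattern stratum proportions; both are modeled through the
    cell probabilities ``pi`` and the observation probability ``alpha``
    (MCAR makes the partial-pattern proportions proportional to the stratum
    margins of ``pi``).  The weight matrix is the pseudo-inverse of the
    estimated product-multinomial covariance, re-evaluated each iteration;
    partial counts are then allocated from the fitted conditionals.
    """
    out = table.copy()
    if out.partial.sum() == 0.0:
        return out
    _check_allocatable(out)
    n = out.n_total
    s_count, two = out.full.shape
    c = s_count * two  # number of full cells
    member = np.zeros((s_count, c))  # stratum <- cell incidence
    for s in range(s_count):
        member[s, 2 * s] = member[s, 2 * s + 1] = 1.0
    p_obs = np.concatenate([out.full.reshape(-1) / n, out.partial / n])
    pi = (out.full / out.full.sum()).reshape(-1)
    alpha = float(out.full.sum() / n)
    free = np.eye(c)[:, :-1]
    free[-1, :] = -1.0  # d(pi)/d(free components), last cell = 1 - sum
    chi2_prev = np.inf
    for _ in range(max_iter):
        q = np.concatenate([alpha * pi, (1.0 - alpha) * (member @ pi)])
        v = (np.diag(q) - np.outer(q, q)) / n
        w = np.linalg.pinv(v + ridge * np.eye(v.shape[0]))
        j_pi = np.vstack([alpha * np.eye(c), (1.0 - alpha) * member]) @ free
        j_alpha = np.concatenate([pi, -(member @ pi)])[:, None]
        jac = np.hstack([j_pi, j_alpha])
        r = p_obs - q
        lhs = jac.T @ w @ jac + ridge * np.eye(jac.shape[1])
        try:
            delta = np.linalg.solve(lhs, jac.T @ w @ r)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular GLS weight system: {err}") from err
        pi_free = pi[:-1] + delta[:-1]
        pi_new = np.concatenate([pi_free, [1.0 - pi_free.sum()]])
        pi_new = np.clip(pi_new, 1e-12, None)
        pi_new = pi_new / pi_new.sum()
        alpha_new = float(np.clip(alpha + delta[-1], 1e-9, 1.0 - 1e-9))
        # measure actual movement after clipping: boundary cells may reject
        # part of a proposed step indefinitely, so also stop once the
        # weighted chi-square objective has stalled
        moved = max(float(np.max(np.abs(pi_new - pi))), abs(alpha_new - alpha))
        chi2 = float(r @ w @ r)
        pi, alpha = pi_new, alpha_new
        if moved < tol or abs(chi2 - chi2_prev) < 1e-9 * (1.0 + chi2):
            break
        chi2_prev = chi2
    else:
        raise ConvergenceError("iterated GLS did not converge")
    pi2 = pi.reshape(s_count, two)
    pi_s = pi2.sum(axis=1, keepdims=True)
    cond = np.divide(pi2, pi_s, out=np.full_like(pi2, 0.5), where=pi_s > 0)
    out.full = out.full + out.partial[:, None] * cond
    out.partial = np.zeros_like(out.partial)
    return out


def from_catdata(table: CatTable) -> ConfusionCounts:
    """Marginalize a pseudo-complete table to the 2x2 (D x Y) counts."""
    if float(np.abs(table.partial).sum()) > 1e-9:
        raise IncompleteDataError("table still contains partial counts")
    if "D" not in table.stratum_cols:
        raise ValueError("stratum columns must include the reference standard 'D'")
    d_col = table.stratum_cols.index("D")
    diseased = table.strata[:, d_col] == 1
    return ConfusionCounts(
        tp=float(table.full[diseased, 1].sum()),
        fn=float(table.full[diseased, 0].sum()),
        tn=float(table.full[~diseased, 0].sum()),
        fp=float(table.full[~diseased, 1].sum()),
    )
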