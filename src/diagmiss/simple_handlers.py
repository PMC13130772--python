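"""Non-model-based missing-data handlers.

* ``cca`` — complete case analysis: drop rows with a missing index test.
* ``worst_case`` — intention-to-diagnose coding: a missing result counts as a
  diagnostic error given the true condition (false negative if diseased,
  false positive if not), yielding a lower bound on both estimands.
* ``random_hot_deck`` — single imputation drawing each missing value uniformly
  (with replacement) from the observed index results in the same
  reference-standard group.

None of these handlers ever alters an observed value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import HandlerFailure

__all__ = ["cca", "worst_case", "random_hot_deck"]


def cca(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows with an observed index test, preserving row order.

    Raises :class:`HandlerFailure` when either reference group is left
    without a single complete case (that margin would be inestimable).
    """
    out = table[table["Y"].notna()].copy()
    for d in (0, 1):
        if ((table["D"] == d).any()) and not ((out["D"] == d).any()):
            raise HandlerFailure(f"no complete cases in reference group D={d}")
    return out


def worst_case(table: pd.DataFrame) -> pd.DataFrame:
    """Code each missing index result as a diagnostic error: false negative
    (Y=0) for diseased subjects, false positive (Y=1) for non-diseased."""
    out = table.copy()
    missing = out["Y"].isna()
    out.loc[missing & (out["D"] == 1), "Y"] = 0.0
    out.loc[missing & (out["D"] == 0), "Y"] = 1.0
    return out


def random_hot_deck(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Impute each missing index result with a uniformly random observed
    value from the same reference-standard group (donors drawn with
    replacement); deterministic under ``seed``."""
    out = table.copy()
    rng = np.random.default_rng(seed)
    for d in (0, 1):
        group = out["D"] == d
        recipients = group & out["Y"].isna()
        n_rec = int(recipients.sum())
        if n_rec == 0:
            continue
        donors = out.loc[group & out["Y"].notna(), "Y"].to_numpy()
        if donors.size == 0:
            raise HandlerFailure(f"no hot-deck donors in reference group D={d}")
        out.loc[recipients, "Y"] = rng.choice(donors, size=n_rec, replace=True)
    return out
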