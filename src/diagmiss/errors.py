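"""Exception hierarchy.

``HandlerFailure`` is the recoverable signal a missing-data handler raises when a
dataset is too degenerate for it (no complete cases in a reference group, a
donor-less hot-deck stratum, a stratum with partial but no complete counts, ...).
The study runner catches it and records a per-method failure flag; every other
exception is a genuine error and propagates.
"""


class DiagmissError(Exception):
    """Base class for all package errors."""


class HandlerFailure(DiagmissError):
    """A missing-data handler cannot produce a pseudo-complete dataset."""


class IncompleteDataError(DiagmissError):
    """An operation requiring complete data received missing values (state error)."""


class EstimationError(DiagmissError):
    """Sensitivity/specificity cannot be estimated (empty reference group)."""


class InfeasibleCorrelationError(DiagmissError):
    """The requested phi coefficient is outside the range attainable by
    dichotomizing a bivariate normal at the given cutpoints."""

    def __init__(self, target: float, lo: float, hi: float):
        self.target = target
        self.bounds = (lo, hi)
        super().__init__(
            f"target phi {target:.4f} outside attainable range "
            f"[{lo:.4f}, {hi:.4f}] for these cutpoints"
        )


class ConvergenceError(DiagmissError):
    """An iterative numerical routine failed to converge."""


class ConfigurationError(DiagmissError):
    """An invalid study or model configuration."""
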