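"""Exception hierarchy shared across the package."""


class GdmNmaError(Exception):
    """Base class for all package errors."""


class FormatError(GdmNmaError):
    """Input file is structurally malformed (missing columns, bad header)."""


class DataValidationError(GdmNmaError):
    """Input violates a data-model invariant; message names the offending row/study."""


class NonInformativeStudyError(GdmNmaError):
    """Study carries no information for an odds ratio (zero events, or all
    events, in every arm). Such studies are excluded from the pairwise
    contrast but retained for the arm-based Bayesian likelihood."""


class DisconnectedNetworkError(GdmNmaError):
    """Treatment network is disconnected where a connected one is required."""


class UnsupportedInputError(GdmNmaError):
    """Summary statistics insufficient for the requested conversion."""


class ConvergenceWarning(UserWarning):
    """MCMC chains did not pass the PSRF threshold; results carry a warning."""
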