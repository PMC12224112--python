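"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, FitError -> 3.
"""


class HgidaError(Exception):
    """Base class for all package errors."""


class ValidationError(HgidaError, ValueError):
    """Invalid user input (negative concentration, missing column, ...)."""


class DegenerateDataError(HgidaError, ValueError):
    """Data carry no information about the requested parameters."""


class FitError(HgidaError, RuntimeError):
    """Nonlinear fit failed to converge from every start."""


class InternalConsistencyError(HgidaError, RuntimeError):
    """A solver produced no physically admissible root; should be unreachable."""


class RangeError(HgidaError, OverflowError):
    """A conversion would overflow (e.g. exp(-dG/RT) with |dG|/RT > 700)."""
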