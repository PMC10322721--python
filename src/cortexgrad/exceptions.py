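"""Exception hierarchy shared across the pipeline.

``DataError`` marks invalid *content* (non-monotone standards, all-missing
cells); ``ParameterError`` marks invalid *arguments*; ``NumericalError``
marks a computation that degenerated (singular covariance, rank-0 matrix).
The CLI maps DataError to exit code 2 and ParameterError to exit code 3.
"""


class CortexGradError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CortexGradError, ValueError):
    """An argument violates a precondition."""


class DataError(CortexGradError, ValueError):
    """Input data are structurally valid but unusable."""


class NumericalError(CortexGradError, ArithmeticError):
    """A numerical routine degenerated (singular matrix, rank collapse)."""
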