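"""Exception hierarchy shared across the package."""


class PyrocosmError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PyrocosmError, ValueError):
    """A configuration or parameter value violates its invariants.

    The message names the offending field.
    """


class DataError(PyrocosmError, ValueError):
    """Input data are missing, empty, or structurally invalid."""


class DegenerateDataError(DataError):
    """Data are structurally valid but carry no statistical information
    (e.g. zero variance in both samples, a zero marginal total)."""


class NumericalError(PyrocosmError, RuntimeError):
    """The solver produced a non-finite value; the message names the
    first offending time step."""
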