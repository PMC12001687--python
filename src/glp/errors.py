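"""Exception hierarchy shared across the package.

Errors are split by cause so the command-line wrapper can map them to
distinct exit codes: problems locating/opening inputs (:class:`InputError`),
inputs that open but violate a contract (:class:`ValidationError`), and
numerical failures of the fitting machinery (:class:`NumericalError`).
"""


class GLPError(Exception):
    """Base class for all errors raised by this package."""


class InputError(GLPError):
    """A required input file or directory is missing or unreadable."""


class ValidationError(GLPError):
    """An input or parameter violates a documented precondition."""


class NumericalError(GLPError):
    """A numerical procedure failed (singular/degenerate fit)."""


class DegenerateFitError(NumericalError):
    """A smoother interpolated the data exactly (RSS = 0); BIC is undefined."""
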