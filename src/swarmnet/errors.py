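"""Exception hierarchy shared across the pipeline.

Validation problems (bad input files, out-of-range values, degenerate
requests) raise :class:`ValidationError`; model fitting problems raise
:class:`ConvergenceError`.  The CLI maps these to exit codes 2 and 3.
"""


class SwarmnetError(Exception):
    """Base class for all package errors."""


class ValidationError(SwarmnetError):
    """Invalid input data or parameters."""


class SchemaError(ValidationError):
    """A required column is missing or a file is structurally malformed."""


class ConvergenceError(SwarmnetError):
    """A model fit failed to converge.

    Carries optional diagnostics (gradient norm, iteration count).
    """

    def __init__(self, message, *, grad_norm=None, n_iter=None):
        super().__init__(message)
        self.grad_norm = grad_norm
        self.n_iter = n_iter
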