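"""Exception hierarchy shared by all rfspace modules."""


class RFSpaceError(Exception):
    """Base class for all rfspace errors."""


class ParameterError(RFSpaceError, ValueError):
    """Invalid parameter value (non-positive scale, indefinite covariance, ...)."""


class UnsupportedOrderError(ParameterError):
    """Derivative order beyond the supported range."""


class SizeError(RFSpaceError, ValueError):
    """Kernel does not fit the image it is applied to."""


class DomainError(RFSpaceError, ValueError):
    """Point or window falls outside the valid image domain."""


class SelectionError(RFSpaceError, RuntimeError):
    """No extremum found during scale selection.

    Carries the sampled signature for diagnostics.
    """

    def __init__(self, message, signature=None):
        super().__init__(message)
        self.signature = signature


class ConvergenceError(RFSpaceError, RuntimeError):
    """Iterative adaptation failed to converge; carries the residual trace."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class DegeneracyError(RFSpaceError, RuntimeError):
    """Rank-deficient measurement (aperture problem, flat patch)."""


class FormatError(RFSpaceError, ValueError):
    """Unsupported or inconsistent file format / sequence numbering."""
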