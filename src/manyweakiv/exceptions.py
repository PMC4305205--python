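"""Typed errors raised across the package."""


class ManyWeakIVError(Exception):
    """Base class for all package errors."""


class DataValidationError(ManyWeakIVError):
    """Input data violates a structural requirement (shapes, codes, missingness)."""


class DegenerateDesignError(ManyWeakIVError):
    """Design matrices are rank deficient (singular X'X, collinear instruments, ...)."""


class NumericalDegeneracyError(ManyWeakIVError):
    """A numerically meaningless quantity was produced (negative variance,
    complex eigenvalue beyond tolerance, ...)."""


class NotOveridentifiedError(ManyWeakIVError):
    """An overidentification test was requested for a just-identified model."""


class UndefinedBiasError(ManyWeakIVError):
    """A weak-instrument bias approximation is undefined (zero concentration)."""
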