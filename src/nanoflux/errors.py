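"""Exception hierarchy shared across the package.

All nanoflux errors derive from :class:`NanofluxError` so callers can catch
one base class; the subclasses distinguish bad inputs from configuration
mistakes, out-of-regime requests and numerical failures.
"""


class NanofluxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NanofluxError, ValueError):
    """A physical quantity violates its domain (non-positive size, etc.)."""


class OutOfRegimeError(NanofluxError, ValueError):
    """A model was asked to operate outside its validity range."""


class ConfigurationError(NanofluxError, ValueError):
    """A mesh/solver/CLI configuration is internally inconsistent."""


class NumericalFailureError(NanofluxError, RuntimeError):
    """A solver failed to converge; the message carries diagnostics."""


class DataQualityError(NanofluxError, ValueError):
    """Experimental records violate a physical constraint (e.g. outlet > inlet)."""


class GenerationError(NanofluxError, ValueError):
    """A synthetic-data trend produced non-physical values."""
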