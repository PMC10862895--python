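"""Exception hierarchy shared across the package.

Every error raised on a contract violation derives from
:class:`SwitchscopeError` so callers can catch package failures with a
single ``except`` clause while still discriminating the cause.
"""

from __future__ import annotations


class SwitchscopeError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(SwitchscopeError, ValueError):
    """A generator/analysis spec field violates its invariant.

    Parameters
    ----------
    field
        Name of the offending field; always present so error messages
        name the field that failed validation.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid field {field!r}: {message}")


class InputError(SwitchscopeError, ValueError):
    """Input data fails a structural precondition (length, ordering, NaNs)."""


class NoTransitionError(SwitchscopeError):
    """Melting signal shows no resolvable unfolding transition."""


class NoSignalError(SwitchscopeError):
    """Kinetic trace amplitude is indistinguishable from noise."""


class NormalizationError(SwitchscopeError):
    """Fingerprint normalization is undefined (reference signal absent/non-positive)."""


class ConfigurationError(SwitchscopeError):
    """User-supplied configuration is internally inconsistent."""


class ConstructionError(SwitchscopeError):
    """A synthetic trajectory schedule cannot be realized.

    Carries the list of irreconcilable schedule entries in ``conflicts``.
    """

    def __init__(self, message: str, conflicts: list | None = None):
        self.conflicts = conflicts or []
        super().__init__(message)


class AggregationError(SwitchscopeError):
    """Replica/fit aggregation is impossible (no usable inputs, key mismatch)."""


class MergeError(SwitchscopeError):
    """Conflicting stage outputs for the same variant cannot be merged."""
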