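"""Exception hierarchy.

All package errors derive from :class:`KonioError` so callers can catch one
base class; the concrete classes also subclass the matching builtin.
"""


class KonioError(Exception):
    """Base class for all koniolearn errors."""


class DomainError(KonioError, ValueError):
    """A value lies outside its mathematically valid domain."""


class DimensionError(KonioError, ValueError):
    """Array arguments have incompatible shapes or lengths."""


class NotFittedError(KonioError, RuntimeError):
    """An estimator was used before being fitted."""


class SchemaError(KonioError, ValueError):
    """A configuration or serialized model failed validation."""
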