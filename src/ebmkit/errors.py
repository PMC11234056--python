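"""Exception hierarchy.

Structural validation never raises -- :func:`ebmkit.model.validate_resource`
returns issue lists.  Exceptions are reserved for unusable inputs (malformed
JSON, unknown resource types, undefined statistical measures and the like).
"""


class EbmKitError(Exception):
    """Base class for all package errors."""


class UnknownResourceTypeError(EbmKitError):
    """A resourceType discriminator that this package does not model."""


class UnsupportedElementError(EbmKitError):
    """An element not in the supported set, encountered in strict mode."""


class MalformedDocumentError(EbmKitError):
    """Input text that is not well-formed JSON / tagged-record syntax."""


class BundleError(EbmKitError):
    """Bundle-level problems: duplicate ids, unresolvable references."""


class SerializationError(EbmKitError):
    """Refusal to write a resource that does not validate."""

    def __init__(self, message, issues=()):
        super().__init__(message)
        self.issues = list(issues)


class TerminologyError(EbmKitError):
    """Code-system / value-set problems (unregistered system, cycle)."""


class UndefinedMeasureError(EbmKitError):
    """A contingency table on which the requested measure is undefined."""


class EstimateError(EbmKitError):
    """A Statistic from which no effect estimate can be recovered."""


class SynthesisError(EbmKitError):
    """Pooling preconditions violated (mixed measures, missing dispersion)."""


class ConversionError(EbmKitError):
    """A bibliographic record that cannot become a Citation."""
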