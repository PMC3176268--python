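"""Exception hierarchy.

Invariant *violations* in user data are reported as data (see
:class:`kefed.model.ValidationReport`); exceptions are reserved for
malformed documents, unresolvable references and misconfiguration.
"""


class KefedError(Exception):
    """Base class for all errors raised by this package."""


class DocumentParseError(KefedError):
    """A document does not conform to the expected structure.

    ``location`` is a JSON-pointer for JSON documents or a
    human-readable cell/line address for tabular ones.
    """

    def __init__(self, message: str, location: str = ""):
        self.location = location
        super().__init__(f"{message} (at {location})" if location else message)


class ExtentParseError(DocumentParseError):
    """A region-extent mini-expression could not be parsed."""


class UnknownNodeError(KefedError):
    """A node id does not resolve within a model."""


class NodeKindError(KefedError):
    """A node has the wrong kind for the requested operation."""


class ModelValidationError(KefedError):
    """An operation that requires a valid model received an invalid one."""

    def __init__(self, report):
        self.report = report
        lines = "; ".join(v.message for v in report)
        super().__init__(f"model is invalid: {lines}")


class ModelMismatchError(KefedError):
    """A table references a different model than the one supplied."""


class UnknownRegionError(KefedError):
    """A region abbreviation does not resolve within an atlas."""


class AtlasIntegrityError(KefedError):
    """An atlas violates its structural invariants (e.g. containment cycle)."""


class DomainError(KefedError):
    """A value lies outside its declared value domain."""


class TracerConfigError(KefedError):
    """A tracer chemical is not registered with a transport direction."""


class GeneratorParameterError(KefedError):
    """A synthetic-corpus generator received degenerate knobs."""
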