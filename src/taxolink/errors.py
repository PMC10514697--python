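"""Exception hierarchy shared across the package."""


class TaxolinkError(Exception):
    """Base class for all taxolink errors."""


class MalformedIdentifierError(TaxolinkError, ValueError):
    """An identifier string does not conform to its syntax."""


class EmptySetError(TaxolinkError, ValueError):
    """An operation requiring a non-empty identifier set received an empty one."""


class ParseFailureError(TaxolinkError, ValueError):
    """A microcitation string matched none of the known citation patterns.

    Carries the raw string so callers can log or audit the failure.
    """

    def __init__(self, raw: str, message: str = "could not parse microcitation"):
        super().__init__(f"{message}: {raw!r}")
        self.raw = raw


class MissingFieldError(TaxolinkError, ValueError):
    """A record lacks fields required by the requested operation."""

    def __init__(self, fields, message: str = "missing required fields"):
        self.fields = tuple(fields)
        super().__init__(f"{message}: {', '.join(self.fields)}")


class DuplicateWorkIdError(TaxolinkError, ValueError):
    """Two works in one bibliography share a work_id."""


class NoIdentifierError(TaxolinkError, ValueError):
    """A work has no persistent identifier from which to derive a reference id."""


class DanglingWorkError(TaxolinkError, KeyError):
    """A mapping entry points at a work_id absent from the bibliography."""


class ReferentialIntegrityError(TaxolinkError, ValueError):
    """A checklist name row cites a reference id missing from the reference table."""


class NoDoiError(TaxolinkError, ValueError):
    """RDF export was requested for a work without a DOI."""


class PersonRejected(TaxolinkError, ValueError):
    """A person record could not be salvaged during cleaning.

    ``reason`` is a short machine-readable code: ``bad-orcid`` or ``empty-record``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class InvalidSpecError(TaxolinkError, ValueError):
    """A synthetic corpus specification is out of range."""
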