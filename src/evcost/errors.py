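"""Exception hierarchy for evcost."""


class EVCostError(Exception):
    """Base class for all evcost errors."""


class DomainError(EVCostError):
    """A value violates a model precondition (non-positive workload, zero population, ...).

    Deliberately not a ``ValueError`` subclass so that pydantic validators can
    raise it and have it propagate to the caller unwrapped.
    """


class SchemaError(EVCostError):
    """An input file or record set violates the documented schema.

    ``details`` carries one human-readable finding per offending row/field.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        self.details = details or []
        if self.details:
            message = message + "\n  - " + "\n  - ".join(self.details)
        super().__init__(message)
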