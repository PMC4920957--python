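"""Exception types shared across the package."""


class CorpusFormatError(ValueError):
    """A corpus record is malformed (missing field, bad timestamp, ...)."""

    def __init__(self, message: str, *, line: int | None = None, field: str | None = None):
        detail = message
        if line is not None:
            detail = f"line {line}: {detail}"
        if field is not None:
            detail = f"{detail} (field: {field})"
        super().__init__(detail)
        self.line = line
        self.field = field


class DuplicateIdError(ValueError):
    """Two records in one corpus share an id."""

    def __init__(self, record_id: str, line: int | None = None):
        where = f" at line {line}" if line is not None else ""
        super().__init__(f"duplicate record id {record_id!r}{where}")
        self.record_id = record_id


class EmptyVocabularyError(ValueError):
    """Document-frequency pruning removed every candidate term."""


class NoSignalError(RuntimeError):
    """The (residual) matrix is identically zero; no component can be extracted."""


class RowRemovalError(ValueError):
    """A document row was removed twice (or was already empty)."""


class SynthSpecError(ValueError):
    """A synthetic-corpus specification field is invalid."""

    def __init__(self, field: str, message: str):
        super().__init__(f"invalid SynthSpec.{field}: {message}")
        self.field = field
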