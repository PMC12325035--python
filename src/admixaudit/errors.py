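"""Exception hierarchy.

Grouped so the CLI can map classes of failure to distinct exit codes:
configuration problems (2), data/format problems (3), stage failures (4).
"""


class AdmixAuditError(Exception):
    """Base class for all package errors."""


class ParameterError(AdmixAuditError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class ConfigError(AdmixAuditError, ValueError):
    """A run configuration failed schema or semantic validation."""


class SchemaError(AdmixAuditError, ValueError):
    """Input data violates a structural contract (dosage values, ancestry labels, columns)."""


class DataError(AdmixAuditError, ValueError):
    """Input data is structurally valid but unusable (empty table, zero-size group)."""


class ParseError(AdmixAuditError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class EmptyPanelError(DataError):
    """Array ascertainment produced an empty variant panel."""
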