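"""Exception taxonomy.

Three families so callers (and the CLI exit codes) can distinguish bad
parameters, bad data, and internal faults.
"""


class HrvPartError(Exception):
    """Base class for all package errors."""


class ParameterError(HrvPartError, ValueError):
    """A caller-supplied parameter violates its documented constraints."""


class DataQualityError(HrvPartError, RuntimeError):
    """Input data failed a quality gate (e.g. too many beats removed)."""


class ParseError(HrvPartError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class SubjectMismatchError(HrvPartError, ValueError):
    """Two per-subject objects that must belong together do not."""
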