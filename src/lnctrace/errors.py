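"""Exception hierarchy shared across the pipeline.

Config errors, data/validation errors and computation errors are kept
distinct so the CLI can map them to distinct exit codes.
"""


class LnctraceError(Exception):
    """Base class for all package errors."""


class ParseError(LnctraceError):
    """A file could not be parsed (malformed line, bad field count...)."""


class ValidationError(LnctraceError):
    """Parsed data violates an invariant (duplicate ids, negative counts...)."""


class ReconciliationError(ValidationError):
    """Two inputs that must describe the same entities disagree."""


class ConfigError(LnctraceError):
    """Invalid configuration or parameters."""


class ContrastError(LnctraceError):
    """A requested contrast cannot be formed from the available samples."""


class CapacityError(LnctraceError):
    """Simulated genome too small for the requested annotation."""
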