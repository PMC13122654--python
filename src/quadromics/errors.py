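"""Exception hierarchy.

Validation/configuration/format problems (user-correctable) are distinct from
pipeline/runtime failures so the CLI can map them to exit code 2 vs 1.
"""


class QuadromicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuadromicsError):
    """Invalid parameter or configuration value."""


class ValidationError(QuadromicsError):
    """Input data violates a documented contract."""


class FormatError(QuadromicsError):
    """A file is structurally malformed."""


class PipelineError(QuadromicsError):
    """A pipeline stage cannot proceed (e.g. empty result after filtering)."""
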