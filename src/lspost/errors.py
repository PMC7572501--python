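"""Exception hierarchy shared across the package."""


class LspostError(Exception):
    """Base class for user-facing errors raised by this package."""


class StackIOError(LspostError):
    """Raised for unreadable, inconsistent, or unsupported stack inputs."""


class ConfigError(LspostError):
    """Raised for malformed or invalid pipeline configuration documents."""


class FilterError(LspostError):
    """Raised for invalid frequency-filter specifications or applications."""


class PipelineError(LspostError):
    """Raised for invalid stage combinations or orchestration failures."""
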