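"""Exception hierarchy used across the package.

Validation failures raise subclasses of :class:`QeegError` so callers
(and the CLI, which maps them to exit code 2) can distinguish bad input
from genuine runtime failures.
"""


class QeegError(Exception):
    """Base class for all qeegconn errors."""


class InputError(QeegError):
    """A file is missing or unreadable."""


class FormatError(QeegError):
    """A file was read but its contents violate the expected format."""


class ParameterError(QeegError):
    """An argument violates a precondition (band edges, window sizes...)."""


class TooShortError(ParameterError):
    """The recording is too short for the requested filter."""


class EmptyResultError(QeegError):
    """An operation produced nothing (e.g. every epoch was rejected)."""


class DegenerateChannelError(QeegError):
    """A channel is constant / zero-variance where variance is required."""


class DegeneracyError(QeegError):
    """A regression design is singular (e.g. duplicated channels)."""


class InstabilityError(QeegError):
    """No stable autoregressive model could be fitted."""


class MissingChannelError(QeegError):
    """A scalp region has none of its channels present."""


class LabelError(QeegError):
    """A group or channel label is unknown or unmappable."""


class ContractError(QeegError):
    """Two objects that must agree (metric, band, nodes) do not."""


class StabilityError(QeegError):
    """A synthetic coupling graph implies an unstable process."""


class ConfigError(QeegError):
    """A run configuration failed validation."""
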