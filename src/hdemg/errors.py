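"""Exception hierarchy for the hdemg package.

All errors raised by the library derive from :class:`HDEMGError` so callers
(and the CLI) can distinguish configuration problems, malformed data, and
analysis failures from programming errors.
"""


class HDEMGError(Exception):
    """Base class for all hdemg errors."""


class ParameterError(HDEMGError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(HDEMGError, ValueError):
    """A study configuration value is out of its documented range."""


class FormatError(HDEMGError, ValueError):
    """A file or bundle is malformed; the message names the offending field."""


class SegmentationError(HDEMGError, RuntimeError):
    """Onset detection found fewer (or ill-formed) activity bursts than expected."""

    def __init__(self, message: str, n_found: int | None = None):
        super().__init__(message)
        self.n_found = n_found


class UnrecoverableChannelError(HDEMGError, RuntimeError):
    """A faulty channel has no non-faulty neighbors to interpolate from."""


class ZeroVarianceError(HDEMGError, ValueError):
    """A heatmap with zero variance makes a Pearson correlation undefined."""


class UndefinedCOGError(HDEMGError, ValueError):
    """Center of gravity is undefined (all-zero heatmap)."""
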