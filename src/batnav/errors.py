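"""Exception types raised across the package."""


class BatnavError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BatnavError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class GenerationError(BatnavError, RuntimeError):
    """A stochastic generator could not satisfy its constraints."""


class ProtocolError(BatnavError, ValueError):
    """An acquisition protocol is inconsistent with the route it is applied to."""


class SplitError(BatnavError, ValueError):
    """A train/test split violates its declared spatial-separation contract."""


class PlacementError(BatnavError, RuntimeError):
    """Off-route probe placement failed within the retry budget."""


class TrainingError(BatnavError, RuntimeError):
    """Training diverged (non-finite loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class SimulationError(BatnavError, RuntimeError):
    """The closed-loop simulator received a non-finite estimate."""


class CoverageError(BatnavError, ValueError):
    """Probe views do not cover the circle at the required gaze spacing."""
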