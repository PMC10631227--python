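"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ClimDamageError` so callers (and
the CLI) can distinguish bad user input from internal failures.
"""


class ClimDamageError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ClimDamageError, ValueError):
    """An argument violates a documented precondition."""


class InvalidCalibrationError(ClimDamageError, ValueError):
    """Generator or emulator hyperparameters are outside their support."""


class FormatError(ClimDamageError, ValueError):
    """An on-disk artifact does not match its documented schema."""


class InvalidStateError(ClimDamageError, RuntimeError):
    """An operation was applied to an object in the wrong state
    (e.g. rebaselining a trajectory twice)."""


class ConfigurationError(ClimDamageError, ValueError):
    """A run configuration references unknown sectors, variants or inputs."""


class DegenerateConsumptionError(ClimDamageError, ValueError):
    """Per-capita consumption became non-positive; Ramsey growth is
    undefined for the affected scenario."""
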