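"""Exception hierarchy used across the package."""


class SonosegError(Exception):
    """Base class for package errors."""


class ConfigurationError(SonosegError, ValueError):
    """Invalid configuration value or unknown option."""


class GeometryError(SonosegError, ValueError):
    """Degenerate or out-of-bounds geometry (zero-length needle, oversized blob)."""


class ShapeError(SonosegError, ValueError):
    """Array shape violates a contract (names the offending axis/stage)."""


class EmptyMaskError(SonosegError, ValueError):
    """An operation that needs foreground pixels received an empty mask."""


class UndefinedMetricError(SonosegError, ValueError):
    """A metric is mathematically undefined for the given inputs.

    Reported as a per-sample failure by the evaluator, never as 0.
    """


class CheckpointError(SonosegError, RuntimeError):
    """Unreadable, version-incompatible or digest-mismatched checkpoint."""


class IncompatibleCheckpointError(CheckpointError):
    """Reference-weight mapping failed (shape mismatch), lists the key."""


class DivergenceError(SonosegError, RuntimeError):
    """Training produced a non-finite loss or gradient."""
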