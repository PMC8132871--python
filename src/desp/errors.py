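"""Exception hierarchy shared across the package."""


class DespError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(DespError):
    """Degenerate geometry: zero-length bond vector or collinear atom triple."""


class UndefinedAngleError(DespError):
    """Both cos and sin components of a feature pair are (numerically) zero."""


class ShapeError(DespError):
    """Array dimensions inconsistent with the operation's contract."""


class ConfigurationError(DespError):
    """An invalid configuration value or combination of values."""


class TrainingDivergedError(DespError):
    """Non-finite loss encountered during optimization."""


class CheckpointError(DespError):
    """A run checkpoint is missing, incomplete, or inconsistent."""


class AdapterError(DespError):
    """A dynamics-engine adapter violated its contract."""
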