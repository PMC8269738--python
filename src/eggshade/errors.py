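"""Exception hierarchy shared across the pipeline."""


class EggshadeError(Exception):
    """Base class for all pipeline errors."""


class DomainError(EggshadeError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class GeometryError(EggshadeError, ValueError):
    """Regions or scene elements do not fit the image geometry."""


class CalibrationError(EggshadeError, ValueError):
    """Grey-standard normalization cannot be performed."""


class DataError(EggshadeError, ValueError):
    """A table or pixel set is empty, incomplete, or too small."""


class ShapeError(EggshadeError, ValueError):
    """Array shapes or feature lengths are incompatible."""


class ConfigError(EggshadeError, ValueError):
    """Invalid configuration value."""
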