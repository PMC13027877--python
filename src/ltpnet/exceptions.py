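"""Error taxonomy shared across the package."""


class ConfigurationError(ValueError):
    """A block/model/training configuration violates its contract."""


class ShapeError(ValueError):
    """Array extents incompatible with the requested operation."""


class InputError(ValueError):
    """Malformed user-supplied input (files, masks, image sizes)."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given confusion counts."""


class GenerationError(RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""
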