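"""Exception hierarchy shared by all pipeline stages."""


class AtlasError(Exception):
    """Base class for all errors raised by this package."""


class GeometryError(AtlasError):
    """Grids that should share shape/spacing do not."""


class DimensionalityError(AtlasError):
    """A volume that should be 3D is not."""


class ConfigError(AtlasError):
    """A parameter is outside its documented domain."""


class ValidationError(AtlasError):
    """A file or object failed an integrity check on load."""


class RegistrationError(AtlasError):
    """Registration cannot proceed (degenerate input, no overlap)."""

    def __init__(self, message, best_transform=None):
        super().__init__(message)
        self.best_transform = best_transform


class TrainingError(AtlasError):
    """Classifier training preconditions violated."""


class DiagnosticError(AtlasError):
    """A diagnostic (e.g. imprint curve) cannot be computed."""


class MeshError(AtlasError):
    """Mesh extraction or comparison failed."""
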