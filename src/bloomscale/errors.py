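"""Exception hierarchy for the bloomscale pipeline."""


class BloomscaleError(Exception):
    """Base class for all bloomscale errors."""


class TilingError(BloomscaleError):
    """Requested tile grid cannot be laid out on the image."""


class MaskShapeError(BloomscaleError):
    """Mask dimensions do not match the image or each other."""


class ParameterError(BloomscaleError):
    """A parameter is outside its valid range."""


class BackendError(BloomscaleError):
    """A segmentation backend failed or violated its contract."""

    def __init__(self, backend_id: str, message: str):
        self.backend_id = backend_id
        super().__init__(f"backend {backend_id!r}: {message}")


class ReferenceNotDetectedError(BloomscaleError):
    """No reference-object pixels were found; the image has no scale."""


class UndefinedIoUError(BloomscaleError):
    """IoU of two empty masks is undefined."""


class DegenerateRegressionError(BloomscaleError):
    """Regression is undefined (fewer than two points or constant regressor)."""


class SchemaError(BloomscaleError):
    """A table does not conform to the evaluation schema."""


class PlacementError(BloomscaleError):
    """Synthetic scene objects could not be placed inside the canvas."""
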