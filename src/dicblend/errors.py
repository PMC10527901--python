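"""Exception hierarchy for dicblend."""


class DicblendError(Exception):
    """Base class for all dicblend errors."""


class SchemaError(DicblendError):
    """A dataset file does not have the required columns."""


class DatasetValidationError(DicblendError):
    """A dataset row violates an invariant (e.g. fraction outside [0, 1])."""


class RoiBoundsError(DicblendError):
    """A region of interest does not lie fully inside the image."""


class ImageFormatError(DicblendError):
    """The raster does not provide at least three color channels."""


class DegenerateBlankError(DicblendError):
    """A blank measurement cannot serve as a white reference.

    Raised when the blank's theoretical illuminance is non-positive (the
    blank is not a plausible white patch) or a blank channel is ~0 and a
    ratio correction would divide by it.
    """

    def __init__(self, message: str, sample_id: str | None = None):
        super().__init__(message)
        self.sample_id = sample_id


class SingularDesignError(DicblendError):
    """The descriptor matrix is rank deficient; OLS has no unique solution."""
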