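"""Exception hierarchy for the dermfractal pipeline."""


class DermFractalError(Exception):
    """Base class for all dermfractal errors."""


class IngestError(DermFractalError):
    """An input image could not be read or decoded."""


class DegenerateImageError(DermFractalError):
    """An image has no separable intensity classes (e.g. constant intensity)."""


class EmptyMaskError(DermFractalError):
    """A binary mask contains no foreground pixels."""


class VocabularyError(DermFractalError):
    """A diagnosis label is outside the controlled vocabulary."""


class InsufficientDataError(DermFractalError):
    """A statistical comparison was requested on too few records."""


class DegenerateInputError(DermFractalError):
    """A numerical input is degenerate (e.g. a zero-variance feature column)."""
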