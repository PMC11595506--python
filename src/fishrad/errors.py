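"""Exception hierarchy for the fishrad pipeline."""


class FishradError(Exception):
    """Base class for all fishrad errors."""


class LoadError(FishradError):
    """An image or mask file could not be read."""


class FormatError(FishradError):
    """Unsupported file format or extension."""


class AlignmentError(FishradError):
    """Mask and image grids do not match."""


class EmptyMaskError(FishradError):
    """A mask contains no foreground pixels."""


class DegenerateMaskError(FishradError):
    """A mask vanished under resampling/resizing."""


class NormalizationError(FishradError):
    """Intensity normalization is undefined (zero variance)."""


class MergeError(FishradError):
    """Two studies cannot be merged because extraction settings differ."""


class PairingError(FishradError):
    """Two feature tables cannot be paired (mismatched keys or features)."""


class LabelError(FishradError):
    """Class labels are unusable (e.g. a class is absent)."""


class PhantomError(FishradError):
    """A phantom specification is geometrically invalid."""


class StudyError(FishradError):
    """A study manifest is invalid or inconsistent."""
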