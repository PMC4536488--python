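"""Exception hierarchy for the codeit package."""


class CodeitError(Exception):
    """Base class for all codeit-specific errors."""


class ImageIOError(CodeitError):
    """A stack or mosaic could not be read or written."""


class MissingVoxelSizeError(ImageIOError):
    """Voxel-size metadata is absent and no override was supplied.

    Voxel size is mandatory input: every volume filter of the method is
    expressed in micrometres, so a stack without physical calibration
    cannot be quantified. It is never silently defaulted.
    """


class MissingChannelError(ImageIOError):
    """A required channel role (nuclei, membrane, did) is not mapped."""


class UnsupportedBitDepthError(CodeitError):
    """Intensity scale is not one of the supported bit depths."""


class SegmentationError(CodeitError):
    """Segmentation could not produce a usable cell partition."""


class NoMarkersError(SegmentationError):
    """No nucleus markers were found; the stack is rejected."""


class MultipleDonorsError(CodeitError):
    """Two or more donor components map to different segmented cells.

    Doublets and groups of donor cells are excluded from analysis because
    transfer could not be attributed to a single donor.
    """


class InvalidSpecError(CodeitError):
    """A synthetic-data specification violates its invariants."""


class StatisticsError(CodeitError):
    """A statistical routine received unusable input."""
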