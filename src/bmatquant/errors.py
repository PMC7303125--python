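"""Exception hierarchy.

Every error raised by the package derives from :class:`BmatQuantError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class BmatQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BmatQuantError, ValueError):
    """Invalid configuration or generator/model parameters."""


class VolumeIOError(BmatQuantError, IOError):
    """Failure reading or writing a volume or mask file."""


class AlignmentError(BmatQuantError, ValueError):
    """Volume and mask are not on the same voxel grid."""


class RegionLookupError(BmatQuantError, KeyError):
    """A named region is absent from a mask (or an age/sex band from a table)."""


class EmptyRegionError(BmatQuantError, ValueError):
    """A region exists but contains no voxels (or a sample is empty)."""
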