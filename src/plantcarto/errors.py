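"""Exception hierarchy for the cartography pipeline.

Every stage raises a subclass of :class:`CartoError` so the CLI can abort
with the stage name and a single human-readable cause.
"""


class CartoError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CartoError):
    """A file does not parse as the named dialect; message names the first
    offending element or record."""


class EmptyRunError(FormatError):
    """An LC-MS run contains no MS1 scans."""


class EmptyLibraryError(FormatError):
    """A spectral library file yields zero valid records."""


class EmptyMeshError(FormatError):
    """An STL file contains no facets."""


class ValidationError(CartoError):
    """Input data violates a documented invariant (duplicate ids, missing
    metadata, coordinates outside the mesh, ...)."""


class DegenerateSampleError(ValidationError):
    """A sample column is all-zero and cannot be normalized."""


class LevelError(ValidationError):
    """An operation received a spectrum of the wrong MS level."""


class ParameterError(CartoError):
    """A configuration parameter is outside its valid range."""
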