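"""Exception hierarchy.

Every error raised by the library derives from :class:`TrackQueryError` so
callers (and the REST layer) can distinguish library failures from bugs.
"""


class TrackQueryError(Exception):
    """Base class for all trackquery errors."""


# --- resource / byte-range access -------------------------------------------

class ResourceUnavailable(TrackQueryError):
    """A local path does not exist or a URL is unreachable."""


class RangesUnsupported(TrackQueryError):
    """A remote server does not honor HTTP Range requests."""


class OutOfRange(TrackQueryError):
    """A byte-range read extends past the end of the resource."""


class SerializationError(TrackQueryError):
    """A serialized file-object stream is corrupt or version-mismatched."""


# --- format parsing ----------------------------------------------------------

class UnrecognizedFormat(TrackQueryError):
    """Magic number matches no supported format."""


class CorruptHeader(TrackQueryError):
    """A file header is structurally invalid."""


class CorruptIndex(TrackQueryError):
    """A B+ tree / R-tree / Tabix index is structurally invalid."""


class CorruptBlock(TrackQueryError):
    """A data block fails to decompress or decode."""


class InvalidOffset(TrackQueryError):
    """A BGZF virtual offset is out of its packing range."""


# --- catalog / query ---------------------------------------------------------

class UnknownChromosome(TrackQueryError):
    """Queried chromosome is absent from the file's index."""


class UnknownMeasurement(TrackQueryError):
    """Measurement id not registered in the catalog."""


class UnknownGene(TrackQueryError):
    """Gene name absent from a genome annotation."""


class DuplicateId(TrackQueryError):
    """Measurement id already registered."""


class ConfigError(TrackQueryError):
    """Malformed configuration or manifest entry."""


# --- computed measurements ---------------------------------------------------

class OverlapWithinSource(TrackQueryError):
    """A single source track has internally overlapping records."""


class ComputeError(TrackQueryError):
    """A user-supplied transformation function raised."""


class ShapeError(TrackQueryError):
    """A transformation output violates its declared arity."""


# --- fixtures ----------------------------------------------------------------

class GenerationError(TrackQueryError):
    """Synthetic track generation failed."""
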