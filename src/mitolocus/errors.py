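"""Exception hierarchy for the package."""


class MitolocusError(Exception):
    """Base class for all package errors."""


class AlignmentError(MitolocusError):
    """Sequences of unequal length, or an operation on an invalid alignment."""


class InputError(MitolocusError):
    """Malformed input: duplicate ids, non-IUPAC symbols, bad schema."""


class BoundsError(MitolocusError):
    """Coordinate range outside the sequence, or an invalid range."""


class SaturationError(MitolocusError):
    """K2P correction undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


class UndefinedDistanceError(MitolocusError):
    """Distance undefined, e.g. empty site subset or zero site count."""


class TaxonomyError(MitolocusError):
    """Sample id unresolvable in the taxonomy table."""


class TreeError(MitolocusError):
    """Invalid tree input or unknown leaf label."""


class ConfigError(MitolocusError):
    """Invalid simulation or pipeline configuration."""
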