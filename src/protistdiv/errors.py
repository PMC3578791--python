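"""Exception hierarchy shared across the package."""


class ProtistDivError(Exception):
    """Base class for all package-specific errors."""


class InputError(ProtistDivError):
    """Malformed or inconsistent user input (files, names, parameters)."""


class AlignmentError(ProtistDivError):
    """Rows of an alignment violate the equal-length invariant."""


class RegionError(ProtistDivError):
    """A requested region is invalid or a primer cannot be located."""


class UndefinedDistanceError(ProtistDivError):
    """A pairwise distance cannot be computed (no comparable sites)."""


class SaturationError(UndefinedDistanceError):
    """Observed divergence at or beyond the Jukes-Cantor domain bound (p >= 3/4)."""


class MonophylyError(ProtistDivError):
    """A set of tips expected to be monophyletic is not."""


class DegenerateFitError(ProtistDivError):
    """A regression or statistic is undefined for the given data."""
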