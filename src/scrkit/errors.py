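"""Exception types shared across the package."""


class ScrkitError(Exception):
    """Base class for all package-specific errors."""


class MalformedSequenceError(ScrkitError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""

    def __init__(self, position: int, char: str):
        self.position = position
        self.char = char
        super().__init__(f"non-nucleotide character {char!r} at position {position}")


class AmbiguousSequenceError(ScrkitError):
    """Translation was requested over a region containing ambiguity codes."""


class FrameError(ScrkitError):
    """A region length is not a multiple of the codon size."""


class TopologyIncompleteError(ScrkitError):
    """Fewer than two downstream in-frame stop codons were found.

    Carries whatever stops were found so callers can report partial topology.
    """

    def __init__(self, stops_found):
        self.stops_found = list(stops_found)
        super().__init__(
            f"need 2 downstream in-frame stops, found {len(self.stops_found)}"
        )


class InsufficientDataError(ScrkitError):
    """Not enough observations to compute the requested statistic."""


class DegenerateReplicateError(ScrkitError):
    """A normalizing measurement (e.g. RLuc, I538) is zero."""


class InvalidControlError(ScrkitError):
    """A control value makes the efficiency denominator non-positive."""


class ParseError(ScrkitError):
    """A structured input file is malformed; message carries the location."""


class ConfigError(ScrkitError):
    """Unknown or invalid run-configuration key."""
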