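"""Exception hierarchy for mapfp.

All library errors derive from :class:`MapFPError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class MapFPError(Exception):
    """Base class for all mapfp errors."""


class ParseError(MapFPError):
    """The SMILES string could not be parsed or sanitized."""


class EmptyMoleculeError(MapFPError):
    """The molecule contains no heavy atoms."""


class DisconnectedError(MapFPError):
    """Multi-fragment input where a connected molecule is required."""


class TooSmallError(MapFPError):
    """The molecule (or shingle set) is too small for the operation."""


class EmptySetError(MapFPError):
    """MinHashing requires at least one shingle."""


class ConfigMismatchError(MapFPError):
    """Two fingerprints were computed under incompatible configurations."""


class FormatError(MapFPError):
    """A substructure string does not start with an atom token."""


class TooManyCentersError(MapFPError):
    """Combinatorial stereo enumeration beyond the safety guard."""


class TooFewActivesError(MapFPError):
    """A benchmark set does not contain enough actives for the query protocol."""


class MissingSetError(MapFPError):
    """Rank aggregation requires every fingerprint to cover the same sets."""
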