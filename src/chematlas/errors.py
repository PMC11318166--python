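"""Exception hierarchy shared across chematlas modules."""


class ChemAtlasError(Exception):
    """Base class for all chematlas errors."""


class NoStructureColumnError(ChemAtlasError):
    """No CSV column parses as SMILES at a sufficient rate."""


class AmbiguousColumnError(ChemAtlasError):
    """Two or more columns tie for the same role and no tie rule resolves them."""


class InvalidMoleculeError(ChemAtlasError):
    """An operation requiring a valid structure was given an invalid record."""


class ConfigError(ChemAtlasError):
    """A training or run configuration violates its invariants."""


class ModelFormatError(ChemAtlasError):
    """A model file is corrupted, truncated, or of an unsupported version."""
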