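"""Exception hierarchy shared across the package."""


class CambindError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CambindError):
    """A structure or table file could not be parsed."""


class CompositionError(CambindError):
    """Models of an ensemble do not share an identical atom composition."""


class SelectionError(CambindError):
    """An atom selection is empty or refers to absent residues."""


class PairingError(CambindError):
    """Two coordinate sets cannot be paired atom-by-atom."""


class DegeneracyError(CambindError):
    """Too few or geometrically degenerate points for the operation."""


class FormatError(CambindError):
    """A delimited input table lacks the required columns."""
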