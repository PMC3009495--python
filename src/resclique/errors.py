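"""Exception hierarchy for resclique.

All errors raised by the library derive from :class:`RescliqueError`, so CLI
code can catch a single type and exit nonzero with the message.
"""


class RescliqueError(Exception):
    """Base class for all resclique errors."""


class ParseError(RescliqueError):
    """PDB text could not be parsed (empty input, malformed record, ...)."""


class NoCoordinatesError(ParseError):
    """Input contained no parseable ATOM/HETATM coordinates."""


class ChainNotFoundError(RescliqueError):
    """A requested chain id is absent from the selected model."""


class ModelNotFoundError(RescliqueError):
    """A requested model index is absent from the structure."""


class EmptySelectionError(RescliqueError):
    """Site selection or graph construction produced nothing to work on."""


class InvalidWindowError(RescliqueError):
    """Distance window violates 0 <= d_lo < d_hi."""


class UnknownEdgeError(RescliqueError):
    """An edge was queried that is not present in the contact graph."""


class AnchorError(RescliqueError):
    """Anchor specification invalid (too many anchors, duplicates, ...)."""


class AnchorNotFoundError(AnchorError):
    """An anchor residue key does not resolve to a site in the graph."""


class InvalidResidueTypeError(RescliqueError):
    """An amino-acid type code is not a recognised 3-letter code."""


class PackingError(RescliqueError):
    """Random packing could not satisfy the minimum-separation constraint."""
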