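"""Exception hierarchy for specdelim."""


class SpecDelimError(Exception):
    """Base class for all specdelim errors."""


class FormatError(SpecDelimError):
    """A file violates its declared external format (duplicate IDs, bad fields...)."""


class AlignmentError(SpecDelimError):
    """An alignment violates its invariants (ragged rows, zero length...)."""


class MatrixError(SpecDelimError):
    """A distance matrix violates its invariants (asymmetry, nonzero diagonal...)."""


class MaskError(SpecDelimError):
    """A column-exclusion mask is invalid for its alignment."""


class TreeError(SpecDelimError):
    """A phylogenetic tree is unusable for the requested operation."""


class ClusteringError(SpecDelimError):
    """Clustering or agreement scoring received degenerate input."""
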