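"""Exception hierarchy.

Everything user-facing derives from :class:`EcrscanError` so the CLI can map
any anticipated failure to exit code 2 with a readable message.
"""


class EcrscanError(Exception):
    """Base class for all anticipated errors."""


class FastaFormatError(EcrscanError):
    """Malformed or empty FASTA input."""


class SequenceAlphabetError(EcrscanError):
    """A residue outside the accepted alphabet (20 amino acids, 'X', '-')."""


class NewickParseError(EcrscanError):
    """Malformed Newick text; carries a character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)
        self.offset = offset


class PairingError(EcrscanError):
    """Sequence identifiers and tree leaf labels do not match."""


class EmptyAlignmentError(EcrscanError):
    """Gap filtering removed every column."""


class TreeStructureError(EcrscanError):
    """Invalid tree topology (e.g. an internal node with a single child)."""


class DistanceError(EcrscanError):
    """A sequence pair shares no residue-bearing columns."""


class MatrixError(EcrscanError):
    """Invalid substitution-frequency table."""


class DegenerateProfileError(EcrscanError):
    """The alignment is perfectly conserved; no relative rates exist."""


class AnnotationError(EcrscanError):
    """Invalid residue annotation table."""
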