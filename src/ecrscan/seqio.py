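"""FASTA / Newick input and identifier validation.

Sequences must arrive pre-aligned (equal lengths including gaps); alignment
itself is out of scope — use any standard aligner (MAFFT, Clustal, T-Coffee)
upstream.  Identifiers are the FASTA header up to the first whitespace, and
must match tree leaf labels exactly when a phylogeny is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import FastaFormatError, SequenceAlphabetError
from .phylo import RootedTree, parse_newick  # noqa: F401  (re-exported)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: Residue alphabet: the 20 amino acids, 'X' for unknown, '-' for a gap.
ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "read_newick",
    "PairingReport",
    "validate_pairing",
    "AMINO_ACIDS",
    "ALPHABET",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned protein sequence: an identifier and its residue string."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise FastaFormatError("sequence with empty identifier")
        bad = [(i, c) for i, c in enumerate(self.residues, start=1)
               if c not in ALPHABET]
        if bad:
            pos, char = bad[0]
            raise SequenceAlphabetError(
                f"record {self.id!r}: character {char!r} at position {pos} is "
                "not an amino acid, 'X' or '-'"
            )

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.residues if c != "-")


def _as_handle(source):
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return open(source), True
    if isinstance(source, str):
        import io

        return io.StringIO(source), True
    return source, False


def read_fasta(source) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, path, or text into records.

    Residues are uppercased; the identifier is the header token before the
    first whitespace.  Order is preserved.
    """
    handle, close = _as_handle(source)
    try:
        records = []
        seen = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"duplicate sequence identifier {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper()))
    except ValueError as exc:  # Biopython: content before the first '>'
        raise FastaFormatError(f"not valid FASTA: {exc}") from exc
    finally:
        if close:
            handle.close()
    if not records:
        raise FastaFormatError("no FASTA records found in input")
    return records


def write_fasta(records, dest, width: int = 60) -> None:
    """Write records as wrapped FASTA (UTF-8)."""

    def dump(handle):
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            dump(handle)
    else:
        dump(dest)


def read_newick(source) -> RootedTree:
    """Read a Newick tree from a path or string."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    return parse_newick(text)


@dataclass(frozen=True)
class PairingReport:
    """Outcome of matching sequence ids against tree leaf labels."""

    ok: bool
    leaves_without_sequence: tuple[str, ...] = ()
    sequences_without_leaf: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.ok:
            return "sequence identifiers and tree leaves match"
        parts = []
        if self.leaves_without_sequence:
            parts.append(
                "tree leaves without a sequence: "
                + ", ".join(self.leaves_without_sequence)
            )
        if self.sequences_without_leaf:
            parts.append(
                "sequences without a tree leaf: "
                + ", ".join(self.sequences_without_leaf)
            )
        return "; ".join(parts)


def validate_pairing(records, tree: RootedTree) -> PairingReport:
    """Check that sequence ids and tree leaf labels are the same set."""
    ids = {r.id for r in records}
    leaves = set(tree.leaf_labels())
    return PairingReport(
        ok=ids == leaves,
        leaves_without_sequence=tuple(sorted(leaves - ids)),
        sequences_without_leaf=tuple(sorted(ids - leaves)),
    )
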