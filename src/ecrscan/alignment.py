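"""Gap-column filtering and the three coordinate tracks.

The pipeline works in three coordinate systems, all 1-based inclusive:

* **raw aligned index** — column number in the input alignment;
* **filtered aligned index** — column number after gap-heavy columns are
  removed (a column is dropped when *more than* a threshold fraction of the
  sequences — default 50% — have a gap there);
* **reference protein index** — residue number in the ungapped reference
  (focal) sequence, undefined where the reference has a gap.

'X' counts as a residue, not a gap, for the filter: the rule is purely about
gap content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyAlignmentError, FastaFormatError
from .seqio import SequenceRecord

__all__ = ["MultipleAlignment", "FilteredAlignment", "filter_gap_columns",
           "map_to_reference"]


@dataclass
class MultipleAlignment:
    """Aligned homolog sequences plus the identifier of the focal sequence."""

    records: list[SequenceRecord]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise FastaFormatError("alignment with no sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise FastaFormatError(
                "sequences are not aligned: lengths "
                + ", ".join(f"{r.id}={len(r.residues)}" for r in self.records)
            )
        self.length = lengths.pop()
        if self.length < 1:
            raise FastaFormatError("zero-length alignment")
        ids = [r.id for r in self.records]
        if self.reference_id not in ids:
            raise FastaFormatError(
                f"reference {self.reference_id!r} not among sequence ids"
            )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def reference(self) -> SequenceRecord:
        return next(r for r in self.records if r.id == self.reference_id)

    def to_array(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])


@dataclass
class FilteredAlignment:
    """An alignment after column removal, with coordinate tracks.

    ``kept_columns`` holds the 1-based raw indexes of surviving columns in
    increasing order; ``reference_index[k]`` is the 1-based reference residue
    number at filtered column k+1, or None where the reference is gapped.
    """

    alignment: MultipleAlignment
    kept_columns: list[int]
    raw: MultipleAlignment = field(repr=False, default=None)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.kept_columns, self.kept_columns[1:])):
            raise ValueError("kept_columns must be strictly increasing")
        self.length = len(self.kept_columns)
        self.raw_index = list(self.kept_columns)
        self.filtered_index = list(range(1, self.length + 1))
        ref = self.alignment.reference.residues
        self.reference_index: list[int | None] = []
        count = 0
        # residue numbering counts reference residues in RAW coordinates so
        # that numbers survive column filtering
        raw_ref = (self.raw or self.alignment).reference.residues
        raw_numbers = {}
        for raw_col, ch in enumerate(raw_ref, start=1):
            if ch != "-":
                count += 1
                raw_numbers[raw_col] = count
        for k, raw_col in enumerate(self.kept_columns):
            if ref[k] != "-":
                self.reference_index.append(raw_numbers[raw_col])
            else:
                self.reference_index.append(None)

    @property
    def reference_length(self) -> int:
        return (self.raw or self.alignment).reference.ungapped_length


def filter_gap_columns(aln: MultipleAlignment, threshold: float = 0.5) -> FilteredAlignment:
    """Drop columns whose gap fraction strictly exceeds ``threshold``.

    The denominator is the total number of aligned sequences.  A column with
    a gap fraction exactly equal to the threshold is retained ("more than").
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    arr = aln.to_array()
    gap_fraction = (arr == "-").mean(axis=0)
    keep = gap_fraction <= threshold
    if not keep.any():
        raise EmptyAlignmentError(
            f"every column exceeds the {threshold:.0%} gap threshold; "
            "rerun with a looser --gap-threshold"
        )
    kept_cols = [int(i) + 1 for i in np.flatnonzero(keep)]
    filtered_records = [
        SequenceRecord(id=r.id, residues="".join(arr[i, keep]))
        for i, r in enumerate(aln.records)
    ]
    filtered_aln = MultipleAlignment(records=filtered_records,
                                     reference_id=aln.reference_id)
    return FilteredAlignment(alignment=filtered_aln, kept_columns=kept_cols,
                             raw=aln)


def map_to_reference(filtered: FilteredAlignment, filtered_col: int) -> int | None:
    """Reference residue number at a 1-based filtered column (None on a gap)."""
    if not 1 <= filtered_col <= filtered.length:
        raise IndexError(
            f"filtered column {filtered_col} outside 1..{filtered.length}"
        )
    return filtered.reference_index[filtered_col - 1]
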