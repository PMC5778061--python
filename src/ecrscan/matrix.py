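"""Ancestor-to-child node substitution scores from BLOSUM62 target frequencies.

The package ships the BLOSUM62 clustered target-frequency (qij) table from
the NCBI blocks repository: the joint amino-acid pair frequencies underlying
the BLOSUM62 log-odds matrix.  Scores are built by conditioning on the
ancestor: each row of the ordered-pair frequency table (off-diagonal mass
split between the two directions) is normalised to sum to 1 (giving
substitution frequencies F_S, with the self entry F_SS), and the node
substitution score is

    NSS(a, b) = 1 - F_S(a -> b) / F_SS(a)

so that NSS is 0 for self-substitution, grows with the rarity of the
exchange, and approaches (never attains) 1 for exchanges that are never
observed.  Conditioning on the ancestor corrects for amino-acid abundance
and makes the matrix directional: NSS(a, b) != NSS(b, a) in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import MatrixError
from .seqio import AMINO_ACIDS

__all__ = ["TargetFrequencyTable", "NssMatrix", "load_qij", "build_nss",
           "rarity_order", "nss_to_tsv"]

_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class TargetFrequencyTable:
    """Symmetric 20x20 table of BLOSUM62 target frequencies.

    Off-diagonal entries are ordered-pair frequencies, so the full matrix
    (diagonal once, each off-diagonal cell once) sums to 1 up to the printed
    precision of the source file.
    """

    q: np.ndarray
    amino_acids: str = AMINO_ACIDS

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (20, 20):
            raise MatrixError(f"expected a 20x20 table, got {q.shape}")
        if not (q > 0).all():
            raise MatrixError("target frequencies must all be positive")
        if not np.allclose(q, q.T, rtol=0, atol=1e-12):
            raise MatrixError("target-frequency table must be symmetric")
        object.__setattr__(self, "q", q)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.q[_INDEX[a], _INDEX[b]])


@dataclass(frozen=True)
class NssMatrix:
    """20x20 node substitution scores indexed [ancestor][child].

    ``row_freq`` holds the per-ancestor normalised frequencies F_S (each row
    sums to 1); the diagonal of ``nss`` is exactly 0 and every off-diagonal
    entry lies strictly in (0, 1).
    """

    nss: np.ndarray
    row_freq: np.ndarray
    amino_acids: str = AMINO_ACIDS

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.nss[_INDEX[a], _INDEX[b]])

    def score(self, ancestor: str, child: str) -> float:
        return self[ancestor, child]

    @property
    def index(self) -> dict[str, int]:
        return dict(_INDEX)


def load_qij(path: str | Path | None = None) -> TargetFrequencyTable:
    """Read a blocks-repository qij file (lower triangle, '#' comments).

    With no argument, loads the BLOSUM62 table shipped with the package.
    """
    if path is None:
        source = resources.files("ecrscan").joinpath("data", "blosum62.qij")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows: list[list[float]] = []
    order: str | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if all(len(f) == 1 and f.isalpha() for f in fields):
            order = "".join(fields)
            continue
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise MatrixError(f"unparseable qij line: {line!r}") from exc
    if len(rows) != 20:
        raise MatrixError(f"expected 20 triangular rows, found {len(rows)}")
    if order is not None and order != AMINO_ACIDS:
        raise MatrixError(
            f"unexpected amino-acid order {order!r}; expected {AMINO_ACIDS!r}"
        )
    q = np.zeros((20, 20))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise MatrixError(
                f"triangular row {i + 1} has {len(row)} entries, expected {i + 1}"
            )
        for j, value in enumerate(row):
            q[i, j] = q[j, i] = value
    return TargetFrequencyTable(q=q)


def build_nss(table: TargetFrequencyTable) -> NssMatrix:
    """Row-normalise the directional frequencies and apply NSS = 1 - F_S/F_SS.

    An off-diagonal entry of the target-frequency table is the mass of an
    unordered pair and therefore covers both substitution directions; the
    frequency of the ordered event "ancestor a, child b" is q(a,b)/2 for
    a != b and q(a,a) on the diagonal.  Conditioning on the ancestor row of
    that ordered-pair distribution keeps every self-substitution the most
    frequent event in its row, so scores stay within [0, 1) with 0 exactly
    on the diagonal.  (Normalising the raw symmetrised rows instead would
    push NSS(M, L) below zero, because Met->Leu exchanges outnumber
    Met->Met conservation in the underlying block data.)
    """
    q = table.q
    directional = q / 2.0
    np.fill_diagonal(directional, np.diag(q))
    row_freq = directional / directional.sum(axis=1, keepdims=True)
    fss = np.diag(row_freq)
    nss = 1.0 - row_freq / fss[:, None]
    # 1 - x/x is exactly 0 in IEEE arithmetic, but keep the contract explicit
    np.fill_diagonal(nss, 0.0)
    return NssMatrix(nss=nss, row_freq=row_freq, amino_acids=table.amino_acids)


def rarity_order(matrix: NssMatrix, ancestor: str) -> list[str]:
    """Children sorted by ascending score (commonest exchange first).

    The ancestor itself always sorts first (score 0); ties, which cannot
    occur with distinct frequencies, would fall back to alphabetical order.
    """
    row = matrix.nss[_INDEX[ancestor]]
    return [a for _, a in sorted(zip(row, matrix.amino_acids))]


def nss_to_tsv(matrix: NssMatrix) -> str:
    """Render the matrix as TSV (rows = ancestor, columns = child)."""
    lines = ["ancestor\t" + "\t".join(matrix.amino_acids)]
    for i, a in enumerate(matrix.amino_acids):
        lines.append(
            a + "\t" + "\t".join(f"{matrix.nss[i, j]:.10f}" for j in range(20))
        )
    return "\n".join(lines) + "\n"
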