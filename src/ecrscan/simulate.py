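"""Synthetic ortholog families with known constraint structure.

The simulator draws an ancestral protein from the BLOSUM62 amino-acid
frequencies and evolves it down a (given or Yule-sampled) tree.  Each site
mutates on each branch with probability ``baseline`` times the site's rate
multiplier; constrained blocks carry a multiplier below 1, so they accumulate
fewer substitutions.  Replacements are drawn from the row-normalised
BLOSUM62 conditional frequencies excluding self, i.e. common exchanges are
simulated as common.  Optional geometric-length deletions add gap realism so
the gap-column filter is exercised; insertions are not modelled, which keeps
ancestral coordinates identical to alignment coordinates.

This is a validation harness, not a phylogenetic simulator: mutation is a
per-branch Bernoulli trial per site (no branch lengths, no rate
heterogeneity beyond the block multipliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import build_nss, load_qij
from .phylo import RootedTree, TreeNode
from .seqio import AMINO_ACIDS, SequenceRecord, write_fasta

__all__ = ["SimulationConfig", "SimulatedFamily", "simulate_family",
           "sample_yule_tree", "write_family"]

#: Default constrained blocks: three 20-column blocks, evenly spaced over a
#: 300-column protein, at one fifth of the background substitution rate.
DEFAULT_BLOCKS = ((51, 70, 0.2), (141, 160, 0.2), (231, 250, 0.2))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated ortholog family.

    ``baseline`` is the per-branch, per-site substitution probability for
    unconstrained sites; blocks are (start, end, rate_multiplier) with
    1-based inclusive ancestral coordinates and multiplier in [0, 1).
    """

    n_leaves: int = 12
    sequence_length: int = 300
    baseline: float = 0.08
    blocks: tuple[tuple[int, int, float], ...] = DEFAULT_BLOCKS
    indel_prob: float = 0.01
    indel_mean_length: float = 4.0
    tree: RootedTree | None = None
    seed: int = 0

    def __post_init__(self):
        last_end = 0
        for start, end, mult in sorted(self.blocks):
            if not (1 <= start <= end <= self.sequence_length):
                raise ValueError(
                    f"block {start}..{end} outside 1..{self.sequence_length}"
                )
            if start <= last_end:
                raise ValueError("constrained blocks must not overlap")
            if not (0 <= mult < 1):
                raise ValueError("rate multiplier must be in [0, 1)")
            last_end = end
        if not (0 <= self.baseline <= 1):
            raise ValueError("baseline must be a probability")


@dataclass
class SimulatedFamily:
    """A simulated family plus its ground truth."""

    records: list[SequenceRecord]
    tree: RootedTree
    blocks: tuple[tuple[int, int, float], ...]
    ancestral: str
    site_multiplier: np.ndarray
    #: substitutions per site realised along the whole tree (true history)
    site_changes: np.ndarray
    config: SimulationConfig

    def leaf_blocks(self) -> dict[str, list[tuple[int, int, float]]]:
        """Truth blocks in per-leaf ungapped coordinates (clipped by
        deletions; a block fully deleted in a leaf is omitted for it)."""
        out: dict[str, list[tuple[int, int, float]]] = {}
        for rec in self.records:
            cum = np.cumsum([c != "-" for c in rec.residues])
            blocks = []
            for start, end, mult in self.blocks:
                n_before = int(cum[start - 2]) if start > 1 else 0
                n_through = int(cum[end - 1])
                if n_through > n_before:
                    blocks.append((n_before + 1, n_through, mult))
            out[rec.id] = blocks
        return out


def sample_yule_tree(n_leaves: int, rng: np.random.Generator) -> RootedTree:
    """Pure-birth topology: split a uniformly chosen leaf until n_leaves.

    Branch lengths are set to 1 (the mutation model is length-free).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    root = TreeNode(length=None)
    leaves = []
    for _ in range(2):
        leaves.append(root.add_child(TreeNode(length=1.0)))
    while len(leaves) < n_leaves:
        chosen = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            leaves.append(chosen.add_child(TreeNode(length=1.0)))
    # deterministic left-to-right leaf naming
    tree = RootedTree(root)
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"taxon{i}"
    return tree


def _site_multipliers(config: SimulationConfig) -> np.ndarray:
    mult = np.ones(config.sequence_length)
    for start, end, m in config.blocks:
        mult[start - 1:end] = m
    return mult


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Run one simulation; the same config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree or sample_yule_tree(config.n_leaves, rng)

    table = load_qij()
    nss = build_nss(table)
    marginals = table.q.sum(axis=1)
    marginals = marginals / marginals.sum()
    conditional = nss.row_freq.copy()
    np.fill_diagonal(conditional, 0.0)
    conditional /= conditional.sum(axis=1, keepdims=True)

    length = config.sequence_length
    mult = _site_multipliers(config)
    ancestral = rng.choice(20, size=length, p=marginals)

    site_changes = np.zeros(length, dtype=int)
    states: dict[TreeNode, np.ndarray] = {tree.root: ancestral}
    for node in tree.preorder():
        if node is tree.root:
            continue
        seq = states[node.parent].copy()
        hits = np.flatnonzero(rng.random(length) < config.baseline * mult)
        for site in hits:
            seq[site] = rng.choice(20, p=conditional[seq[site]])
            site_changes[site] += 1
        states[node] = seq

    records = []
    for leaf in tree.leaves():
        chars = [AMINO_ACIDS[i] for i in states[leaf]]
        if config.indel_prob > 0:
            starts = np.flatnonzero(rng.random(length) < config.indel_prob)
            for start in starts:
                gap_len = 1 + rng.geometric(1.0 / config.indel_mean_length)
                chars[start:start + gap_len] = ["-"] * len(chars[start:start + gap_len])
        records.append(SequenceRecord(id=leaf.label, residues="".join(chars)))

    return SimulatedFamily(
        records=records, tree=tree, blocks=tuple(config.blocks),
        ancestral="".join(AMINO_ACIDS[i] for i in ancestral),
        site_multiplier=mult, site_changes=site_changes, config=config,
    )


def write_family(family: SimulatedFamily, outdir, stem: str = "family") -> dict[str, str]:
    """Write FASTA + Newick + truth-block TSV (1-based inclusive)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fasta"
    write_fasta(family.records, fasta)
    newick = outdir / f"{stem}.nwk"
    newick.write_text(family.tree.to_newick() + "\n")
    truth = outdir / f"{stem}.truth_blocks.tsv"
    with open(truth, "w") as fh:
        fh.write("sequence\tstart\tend\trate_multiplier\n")
        for start, end, mult in family.blocks:
            fh.write(f"ancestral\t{start}\t{end}\t{mult:g}\n")
        for leaf, blocks in family.leaf_blocks().items():
            for start, end, mult in blocks:
                fh.write(f"{leaf}\t{start}\t{end}\t{mult:g}\n")
    return {"fasta": str(fasta), "newick": str(newick), "truth": str(truth)}
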