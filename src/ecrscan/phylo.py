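"""Rooted trees for ancestral reconstruction.

A minimal parent/child node structure is used for the per-column dynamic
programming; dendropy handles Newick parsing/serialisation and
neighbor-joining when no user tree is supplied.  Branch lengths are parsed
and retained, but the scoring procedure is length-free: only the topology
matters downstream.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DistanceError, NewickParseError, TreeStructureError

__all__ = [
    "TreeNode",
    "RootedTree",
    "parse_newick",
    "build_guide_tree",
    "resolve_polytomies",
]


@dataclass(eq=False)
class TreeNode:
    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class RootedTree:
    """A rooted tree whose leaves carry sequence identifiers.

    Internal nodes get deterministic generated labels (``node1`` ... in
    postorder) unless the source Newick named them.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._label_internals()

    def _label_internals(self) -> None:
        counter = itertools.count(1)
        for node in self.postorder():
            if not node.is_leaf and not node.label:
                node.label = f"node{next(counter)}"

    def postorder(self):
        """Yield nodes children-first (the order bottom-up passes need)."""
        stack = [(self.root, False)]
        while stack:
            node, visited = stack.pop()
            if visited:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self):
        """Yield (parent, child) pairs."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self.postorder() if not n.is_leaf)

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeStructureError(f"duplicate leaf labels: {', '.join(dupes)}")
        for node in self.postorder():
            if not node.is_leaf and len(node.children) == 1:
                raise TreeStructureError(
                    f"internal node {node.label!r} has a single child"
                )
            if node.is_leaf and not node.label:
                raise TreeStructureError("leaf without a label")

    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                out = node.label or ""
            else:
                out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if include_lengths and node.length is not None:
                out += f":{node.length:g}"
            return out

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return RootedTree(convert(dtree.seed_node))


def parse_newick(text: str) -> RootedTree:
    """Parse a rooted Newick string into a :class:`RootedTree`.

    Raises :class:`NewickParseError` for unbalanced parentheses, a missing
    terminating ';', or empty leaf labels, with a character offset where it
    can be localised.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick input", offset=0)
    if not stripped.endswith(";"):
        raise NewickParseError("Newick tree must end with ';'", offset=len(text) - 1)
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=pos)
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis",
                               offset=len(text) - 1)
    # empty leaf label: a '(' or ',' immediately followed by a separator
    bare = stripped
    for pos in range(len(bare) - 1):
        if bare[pos] in "(," and bare[pos + 1] in ",)":
            raise NewickParseError("empty leaf label", offset=pos + 1)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    tree.validate()
    return tree


def p_distance_matrix(records) -> np.ndarray:
    """Pairwise p-distances: mismatch fraction over columns where both
    sequences carry a residue (gaps and 'X' excluded).

    Raises :class:`DistanceError` if a pair shares no residue columns.
    """
    arr = np.array([list(r.residues) for r in records])
    informative = (arr != "-") & (arr != "X")
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = informative[i] & informative[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise DistanceError(
                    f"sequences {records[i].id!r} and {records[j].id!r} share "
                    "no residue-bearing columns; cannot compute a distance"
                )
            mism = int((arr[i][shared] != arr[j][shared]).sum())
            dist[i, j] = dist[j, i] = mism / n_shared
    return dist


def build_guide_tree(records) -> RootedTree:
    """Neighbor-joining on p-distances, midpoint-rooted.

    Used when the caller supplies no phylogeny.  Deterministic for a given
    input order.  Negative NJ branch lengths are clamped to zero before
    midpoint rooting.
    """
    if len(records) < 2:
        raise TreeStructureError("a guide tree needs at least 2 sequences")
    dist = p_distance_matrix(records)
    ids = [r.id for r in records]
    if len(records) == 2:
        root = TreeNode()
        half = dist[0, 1] / 2
        root.add_child(TreeNode(label=ids[0], length=half))
        root.add_child(TreeNode(label=ids[1], length=half))
        return RootedTree(root)

    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i, name in enumerate(ids):
        buf.write(name + "," + ",".join(f"{dist[i, j]:.12g}" for j in range(len(ids))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, is_first_row_column_names=True, is_first_column_row_names=True,
        delimiter=",",
    )
    njt = pdm.nj_tree()
    for edge in njt.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if max(dist.max(), 0.0) > 0.0:
        njt.reroot_at_midpoint(update_bipartitions=False)
    njt.suppress_unifurcations()
    tree = _from_dendropy(njt)
    _canonicalize(tree)
    tree.validate()
    return tree


def _canonicalize(tree: RootedTree) -> None:
    """Sort every node's children by smallest descendant leaf label.

    dendropy's NJ emits siblings in hash order; a canonical order makes
    guide-tree serialisation a pure function of the input (scoring itself is
    child-order-free).
    """
    smallest: dict[TreeNode, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            smallest[node] = node.label or ""
        else:
            node.children.sort(key=lambda c: smallest[c])
            smallest[node] = smallest[node.children[0]]


def resolve_polytomies(tree: RootedTree) -> RootedTree:
    """Validate arity and return the tree unchanged.

    Polytomies are legal throughout (the reconstruction generalises to any
    child count); this pass only rejects single-child internals and records
    the maximum arity on the tree object.
    """
    tree.validate()
    tree.max_arity = max(
        (len(n.children) for n in tree.postorder() if not n.is_leaf), default=0
    )
    return tree
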