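"""Hartigan maximum-parsimony ancestral reconstruction, one column at a time.

The bottom-up pass computes, for every node, the set of amino acids that can
start a minimum-mutation history of the subtree below it.  For a binary node
this is the classic rule — intersection of the child sets when non-empty,
otherwise their union; for a polytomy it is Hartigan's generalisation: the
states attaining the maximum support count over the (non-missing) children.

The top-down pass turns sets into single states.  The root state is chosen
by trying every root candidate and keeping the one whose greedy descent
yields the smallest total node-substitution score (alphabetical tie-break);
below the root a node keeps its parent's state whenever that state is in its
candidate set (score 0 is always minimal because off-diagonal scores are
strictly positive), and otherwise takes the candidate with the smallest
ancestor-to-child score, again breaking ties alphabetically.  Any choice
from the candidate sets realises the minimum unweighted change count; the
substitution-score refinement only selects among those minimum-change
histories.

A leaf bearing a gap or 'X' is missing: it is excluded from set computation
and its incident edge contributes no score.  An internal node all of whose
children are missing is itself missing.

The column substitution score SS is the sum of NSS(parent, child) over all
tree edges with both endpoints assigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .matrix import NssMatrix
from .phylo import RootedTree, TreeNode

__all__ = ["ColumnStates", "bottom_up", "top_down_refine", "score_column",
           "reconstruct_column"]

MISSING = frozenset()


@dataclass
class ColumnStates:
    """Reconstruction of one alignment column.

    Maps are keyed by node object; ``assigned`` is None for missing nodes.
    """

    candidate_sets: dict[TreeNode, frozenset[str]]
    assigned: dict[TreeNode, str | None]
    column_ss: float
    n_informative: int


def bottom_up(tree: RootedTree, column: dict[str, str | None]) -> dict[TreeNode, frozenset[str]]:
    """Hartigan's bottom-up pass.

    ``column`` maps leaf label to residue; gaps, 'X' and None mark a leaf as
    missing.  Returns the per-node candidate sets (empty set = missing).
    """
    sets: dict[TreeNode, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            residue = column.get(node.label)
            if residue is None or residue in ("-", "X"):
                sets[node] = MISSING
            else:
                sets[node] = frozenset((residue,))
            continue
        child_sets = [sets[c] for c in node.children if sets[c]]
        if not child_sets:
            sets[node] = MISSING
            continue
        support = Counter()
        for cs in child_sets:
            support.update(cs)
        top = max(support.values())
        sets[node] = frozenset(s for s, k in support.items() if k == top)
    return sets


def _descend(tree: RootedTree, sets, root_state: str, nss: NssMatrix):
    """Greedy top-down assignment given a root state; returns (assigned, score)."""
    assigned: dict[TreeNode, str | None] = {}
    total = 0.0
    assigned[tree.root] = root_state if sets[tree.root] else None
    for node in tree.preorder():
        if node is tree.root:
            continue
        candidates = sets[node]
        if not candidates:
            assigned[node] = None
            continue
        parent_state = assigned[node.parent]
        if parent_state is None:
            # parent missing implies every child missing, so this branch is
            # unreachable under the bottom-up rule; keep it defensive
            state = min(candidates)
        elif parent_state in candidates:
            state = parent_state
        else:
            state = min(candidates, key=lambda s: (nss[parent_state, s], s))
            total += nss[parent_state, state]
        assigned[node] = state
    return assigned, total


def top_down_refine(tree: RootedTree, candidate_sets, nss: NssMatrix):
    """Resolve candidate sets to one state per node (see module docstring)."""
    root_candidates = candidate_sets[tree.root]
    if not root_candidates:
        return {node: None for node in tree.postorder()}
    best = None
    for root_state in sorted(root_candidates):
        assigned, total = _descend(tree, candidate_sets, root_state, nss)
        if best is None or total < best[1]:
            best = (assigned, total)
    return best[0]


def score_column(tree: RootedTree, assigned, nss: NssMatrix) -> float:
    """Sum NSS(parent, child) over edges with both endpoints assigned."""
    total = 0.0
    for parent, child in tree.edges():
        p, c = assigned[parent], assigned[child]
        if p is None or c is None:
            continue
        total += nss[p, c]
    return total


def parsimony_changes(tree: RootedTree, assigned) -> int:
    """Unweighted change count of an assignment (missing edges excluded)."""
    return sum(
        1
        for parent, child in tree.edges()
        if assigned[parent] is not None
        and assigned[child] is not None
        and assigned[parent] != assigned[child]
    )


def column_states_tsv(tree: RootedTree, columns: list["ColumnStates"]) -> str:
    """Debug dump: per column and node, the candidate set and assigned state."""
    lines = ["column\tnode\tcandidates\tassigned"]
    nodes = list(tree.preorder())
    for k, states in enumerate(columns, start=1):
        for node in nodes:
            candidates = "".join(sorted(states.candidate_sets[node])) or "-"
            assigned = states.assigned[node] or "-"
            lines.append(f"{k}\t{node.label}\t{candidates}\t{assigned}")
    return "\n".join(lines) + "\n"


def reconstruct_column(tree: RootedTree, column: dict[str, str | None],
                       nss: NssMatrix) -> ColumnStates:
    """Full per-column reconstruction: sets, states, score, informative count."""
    sets = bottom_up(tree, column)
    assigned = top_down_refine(tree, sets, nss)
    ss = score_column(tree, assigned, nss)
    n_informative = sum(
        1 for leaf in tree.leaves()
        if column.get(leaf.label) not in (None, "-", "X")
    )
    return ColumnStates(candidate_sets=sets, assigned=assigned,
                        column_ss=ss, n_informative=n_informative)
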