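"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (exhaustive enumeration, triple
loops) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def fitch_sets(tree, column):
    """Textbook Fitch bottom-up sets for a binary tree with informative
    leaves: intersection if non-empty, else union."""
    sets = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[node] = frozenset((column[node.label],))
        else:
            left, right = (sets[c] for c in node.children)
            inter = left & right
            sets[node] = inter if inter else left | right
    return sets


def min_changes_bruteforce(tree, column, alphabet):
    """Minimum substitution count over ALL internal labelings (exhaustive).

    Missing leaves (None/'-'/'X') contribute no edges.  Tractable only for
    tiny trees.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    best = None
    for labels in itertools.product(alphabet, repeat=len(internals)):
        state = dict(zip(internals, labels))
        for leaf in leaves:
            state[leaf] = column.get(leaf.label)
        changes = 0
        for parent, child in tree.edges():
            p, c = state[parent], state[child]
            if p in (None, "-", "X") or c in (None, "-", "X"):
                continue
            if p != c:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


def assignment_changes(tree, assigned):
    """Recount substitutions of an assignment straight off the edge list."""
    return sum(
        1
        for parent, child in tree.edges()
        if assigned[parent] is not None
        and assigned[child] is not None
        and assigned[parent] != assigned[child]
    )


def smooth_naive(x, window, smooth_window, smooth_passes):
    """Three explicit moving-average loops with truncated centred windows."""
    x = list(map(float, x))
    for w in [window] + [smooth_window] * smooth_passes:
        half = w // 2
        out = []
        for i in range(len(x)):
            lo = max(0, i - half)
            hi = min(len(x), i + half + 1)
            out.append(sum(x[lo:hi]) / (hi - lo))
        x = out
    return np.array(x)


def fisher_twosided_enum(a, b, c, d):
    """Two-sided Fisher exact p by summing hypergeometric point
    probabilities of every table with the same margins whose probability is
    at most that of the observed table."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def point_prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    observed = point_prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = point_prob(x)
        if p <= observed * (1 + 1e-12):
            total += p
    return min(1.0, total)


def interval_union_length(intervals):
    """Total length of a union of 1-based inclusive intervals."""
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end + 1))
    return len(covered)
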