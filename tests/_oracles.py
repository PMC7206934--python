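"""Independent brute-force oracles used only by the tests.

Everything here deliberately avoids the package's own algorithms: scores
are found by enumerating alignments, and parsimony informativeness by
scoring every unrooted topology with Fitch counting.
"""

from __future__ import annotations

import math
from functools import lru_cache

FULL = frozenset("ACGT")
MISSING = set("-N?")


def brute_align_score(ref: str, alt: str, match, mismatch, gap_open, gap_extend) -> float:
    """Best global alignment score by exhaustive recursion over all
    alignments (no DP table); affine gaps pay gap_open for the first base
    of a run and gap_extend for each further base."""
    best = -math.inf

    def rec(i: int, j: int, last: str, acc: float) -> None:
        nonlocal best
        if i == len(ref) and j == len(alt):
            best = max(best, acc)
            return
        if i < len(ref) and j < len(alt):
            s = match if ref[i] == alt[j] else mismatch
            rec(i + 1, j + 1, "M", acc + s)
        if i < len(ref):
            rec(i + 1, j, "U", acc + (gap_extend if last == "U" else gap_open))
        if j < len(alt):
            rec(i, j + 1, "L", acc + (gap_extend if last == "L" else gap_open))

    rec(0, 0, "M", 0.0)
    return best


# --- exhaustive parsimony over all unrooted topologies ---------------------


@lru_cache(maxsize=None)
def all_unrooted_topologies(n: int) -> tuple:
    """All unrooted binary topologies on leaves 0..n-1, as edge tuples.

    Internal nodes are negative ints. Built by stepwise addition: leaf k
    is inserted into every edge of every (k)-leaf tree.
    """
    assert n >= 3
    if n == 3:
        return ((((0, -1), (1, -1), (2, -1))),)
    trees = []
    for tree in all_unrooted_topologies(n - 1):
        for split_edge in tree:
            new_internal = -(n - 2)  # internal ids -1, -2, ...
            u, v = split_edge
            edges = [e for e in tree if e != split_edge]
            edges += [(u, new_internal), (new_internal, v), (n - 1, new_internal)]
            trees.append(tuple(sorted(edges)))
    return tuple(trees)


def fitch_length(edges, states: dict[int, frozenset]) -> int:
    """Parsimony length of one column on one topology (Fitch sets).

    ``states`` maps each leaf to its allowed state set (FULL for missing).
    The tree is rooted along its first edge to stay binary.
    """
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    changes = 0

    def down(node: int, parent: int) -> frozenset:
        nonlocal changes
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return states[node]
        sets = [down(k, node) for k in kids]
        cur = sets[0]
        for s in sets[1:]:
            inter = cur & s
            if inter:
                cur = inter
            else:
                cur = cur | s
                changes += 1
        return cur

    u, v = edges[0]
    left = down(u, v)
    right = down(v, u)
    if not (left & right):
        changes += 1
    return changes


def pic_by_exhaustive_parsimony(column: str) -> bool:
    """A column is parsimony-informative iff its minimum-change count
    differs between at least two unrooted topologies."""
    n = len(column)
    states = {
        i: (FULL if c.upper() in MISSING else frozenset(c.upper()))
        for i, c in enumerate(column)
    }
    scores = set()
    for tree in all_unrooted_topologies(n):
        scores.add(fitch_length(tree, states))
        if len(scores) > 1:
            return True
    return False
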