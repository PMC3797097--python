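"""Independent brute-force oracles used only by the tests.

These re-derive expected values through separate, simple code paths:
an explicit three-state affine-gap dynamic program for pairwise alignment
scores, and exhaustive minimisation over single-gain assignments for
presence/absence loss counts.
"""

from __future__ import annotations

import math

from gidphylo.seqio_align import ScoringScheme


def gotoh_global_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Three-state affine global alignment score, end gaps penalised.

    Gap of length L costs open + (L-1)·extend, matching the package's
    stated convention.
    """
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    la, lb = len(a), len(b)
    neg = -math.inf
    m = [[neg] * (lb + 1) for _ in range(la + 1)]
    x = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    m[0][0] = 0.0
    for i in range(1, la + 1):
        x[i][0] = -go - (i - 1) * ge
    for j in range(1, lb + 1):
        y[0][j] = -go - (j - 1) * ge
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[a[i - 1]][b[j - 1]]
            m[i][j] = max(m[i - 1][j - 1], x[i - 1][j - 1], y[i - 1][j - 1]) + s
            x[i][j] = max(m[i - 1][j] - go, x[i - 1][j] - ge, y[i - 1][j] - go)
            y[i][j] = max(m[i][j - 1] - go, y[i][j - 1] - ge, x[i][j - 1] - go)
    return max(m[la][lb], x[la][lb], y[la][lb])


def gotoh_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Three-state affine Smith-Waterman score (never below zero)."""
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    la, lb = len(a), len(b)
    neg = -math.inf
    best = 0.0
    m = [[0.0] * (lb + 1) for _ in range(la + 1)]
    x = [[neg] * (lb + 1) for _ in range(la + 1)]
    y = [[neg] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[a[i - 1]][b[j - 1]]
            m[i][j] = max(0.0,
                          m[i - 1][j - 1] + s,
                          x[i - 1][j - 1] + s,
                          y[i - 1][j - 1] + s)
            x[i][j] = max(m[i - 1][j] - go, x[i - 1][j] - ge)
            y[i][j] = max(m[i][j - 1] - go, y[i][j - 1] - ge)
            best = max(best, m[i][j])
    return best


def dollo_min_losses(tree, presence: dict[str, bool]) -> int | None:
    """Minimal loss count over all feasible single-gain placements.

    ``tree`` is a rooted dendropy tree. Returns None when the character is
    absent from every leaf.
    """
    present = {
        leaf.taxon.label for leaf in tree.leaf_node_iter()
        if presence.get(leaf.taxon.label, False)
    }
    if not present:
        return None
    best = None
    for gain in tree.preorder_node_iter():
        under = {l.taxon.label for l in gain.leaf_iter()}
        if not present <= under:
            continue

        def losses(node, lost):
            leafset = {l.taxon.label for l in node.leaf_iter()}
            if not lost and not (leafset & present):
                return 1
            if node.is_leaf():
                return 0
            return sum(losses(child, lost) for child in node.child_nodes())

        count = losses(gain, False)
        if best is None or count < best:
            best = count
    return best
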