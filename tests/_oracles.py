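"""Independent brute-force oracles used to validate the implementation.

These deliberately use different algorithms from the package: a quadratic
dynamic program for reverse-complement repeats, a plain affine-gap
Smith-Waterman matrix fill for local alignment scores, and exhaustive
enumeration of ancestral assignments for the parsimony mapper.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import reverse_complement

# --- longest disjoint reverse-complement pair (circular) --------------------

def _match_runs(t: str, r: str, min_len: int) -> list[tuple[int, int, int]]:
    """Cells (i, j, run) with diagonal match-run length >= min_len, where
    ``run`` is the common suffix length of t[:i+1] and r[:j+1]. One row of
    the dynamic program is kept at a time."""
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    ra = np.frombuffer(r.encode(), dtype=np.uint8)
    prev = np.zeros(len(ra), dtype=np.int32)
    cells: list[tuple[int, int, int]] = []
    for i in range(len(ta)):
        eq = ta[i] == ra
        cur = np.zeros(len(ra), dtype=np.int32)
        cur[0] = 1 if eq[0] else 0
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        for j in np.nonzero(cur >= min_len)[0]:
            cells.append((i, int(j), int(cur[j])))
        prev = cur
    return cells


def _disjoint(a: int, b: int, length: int, n: int) -> bool:
    return (b - a) % n >= length and (a - b) % n >= length


def max_inverted_repeat(seq: str, min_len: int) -> int:
    """Length of the longest pair of disjoint circular intervals that are
    exact reverse complements of each other; 0 if none reaches ``min_len``."""
    n = len(seq)
    t = seq + seq
    r = reverse_complement(seq) * 2
    cells = _match_runs(t, r, min_len)
    if not cells:
        return 0
    cap = n // 2
    top = min(max(c[2] for c in cells), cap)
    for c in range(top, min_len - 1, -1):
        for i, j, run in cells:
            if run < c:
                continue
            a = i - c + 1  # start in t
            jj = j - c + 1  # start in r
            if not (0 <= a < n and 0 <= jj < n):
                continue
            b = (n - jj - c) % n
            if _disjoint(a, b, c, n):
                return c
    return 0


# --- quadratic affine-gap local alignment score -----------------------------

def smith_waterman_score(
    s1: str, s2: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2
) -> float:
    """Best local alignment score, affine gaps (open cost applies to the
    first gap base). Plain O(mn) matrix fill."""
    m, n = len(s1), len(s2)
    neg = -math.inf
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in s1 (consume s2)
    F = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in s2 (consume s1)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --- exhaustive irreversible parsimony --------------------------------------

_COST = {
    "F": {"F": 0, "P": 1, "D": 2},
    "P": {"F": math.inf, "P": 0, "D": 1},
    "D": {"F": math.inf, "P": math.inf, "D": 0},
}
_STATES = ("F", "P", "D")


def enumerate_min_cost(tree, tip_states: dict[str, str]):
    """Minimum cost over all ancestral assignments (root fixed F), plus the
    set of optimal assignments keyed by internal node id."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    root = tree.seed_node
    best = math.inf
    optimal = []
    for combo in itertools.product(_STATES, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        if assign[id(root)] != "F":
            continue
        cost = 0.0
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            ps = assign[id(parent)]
            cs = (
                tip_states[node.taxon.label]
                if node.is_leaf()
                else assign[id(node)]
            )
            cost += _COST[ps][cs]
            if cost >= math.inf:
                break
        if cost < best:
            best = cost
            optimal = [assign]
        elif cost == best:
            optimal.append(assign)
    return best, optimal
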