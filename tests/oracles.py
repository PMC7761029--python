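"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (quadratic scans, explicit recursions,
exhaustive enumeration) and shares no code with the implementation under
test.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def gotoh_score(a: str, b: str, scheme) -> float:
    """Reference affine-gap DP score; a length-L gap costs
    gap_open + (L-1) * gap_extend.  Global mode penalizes end gaps."""
    n, m = len(a), len(b)
    local = scheme.mode == "local"

    def sub(x, y):
        return scheme.match if (x == y and x != "N") else scheme.mismatch

    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        F[i, 0] = scheme.gap_open + (i - 1) * scheme.gap_extend
        H[i, 0] = 0.0 if local else F[i, 0]
    for j in range(1, m + 1):
        E[0, j] = scheme.gap_open + (j - 1) * scheme.gap_extend
        H[0, j] = 0.0 if local else E[0, j]
    best = 0.0 if local else NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + scheme.gap_extend, H[i, j - 1] + scheme.gap_open)
            F[i, j] = max(F[i - 1, j] + scheme.gap_extend, H[i - 1, j] + scheme.gap_open)
            h = max(H[i - 1, j - 1] + sub(a[i - 1], b[j - 1]), E[i, j], F[i, j])
            if local:
                h = max(h, 0.0)
                best = max(best, h)
            H[i, j] = h
    return float(best if local else H[n, m])


def enumerate_global_score(a: str, b: str, scheme) -> float:
    """Max score over explicitly enumerated global alignment paths (tiny
    inputs only; exponential)."""

    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = NEG
        if i < len(a) and j < len(b):
            s = scheme.match if (a[i] == b[j] and a[i] != "N") else scheme.mismatch
            out = max(out, s + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = scheme.gap_extend if state == "ga" else scheme.gap_open
            out = max(out, cost + rec(i + 1, j, "ga"))
        if j < len(b):
            cost = scheme.gap_extend if state == "gb" else scheme.gap_open
            out = max(out, cost + rec(i, j + 1, "gb"))
        return out

    return rec(0, 0, "m")


def enumerate_local_score(a: str, b: str, scheme) -> float:
    """Best global score over every substring pair (the local optimum)."""
    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1, len(b) + 1):
                    best = max(best, enumerate_global_score(a[i1:i2], b[j1:j2], scheme))
    return best


def naive_hrr(expr: np.ndarray, ids: list[str]) -> np.ndarray:
    """HRR by explicit per-gene sorting: Pearson each pair, sort each gene's
    neighbours by (descending r, ascending id), take the max of the two
    directed ordinal ranks."""
    n = expr.shape[0]
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi = expr[i] - expr[i].mean()
            xj = expr[j] - expr[j].mean()
            r[i, j] = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
    rank = np.zeros((n, n), dtype=int)
    for i in range(n):
        neighbours = sorted((j for j in range(n) if j != i), key=lambda j: (-r[i, j], ids[j]))
        for pos, j in enumerate(neighbours, start=1):
            rank[i, j] = pos
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            out[i, j] = max(rank[i, j], rank[j, i])
    return out


def all_partitions(items: list):
    """Every set partition of ``items`` (Bell(n) of them)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[head] + part[k]] + part[k + 1 :]
        yield [[head]] + part


def modularity_by_hand(edges: list[tuple], blocks: list[list]) -> float:
    """Q = sum_c (e_c - a_c^2) computed from raw edge membership counts."""
    m = len(edges)
    q = 0.0
    for block in blocks:
        s = set(block)
        e_c = sum(1 for u, v in edges if u in s and v in s) / m
        ends = sum((u in s) + (v in s) for u, v in edges) / (2 * m)
        q += e_c - ends**2
    return q
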