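"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import math


def brute_force_global_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global alignment score by exhaustive enumeration of alignments.

    Every monotone path through the alignment grid is scored, with a gap run
    of length k costing gap_open + (k - 1) * gap_extend; N never matches.
    Exponential — for short sequences only.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "A" else gap_open), "A")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "B" else gap_open), "B")

    rec(0, 0, 0.0, "")
    return best


def gotoh_global_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Textbook three-state affine-gap global alignment DP (Gotoh).

    Written directly from the recurrences, independent of the package's
    alignment engines; a gap of length k costs gap_open + (k-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend, Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend, X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def poisson_sf(k_minus_1: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct series summation.

    Sums P(X = j) for j = 0..k-1 term by term and returns the complement —
    independent of any library tail routine.
    """
    k = k_minus_1 + 1
    total = 0.0
    term = math.exp(-lam)
    for j in range(k):
        total += term
        term *= lam / (j + 1)
    return max(0.0, 1.0 - total)


def all_pairs_best_identity(sequences: dict[str, str], align, identity) -> dict[str, tuple[str, float]]:
    """Best partner per element by exhaustively aligning every ordered pair."""
    out = {}
    for eid, seq in sequences.items():
        best = None
        for other, oseq in sequences.items():
            if other == eid:
                continue
            ident = identity(align(seq, oseq))
            if best is None or ident > best[1]:
                best = (other, ident)
        out[eid] = best
    return out
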