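"""Independent brute-force oracles the implementation is checked against.

Each oracle is deliberately naive and shares no code with the module it
verifies: exhaustive enumeration for local alignment, per-character pattern
walking for motifs, per-site counting plus direct formula evaluation for
K2P.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# local alignment: max over all substring pairs of global (Gotoh) scores

def _gotoh_global(a: str, b: str, sub, gap_open: float,
                  gap_extend: float) -> float:
    """Affine-gap global alignment score (first gap costs open+extend)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to -)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def brute_force_local_score(a: str, b: str, sub, gap_open: float,
                            gap_extend: float) -> float:
    """Optimal local alignment score by enumerating every substring pair."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, _gotoh_global(a[i0:i1], b[j0:j1], sub,
                                                   gap_open, gap_extend))
    return best


# ---------------------------------------------------------------------------
# motif patterns, matched by explicit per-character walking

def _char_ok(c: str, spec: str) -> bool:
    if spec == ".":
        return True
    if spec.startswith("["):
        return c in spec[1:-1]
    return c == spec


_PATTERNS: dict[str, list[str]] = {
    "CysHis": ["C", ".", ".", "C", ".", ".", ".", ".", "H",
               ".", ".", ".", ".", "C"],
    "PPPY": ["P", "P", "P", "Y"],
    "MHR": ["Q", "G", ".", ".", "E", ".", ".", ".", ".", "F", ".", "."],
    "Furin": ["[KR]", ".", "[KR]", "R"],
    "CX6CC": ["C", ".", ".", ".", ".", ".", ".", "C", "C"],
    "CX6C": ["C", ".", ".", ".", ".", ".", ".", "C"],
    "YXXL": ["Y", ".", ".", "L"],
    "RBM": ["S", "D", "G", "G", "G", ".", ".", "D", ".", ".", "R"],
}


def brute_force_motifs(protein: str) -> set[tuple[str, int]]:
    """(motif_id, position) pairs by sliding every pattern at every offset.

    Mirrors the contract: matches never contain '*', and CX6C is suppressed
    where CX6CC matches at the same anchor.
    """
    found: set[tuple[str, int]] = set()
    for motif_id, pattern in _PATTERNS.items():
        w = len(pattern)
        for pos in range(len(protein) - w + 1):
            window = protein[pos:pos + w]
            if "*" in window:
                continue
            if all(_char_ok(c, s) for c, s in zip(window, pattern)):
                found.add((motif_id, pos))
    for motif_id, pos in list(found):
        if motif_id == "CX6C" and ("CX6CC", pos) in found:
            found.discard((motif_id, pos))
    return found


# ---------------------------------------------------------------------------
# K2P: per-site counting + direct formula

_PUR = {"A", "G"}
_PYR = {"C", "T"}


def k2p_oracle(a: str, b: str):
    """(P, Q, D) by naive per-site counting; None when saturated."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PUR) == (y in _PUR):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return P, Q, None
    D = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    return P, Q, D
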