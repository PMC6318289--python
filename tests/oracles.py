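"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic-programming code:
the alignment oracles enumerate alignments (exhaustively for tiny
inputs, with memoized top-down search otherwise) and score them by
scanning move strings with affine gap rules.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List


def score_moves(ref: str, qry: str, moves: List[str], sc) -> float:
    """Score an alignment given as a move string (M/X/Y) with affine gaps.

    X consumes a reference base against a gap, Y a query base against a
    gap; a gap run of length L costs gap_open + (L-1)*gap_extend.
    """
    i = j = 0
    prev = None
    score = 0.0
    for mv in moves:
        if mv == "M":
            score += sc.match if ref[i] == qry[j] else sc.mismatch
            i += 1
            j += 1
        elif mv == "X":
            score += sc.gap_extend if prev == "X" else sc.gap_open
            i += 1
        else:
            score += sc.gap_extend if prev == "Y" else sc.gap_open
            j += 1
        prev = mv
    assert i == len(ref) and j == len(qry), "moves do not consume both sequences"
    return score


def enumerate_optimum(ref: str, qry: str, sc) -> float:
    """Plain enumeration of every global alignment (tiny inputs only)."""
    best = float("-inf")
    n, m = len(ref), len(qry)

    def rec(i: int, j: int, moves: List[str]) -> None:
        nonlocal best
        if i == n and j == m:
            best = max(best, score_moves(ref, qry, moves, sc))
            return
        if i < n and j < m:
            rec(i + 1, j + 1, moves + ["M"])
        if i < n:
            rec(i + 1, j, moves + ["X"])
        if j < m:
            rec(i, j + 1, moves + ["Y"])

    rec(0, 0, [])
    return best


def brute_force_optimum(ref: str, qry: str, sc) -> float:
    """Exhaustive optimum via memoized top-down search over all alignments.

    ``nxt`` is the move immediately to the right of the prefix boundary,
    so a gap move pays gap_extend only when it continues a run.
    """

    @lru_cache(maxsize=None)
    def f(i: int, j: int, nxt: str) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = float("-inf")
        if i > 0 and j > 0:
            s = sc.match if ref[i - 1] == qry[j - 1] else sc.mismatch
            best = max(best, f(i - 1, j - 1, "M") + s)
        if i > 0:
            pen = sc.gap_extend if nxt == "X" else sc.gap_open
            best = max(best, f(i - 1, j, "X") + pen)
        if j > 0:
            pen = sc.gap_extend if nxt == "Y" else sc.gap_open
            best = max(best, f(i, j - 1, "Y") + pen)
        return best

    result = f(len(ref), len(qry), "M")
    f.cache_clear()
    return result


def alignment_score_from_rows(ref_aln: str, qry_aln: str, sc) -> float:
    """Recompute a gapped alignment's score directly from its columns."""
    score = 0.0
    prev = None
    for r, q in zip(ref_aln, qry_aln):
        if r == "-":
            score += sc.gap_extend if prev == "Y" else sc.gap_open
            prev = "Y"
        elif q == "-":
            score += sc.gap_extend if prev == "X" else sc.gap_open
            prev = "X"
        else:
            score += sc.match if r == q else sc.mismatch
            prev = "M"
    return score
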