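"""Independent alignment oracles for the test suite.

Everything here is written without reference to kinscope's aligner: scoring
uses Bio.Align's BLOSUM62 directly, the optimal score comes from a top-down
memoized exploration of every alignment path, and tiny cases are checked by
literal enumeration of all alignments.  Gap convention: a run of k gapped
columns costs open + (k - 1) * extend.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from itertools import product

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GO = 10.0
GE = 0.5


def column_score(x: str, y: str) -> float:
    return float(_BLOSUM62[x, y])


def score_gapped_pair(aligned_a: str, aligned_b: str) -> float:
    """Score two gapped strings; independent of kinscope.alignment."""
    assert len(aligned_a) == len(aligned_b)
    total = 0.0
    gap_a = gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        assert not (x == "-" and y == "-")
        if x == "-":
            total -= GE if gap_a else GO
            gap_a, gap_b = True, False
        elif y == "-":
            total -= GE if gap_b else GO
            gap_a, gap_b = False, True
        else:
            total += column_score(x, y)
            gap_a = gap_b = False
    return total


def best_score(a: str, b: str) -> float:
    """Optimal global score by memoized top-down search over all paths."""
    sys.setrecursionlimit(20000)

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(column_score(a[i], b[j]) + go(i + 1, j + 1, "M"))
        if j < len(b):
            cost = GE if state == "A" else GO
            options.append(-cost + go(i, j + 1, "A"))
        if i < len(a):
            cost = GE if state == "B" else GO
            options.append(-cost + go(i + 1, j, "B"))
        return max(options)

    result = go(0, 0, "S")
    go.cache_clear()
    return result


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b).

    Exponential; only for sequences of length <= ~6.
    """

    def rec(i, j, ga, gb):
        if i == len(a) and j == len(b):
            yield "".join(ga), "".join(gb)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ga + [a[i]], gb + [b[j]])
        if j < len(b):
            yield from rec(i, j + 1, ga + ["-"], gb + [b[j]])
        if i < len(a):
            yield from rec(i + 1, j, ga + [a[i]], gb + ["-"])

    yield from rec(0, 0, [], [])


def optimal_identity_gap_sets(a: str, b: str) -> set[tuple[float, int]]:
    """(percent_identity, n_gap_columns) of every score-optimal alignment.

    Identity uses alignment columns as the denominator, matching the
    pipeline's default.  Only feasible for short sequences.
    """
    best = None
    results: set[tuple[float, int]] = set()
    for ga, gb in enumerate_alignments(a, b):
        s = score_gapped_pair(ga, gb)
        ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
        gaps = sum(1 for x, y in zip(ga, gb) if x == "-" or y == "-")
        pid = 100.0 * ident / len(ga)
        if best is None or s > best + 1e-12:
            best = s
            results = {(pid, gaps)}
        elif abs(s - best) <= 1e-12:
            results.add((pid, gaps))
    return results
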