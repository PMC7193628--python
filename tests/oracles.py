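"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming / rank-statistic machinery
of the package: alignments are enumerated exhaustively and scored path by
path; Mann-Whitney p-values are computed by enumerating every rank
configuration.
"""

from __future__ import annotations

import itertools
from math import comb


def brute_force_alignment_score(a: str, b: str, scoring) -> float:
    """Maximum global-alignment score by exhaustive path enumeration.

    Explores every monotone alignment path (diagonal / gap-in-b /
    gap-in-a), charging gap_open for the first column of a gap run and
    gap_extend for each further column.  Exponential; for short strings
    only.
    """
    best = [-float("inf")]

    def rec(i: int, j: int, last: str | None, acc: float) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            same = a[i] == b[j] and a[i] != "N" and b[j] != "N"
            rec(i + 1, j + 1, "M", acc + (scoring.match if same else scoring.mismatch))
        if i < len(a):
            inc = scoring.gap_extend if last == "X" else scoring.gap_open
            rec(i + 1, j, "X", acc + inc)
        if j < len(b):
            inc = scoring.gap_extend if last == "Y" else scoring.gap_open
            rec(i, j + 1, "Y", acc + inc)

    rec(0, 0, None, 0.0)
    return best[0]


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating rank configurations.

    Tie-free data only.  U is the number of (x_i, y_j) pairs with
    x_i > y_j; the p-value doubles the smaller tail probability of the
    exact U distribution (capped at 1).
    """
    x = list(x)
    y = list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n * (n + 1) // 2

    total = comb(n + m, n)
    c_le = 0
    c_ge = 0
    base = (n * (n + 1)) // 2
    for positions in itertools.combinations(range(1, n + m + 1), n):
        u = sum(positions) - base
        if u <= u_obs:
            c_le += 1
        if u >= u_obs:
            c_ge += 1
    return min(1.0, 2.0 * min(c_le, c_ge) / total)
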