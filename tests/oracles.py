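"""Independent brute-force oracles the implementation is checked against.

Deliberately naive: quadratic dynamic programming, exhaustive enumeration,
bisection — no code shared with the package's own algorithms.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s.upper()))


def smith_waterman(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Full affine-gap local alignment (Gotoh), O(nm).

    Gap of length k costs ``gap_open + gap_extend * k``.  Returns
    (best score, query 0-based half-open span, target span) of one optimal
    alignment (traceback preferring diagonal moves).
    """
    n, m = len(query), len(target)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target cons.)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend,
                E[i][j - 1] - gap_extend,
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend,
                F[i - 1][j] - gap_extend,
            )
            s = match if query[i - 1] == target[j - 1] else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, best_pos = h, (i, j)
    # traceback
    i, j = best_pos
    qe, te = i, j
    state = "H"
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            s = match if query[i - 1] == target[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                break
        elif state == "E":
            if E[i][j] == E[i][j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if F[i][j] == F[i - 1][j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, (i, qe), (j, te)


def karlin_lambda_bisection(
    match: int = 1, mismatch: int = -2, tol: float = 1e-12
) -> float:
    """Bisection root of 0.25·e^{λ·match} + 0.75·e^{λ·mismatch} = 1."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1

    lo, hi = 1e-9, 10.0
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def enumerate_revcomp_pairs(
    region: str,
    upstream_offset: int,
    downstream_offset: int,
    min_len: int,
    max_gap: int,
) -> set[tuple[str, int, int]]:
    """Exhaustive maximal reverse-complementary pair enumeration.

    Same window semantics as the implementation: the left member must lie
    inside ``[upstream_offset - max_gap, upstream_offset + max_gap]``, the
    right member inside the downstream window, and maximality is judged
    within those windows.  Returns {(left_seq, left_start_1based,
    right_start_1based)}.
    """
    w1_lo = max(0, upstream_offset - max_gap)
    w1_hi = min(len(region), upstream_offset + max_gap)
    w2_lo = max(0, downstream_offset - max_gap)
    w2_hi = min(len(region), downstream_offset + max_gap)
    found = set()
    for i in range(w1_lo, w1_hi):
        for j in range(w2_lo, w2_hi):
            for length in range(min_len, min(w1_hi - i, w2_hi - j) + 1):
                s = region[i : i + length]
                t = region[j : j + length]
                if t != revcomp(s):
                    continue
                # maximal within windows: extending one base on either
                # side breaks the relation or leaves a window
                left_ext = (
                    i - 1 >= w1_lo
                    and j + length < w2_hi
                    and region[j + length] == _COMP[region[i - 1]]
                )
                right_ext = (
                    i + length < w1_hi
                    and j - 1 >= w2_lo
                    and region[j - 1] == _COMP[region[i + length]]
                )
                if not left_ext and not right_ext:
                    found.add((s, i + 1, j + 1))
    return found
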