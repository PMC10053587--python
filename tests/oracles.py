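"""Independent brute-force oracles used only by the test suite.

Written against the text-book recurrences, deliberately naive, and kept
separate from the package so they cannot share a bug with the
implementation they check.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def _gap_costs(scheme):
    # gap of length k costs gap_open + k * gap_extend
    first = scheme.gap_open + scheme.gap_extend
    return first, scheme.gap_extend


def sw_score_oracle(a: str, b: str, scheme) -> float:
    """Smith–Waterman affine-gap score by the full three-state recurrence."""
    first, ext = _gap_costs(scheme)
    sub = scheme.matrix
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i][j - 1] - first, X[i][j - 1] - ext)
            Y[i][j] = max(M[i - 1][j] - first, Y[i - 1][j] - ext)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + sub[a[i - 1], b[j - 1]]
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def nw_score_oracle(a: str, b: str, scheme) -> float:
    """Needleman–Wunsch affine-gap score, end gaps penalized."""
    first, ext = _gap_costs(scheme)
    sub = scheme.matrix
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -(scheme.gap_open + j * ext)
    for i in range(1, n + 1):
        Y[i][0] = -(scheme.gap_open + i * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i][j - 1] - first, X[i][j - 1] - ext)
            Y[i][j] = max(M[i - 1][j] - first, Y[i - 1][j] - ext)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + sub[a[i - 1], b[j - 1]]
    return max(M[n][m], X[n][m], Y[n][m])


def kruskal_wallis_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """(H, tie-corrected H) computed directly from sorted midranks."""
    pooled = [(value, gi) for gi, group in enumerate(groups) for value in group]
    pooled.sort(key=lambda t: t[0])
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[k] = mid
        i = j + 1
    rank_sums = [0.0] * len(groups)
    for (value, gi), rank in zip(pooled, ranks):
        rank_sums[gi] += rank
    h = 0.0
    for gi, group in enumerate(groups):
        h += rank_sums[gi] ** 2 / len(group)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for value, _ in pooled:
        ties[value] = ties.get(value, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    denom = 1 - tie_sum / (n**3 - n)
    h_corrected = h / denom if denom else 0.0
    return h, h_corrected
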