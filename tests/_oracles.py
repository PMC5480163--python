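"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: a pure-Python Gotoh
local aligner (affine gaps) and a hand-rolled midrank Spearman.
"""

from __future__ import annotations

import math

NEG_INF = float("-inf")


def sw_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Best local-alignment score of a vs b (Gotoh, affine gaps).

    ``gap_open`` is the cost of a gap of length 1; each extra gap base
    costs ``gap_extend``.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def sw_best_score_both_strands(read: str, target: str) -> float:
    return max(sw_score(read, target), sw_score(_revcomp(read), target))


def midranks(values):
    """Average ranks (1-based) with ties sharing their midrank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """Pearson correlation of midranks, from explicit sums."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    vy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return cov / (vx * vy)
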