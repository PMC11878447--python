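"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: the peak oracle is a
naive O(n) circular neighbour scan plus an iterative highest-first merge,
and the alignment oracle enumerates every global alignment recursively,
tracking gap state to score affine gaps (open for the first gapped
position, extend for each further one).
"""

from __future__ import annotations

import math


def circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def brute_force_peaks(
    y, angles, threshold: float = 0.3, min_sep: float = 30.0
) -> list[float]:
    """Angles of circular local maxima >= threshold after highest-first merge."""
    n = len(y)
    cand = [
        (float(angles[i]), float(y[i]))
        for i in range(n)
        if y[i] >= threshold and y[i] > y[(i - 1) % n] and y[i] > y[(i + 1) % n]
    ]
    kept = []
    remaining = list(cand)
    while remaining:
        best = max(remaining, key=lambda p: (p[1], -p[0]))
        kept.append(best)
        remaining = [p for p in remaining if circ_dist(p[0], best[0]) >= min_sep]
    return sorted(a for a, _ in kept)


def exhaustive_alignment_score(
    a: str, b: str, sub, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Best global alignment score by full enumeration (small inputs only)."""
    best = -math.inf

    def rec(i: int, j: int, state: str, acc: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + sub(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "U", acc + (gap_extend if state == "U" else gap_open))
        if j < len(b):
            rec(i, j + 1, "L", acc + (gap_extend if state == "L" else gap_open))

    rec(0, 0, "M", 0.0)
    return best


def closed_form_pearson(a, b) -> float:
    """Textbook product-moment correlation, written out longhand."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
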