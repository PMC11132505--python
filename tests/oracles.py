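"""Independent reference implementations used as test oracles.

Everything here is deliberately written without reusing lcdscope's code
paths: direct per-window counting, exact rational hypergeometric sums,
closed forms re-derived independently, and brute-force enumeration.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from statistics import pstdev


# ---------------------------------------------------------------- dispersion

def boundary_gaps(positions: list[int], W: int) -> list[int]:
    """k+1 boundary-inclusive gaps for 1-based positions in a W-window."""
    pts = [0] + list(positions) + [W + 1]
    return [pts[i + 1] - pts[i] for i in range(len(pts) - 1)]


def even_gap_multiset(k: int, W: int) -> list[int]:
    # derived via rounded partition boundaries rather than divmod
    cuts = [((W + 1) * i) // (k + 1) for i in range(k + 2)]
    return [cuts[i + 1] - cuts[i] for i in range(k + 1)]


def clustered_gap_multiset(k: int, W: int) -> list[int]:
    return [1] * k + [W - k + 1]


def oracle_dispersion(window: str, aa: str) -> float:
    W = len(window)
    positions = [i + 1 for i, ch in enumerate(window) if ch == aa]
    k = len(positions)
    if k < 2:
        return 1.0
    sigma = pstdev(boundary_gaps(positions, W))
    smin = pstdev(even_gap_multiset(k, W))
    smax = pstdev(clustered_gap_multiset(k, W))
    if smax - smin <= 1e-12:
        return 1.0
    return min(1.0, max(0.0, 1.0 - (sigma - smin) / (smax - smin)))


def enumerate_sigma_extremes(k: int, W: int) -> tuple[float, float]:
    """(min, max) gap-sigma over all placements of k residues in a W-window."""
    best_min, best_max = math.inf, -math.inf
    for pos in combinations(range(1, W + 1), k):
        s = pstdev(boundary_gaps(list(pos), W))
        best_min = min(best_min, s)
        best_max = max(best_max, s)
    return best_min, best_max


# ------------------------------------------------------------------ scanning

def oracle_passing_starts(seq: str, primary: str, secondary: str | None,
                          W: int, c1: float, c2: float, delta: float) -> list[int]:
    """Exhaustive per-window check by direct slice counting."""
    starts = []
    for s in range(len(seq) - W + 1):
        win = seq[s:s + W]
        if win.count(primary) / W < c1 - 1e-9:
            continue
        if secondary is not None and win.count(secondary) / W < c2 - 1e-9:
            continue
        if oracle_dispersion(win, primary) < delta - 1e-9:
            continue
        if secondary is not None and oracle_dispersion(win, secondary) < delta - 1e-9:
            continue
        starts.append(s + 1)
    return starts


def union_intervals_from_starts(starts: list[int], W: int) -> list[tuple[int, int]]:
    """Merged intervals via per-window residue sets: windows sharing >=1
    residue are linked; each connected component's residue union is one
    interval."""
    windows = [set(range(s, s + W)) for s in starts]
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if windows[i] & windows[j]:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).update(windows[i])
    return sorted((min(c), max(c)) for c in comps.values())


def oracle_scan_intervals(seq: str, primary: str, secondary: str | None,
                          W: int = 20, c1: float = 0.40, c2: float = 0.20,
                          delta: float = 0.5) -> list[tuple[int, int]]:
    starts = oracle_passing_starts(seq, primary, secondary, W, c1, c2, delta)
    return union_intervals_from_starts(starts, W)


# ---------------------------------------------------------------- statistics

def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full-support rational enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    probs = [Fraction(math.comb(r1, t) * math.comb(n - r1, c1 - t), denom)
             for t in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return float(sum(p for p in probs if p <= p_obs))


def oracle_hypergeom_upper_tail(k: int, pop_n: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(pop_n, K, n), exact rationals."""
    denom = math.comb(pop_n, n)
    total = Fraction(0)
    for t in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, t) * math.comb(pop_n - K, n - t), denom)
    return float(min(total, Fraction(1)))


def oracle_holm_sidak(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - pvals[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def oracle_midrank_percentile(value: float, cohort: list[float]) -> float:
    below = sum(1 for v in cohort if v < value)
    equal = sum(1 for v in cohort if v == value)
    return 100.0 * (below + 0.5 * equal) / len(cohort)
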