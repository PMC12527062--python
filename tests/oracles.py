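"""Independent brute-force oracles used only by the test suite."""

from itertools import combinations
from math import comb


def dtw_bruteforce(a, b):
    """Minimum cumulative |a_i - b_j| over ALL monotone warping paths.

    Exhaustive depth-first enumeration from (0, 0) to (len(a)-1, len(b)-1)
    with steps (1, 0), (0, 1), (1, 1); no memoization, independent of the
    dynamic-programming implementation.  Only usable for tiny inputs.
    """
    n, m = len(a), len(b)
    best = [float("inf")]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], cost)
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def rank_count_u(x, y):
    """min(U1, U2) by direct pair counting with half-credit for ties."""
    u1 = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u1 += 1.0
            elif xi == yj:
                u1 += 0.5
    u2 = len(x) * len(y) - u1
    return min(u1, u2)


def _u1_of(x, y):
    u1 = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u1 += 1.0
            elif xi == yj:
                u1 += 0.5
    return u1


def exact_permutation_p(x, y):
    """Two-sided permutation p for the Mann-Whitney U by full enumeration.

    Reassigns the pooled observations to the two groups in every possible
    way, computing U1 by pair counting each time (no ranks involved), and
    counts assignments at least as far from n1*n2/2 as the observed one.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    center = n1 * (n - n1) / 2.0
    d_obs = abs(_u1_of(x, y) - center)
    hits = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        if abs(_u1_of(xs, ys) - center) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def ols_slope(ts, ys):
    """Closed-form least-squares slope, independent of numpy."""
    n = len(ts)
    mt = sum(ts) / n
    my = sum(ys) / n
    num = sum((t - mt) * (y - my) for t, y in zip(ts, ys))
    den = sum((t - mt) ** 2 for t in ts)
    return num / den
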