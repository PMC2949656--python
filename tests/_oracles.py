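"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths (and, where feasible, the
libraries) they check: naive enumeration, direct summation and
first-principles formulas only.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_ward(D) -> list[tuple[int, int, float]]:
    """Naive Ward agglomeration computed from first principles.

    Treats the dissimilarity as squared distances and, at every step,
    evaluates the merge cost of every cluster pair directly from the
    original matrix via the error-sum-of-squares identity
    cost(A, B) = 2 * [ESS(A+B) - ESS(A) - ESS(B)],
    ESS(C) = (1/|C|) * sum_{i<j in C} D[i, j].
    Returns [(id_a, id_b, height), ...] in scipy id convention.
    """
    n = D.shape[0]

    def ess(cluster: frozenset) -> float:
        members = sorted(cluster)
        total = 0.0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                total += D[members[i], members[j]]
        return total / len(members)

    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    ids = list(range(n))
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cost = 2.0 * (
                    ess(clusters[a] | clusters[b]) - ess(clusters[a]) - ess(clusters[b])
                )
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((min(ids[a], ids[b]), max(ids[a], ids[b]), cost))
        clusters[a] = clusters[a] | clusters[b]
        ids[a] = next_id
        next_id += 1
        del clusters[b]
        del ids[b]
    return merges


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact rational hypergeometric pmf via binomial coefficients."""
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_tail_sum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of pmf terms (exact rationals)."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += hypergeom_pmf_exact(x, N, K, n)
    return float(total)


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher exact p by full enumeration: sum the exact
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's (minimum-likelihood rule)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    N = row1 + row2
    p_obs = hypergeom_pmf_exact(a, N, row1, col1)
    total = Fraction(0)
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p_x = hypergeom_pmf_exact(x, N, row1, col1)
        if p_x <= p_obs:
            total += p_x
    return float(total)


def chi2_sf_df3(x: float) -> float:
    """Closed-form chi-square (df = 3) survival function:
    S(x) = erfc(sqrt(x/2)) + sqrt(2x/pi) * exp(-x/2)."""
    return math.erfc(math.sqrt(x / 2.0)) + math.sqrt(2.0 * x / math.pi) * math.exp(-x / 2.0)


def pearson_r(x, y) -> float:
    """Textbook Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den
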