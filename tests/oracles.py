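"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by the most direct possible route
(per-site loops, exact rational arithmetic, exhaustive enumeration) and is
deliberately kept free of any code path from the package under test.
"""

from fractions import Fraction
from itertools import combinations
from statistics import stdev


def brute_is_dmp(meth_counts, total_counts, min_delta=Fraction(1, 5), strict=True):
    """Direct per-site check of the two progressive inequality chains plus
    the overall-change gate, in exact rational arithmetic."""
    fracs = [Fraction(m, t) for m, t in zip(meth_counts, total_counts)]
    if strict:
        inc = all(a < b for a, b in zip(fracs, fracs[1:]))
        dec = all(a > b for a, b in zip(fracs, fracs[1:]))
    else:
        inc = all(a <= b for a, b in zip(fracs, fracs[1:]))
        dec = all(a >= b for a, b in zip(fracs, fracs[1:]))
    delta = fracs[-1] - fracs[0]
    if not (inc or dec) or delta == 0:
        return None
    if abs(delta) <= Fraction(min_delta).limit_denominator(10**6):
        return None
    return "hyper" if delta > 0 else "hypo"


def brute_region_score(fraction_rows):
    """Mean over CpGs of the sample standard deviation across time points."""
    return sum(stdev(row) for row in fraction_rows) / len(fraction_rows)


def brute_gsea_es(n, hit_positions, scores, weight=1.0):
    """Running-sum enrichment score by direct iteration over the ranked list."""
    hits = set(hit_positions)
    k = len(hits)
    if k == n:
        return 1.0
    denom = sum(abs(scores[i]) ** weight for i in hits)
    running = 0.0
    hi, lo = 0.0, 0.0
    for i in range(n):
        if i in hits:
            running += (abs(scores[i]) ** weight / denom) if denom > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    # signed extremum; the positive side wins an (analytic) tie
    return hi if hi >= -lo - 1e-9 else lo


def brute_ks_d(a, b):
    """sup |ECDF_a - ECDF_b| over every pooled point."""
    d = 0.0
    for x in sorted(set(a) | set(b)):
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d


def brute_u_statistic(a, b):
    """#{a_i > b_j} + half-ties, by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_rank_sum_p(a, b):
    """Exact two-sided permutation p-value of the Mann-Whitney U via
    enumeration of every C(n, |a|) label assignment of the pooled values."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    dev_obs = abs(brute_u_statistic(a, b) - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(brute_u_statistic(sa, sb) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total
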