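"""Independent oracles, deliberately built from primitives only.

These re-derive the expected values of the statistical operations from
first principles (log-factorial enumeration, the error function, plain
loops) so that tests never compare an implementation against itself.
"""
import math


def hypergeom_log_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(X = a) for a 2x2 table with fixed margins."""
    n = row1 + row2

    def lchoose(n_, k_):
        return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                - math.lgamma(n_ - k_ + 1))

    return (lchoose(row1, a) + lchoose(row2, col1 - a)
            - lchoose(n, col1))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Point-probability rule: sum the probabilities of all tables at most
    as probable as the observed one (with the customary 1+1e-7 slack for
    floating-point ties).
    """
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    log_obs = hypergeom_log_pmf(a, row1, row2, col1)
    cutoff = log_obs + math.log1p(1e-7)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = hypergeom_log_pmf(x, row1, row2, col1)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(1.0, total)


def pearson_r(xs, ys) -> float:
    """Pearson correlation straight from the deviation formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def normal_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def normal_quantile(q: float) -> float:
    """Phi^-1 by bisection on the erf-based CDF."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if normal_cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def stouffer_two_sided(p_values, signs, ns) -> float:
    """Sample-size-weighted signed-Z combination, from the erf oracle."""
    zs = [s * normal_quantile(1.0 - p / 2.0) for p, s in zip(p_values, signs)]
    ws = [math.sqrt(n) for n in ns]
    Z = sum(w * z for w, z in zip(ws, zs)) / math.sqrt(sum(w * w for w in ws))
    return min(1.0, 2.0 * (1.0 - normal_cdf(abs(Z))))


def graph_degrees(pairs) -> dict:
    """Degree of every endpoint in an edge list of (a, b) pairs."""
    deg: dict = {}
    for a, b in pairs:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg
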