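"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid numpy/scipy and the package's own code paths:
pure-Python arithmetic over sorted lists and exhaustive enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations


def exact_mann_whitney_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all rank assignments.

    Valid for tie-free pooled samples: every C(n1+n2, n1) assignment of the
    pooled values to group A is equally likely under H0.
    """
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    n_le = n_ge = total = 0
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        n_le += u <= u_obs
        n_ge += u >= u_obs
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def quantile_type7(values, q: float) -> float:
    """R type-7 quantile via explicit index arithmetic on a sorted copy."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def tukey_oracle(values):
    """(range excluding outliers, sorted outliers) via the sorted-array route."""
    q1 = quantile_type7(values, 0.25)
    q3 = quantile_type7(values, 0.75)
    spread = q3 - q1
    lo, hi = q1 - 1.5 * spread, q3 + 1.5 * spread
    inside = [float(v) for v in values if lo <= v <= hi]
    outliers = sorted(float(v) for v in values if v < lo or v > hi)
    return max(inside) - min(inside), outliers


def ols_normal_equations(x, y):
    """Closed-form simple OLS slope/intercept/R² from the normal equations."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2
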