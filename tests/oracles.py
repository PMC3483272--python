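"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's optimized code paths: the Fisher
oracle enumerates hypergeometric tables with exact integer combinatorics,
and the sphere oracle rebuilds each sphere from scratch per call.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.spatial.distance import cdist


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration, exact arithmetic.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability is <= that of the observed table; the
    comparison is done on exact integer numerators (common denominator
    C(n, a+c)), so ties are decided exactly.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c)
    num = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= obs
    )
    return num / comb(n, c1)


def naive_sphere_members(
    center: int, W: float, coords: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Recompute one sphere from scratch: (members, radius, cohort_weight)."""
    d = cdist(coords[center : center + 1], coords)[0]
    order = np.argsort(d, kind="stable")
    cum = np.cumsum(weights[order])
    j = int(np.searchsorted(cum, W, side="left"))
    j = min(j, len(order) - 1)
    radius = float(d[order[j]])
    sd = d[order]
    j_end = int(np.searchsorted(sd, radius, side="right")) - 1
    return order[: j_end + 1], radius, float(cum[j_end])


def naive_sphere_table(
    members: np.ndarray, diseased: np.ndarray, weights: np.ndarray
) -> tuple[float, float, float, float]:
    """(a, b, c, d) of a sphere by sequential accumulation."""
    def seq(x):
        return float(np.cumsum(x)[-1]) if len(x) else 0.0

    w_m = weights[members]
    dis_m = diseased[members]
    a = seq(w_m * dis_m)
    c = seq(w_m * ~dis_m)
    tot_a = seq(weights * diseased)
    tot_c = seq(weights * ~diseased)
    return a, max(tot_a - a, 0.0), c, max(tot_c - c, 0.0)
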