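"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational
hypergeometric enumeration for Fisher's test, full-permutation enumeration
and the closed-form coupon-collector expectation for saturation curves.
"""

from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np


def fisher_two_sided_exact(n11: int, n12: int, n21: int, n22: int) -> Fraction:
    """Two-sided Fisher p by exact enumeration over tables with the observed
    margins, summing the hypergeometric probabilities of all tables no more
    probable than the observed one (exact rational arithmetic)."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    observed = pmf(n11)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        (pmf(k) for k in range(lo, hi + 1) if pmf(k) <= observed), Fraction(0)
    )


def saturation_curve_by_enumeration(matrix: np.ndarray) -> np.ndarray:
    """Expected cumulative discovery curve by enumerating all sample orders."""
    matrix = np.asarray(matrix, dtype=bool)
    n_loci, n_samples = matrix.shape
    total = np.zeros(n_samples)
    count = 0
    for order in permutations(range(n_samples)):
        seen: set[int] = set()
        cum = []
        for j in order:
            seen.update(np.flatnonzero(matrix[:, j]).tolist())
            cum.append(len(seen))
        total += cum
        count += 1
    return total / count


def saturation_curve_closed_form(matrix: np.ndarray) -> np.ndarray:
    """Closed-form expectation: at position j, a locus present in m of n
    samples has been seen unless all j visited samples avoid its carriers,
    so E[cum_j] = sum_l (1 - C(n - m_l, j) / C(n, j))."""
    matrix = np.asarray(matrix, dtype=bool)
    n = matrix.shape[1]
    occurrences = matrix.sum(axis=1)
    curve = []
    for j in range(1, n + 1):
        expected = sum(
            1 - comb(n - int(m), j) / comb(n, j) for m in occurrences if m >= 1
        )
        curve.append(expected)
    return np.array(curve)
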