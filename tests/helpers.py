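"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's own
numerics: plain-python median polish, comb-based hypergeometric tails, and
closed-form Hill algebra, so the tests compare two independent routes.
"""

from __future__ import annotations

import math
from statistics import median

import numpy as np


def brute_median_polish(matrix, n_sweeps: int = 200, tol: float = 1e-12):
    """Textbook row/column median-sweep loop on plain python lists.

    Stops by Tukey's criterion (change in the sum of absolute residuals
    below ``tol``), the convention of canonical implementations.
    """
    z = [list(map(float, row)) for row in matrix]
    nr, nc = len(z), len(z[0])
    prev = sum(abs(v) for row in z for v in row)
    for _ in range(n_sweeps):
        for i in range(nr):
            m = median(z[i])
            for j in range(nc):
                z[i][j] -= m
        for j in range(nc):
            m = median([z[i][j] for i in range(nr)])
            for i in range(nr):
                z[i][j] -= m
        cur = sum(abs(v) for row in z for v in row)
        if abs(prev - cur) < tol:
            break
        prev = cur
    return np.array(z)


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration (math.comb)."""
    n1, n2, k = a + b, c + d, a + c
    denom = math.comb(n1 + n2, k)
    a_min, a_max = max(0, k - n2), min(k, n1)
    probs = [
        math.comb(n1, x) * math.comb(n2, k - x) / denom
        for x in range(a_min, a_max + 1)
    ]
    p_obs = probs[a - a_min]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def fisher_two_sided_enum_all(n1: int, n2: int, k: int) -> np.ndarray:
    """Enumeration-based two-sided p for every table with the given margins."""
    denom = math.comb(n1 + n2, k)
    a_min, a_max = max(0, k - n2), min(k, n1)
    probs = [
        math.comb(n1, x) * math.comb(n2, k - x) / denom
        for x in range(a_min, a_max + 1)
    ]
    return np.array(
        [min(1.0, sum(p for p in probs if p <= po * (1 + 1e-7))) for po in probs]
    )


def hill_viability(d, top, bottom, ic50, hill):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def hill_inverse_dose(effect, top, bottom, ic50, hill):
    """Dose at which the Hill curve's inhibition equals ``effect``."""
    v = 1.0 - effect
    return ic50 * ((top - v) / (v - bottom)) ** (1.0 / hill)
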