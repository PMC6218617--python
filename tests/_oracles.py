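"""Independent brute-force oracles, written before the optimized code paths.

Each function re-derives a quantity by exhaustive enumeration in plain
Python so agreement with the package's implementations is a genuine
cross-check, not a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sample_entropy_bruteforce(x, m: int, r: float) -> float:
    """Exhaustive template-counting sample entropy.

    Pairs (i, j), i < j, over the first N-m template start positions; a
    match is Chebyshev distance strictly below r; SE = -ln(A/B); NaN when
    either count is zero.
    """
    x = list(map(float, x))
    n = len(x)
    a = b = 0
    for i in range(n - m - 1):
        for j in range(i + 1, n - m):
            if all(abs(x[i + k] - x[j + k]) < r for k in range(m)):
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def clustering_coefficient_bruteforce(W, j: int) -> float:
    """Triple loop over ordered neighbor pairs; weighted-degree denominator."""
    n = len(W)
    total = 0.0
    for i in range(n):
        for m_ in range(n):
            if i == j or m_ == j or i == m_:
                continue
            total += (W[j][i] * W[i][m_] * W[j][m_]) ** (1.0 / 3.0)
    k = sum(W[j][i] for i in range(n))
    denom = k * (k - 1.0)
    if denom <= 0:
        return float("nan")
    return total / denom


def shortest_path_bruteforce(W, i: int, j: int, f=lambda w: 1.0 / w) -> float:
    """Minimum f-length over every simple path from i to j (exhaustive)."""
    n = len(W)
    others = [v for v in range(n) if v not in (i, j)]
    best = math.inf
    for k in range(len(others) + 1):
        for mid in itertools.permutations(others, k):
            path = (i, *mid, j)
            length = 0.0
            ok = True
            for u, v in zip(path, path[1:]):
                if W[u][v] <= 0:
                    ok = False
                    break
                length += f(W[u][v])
            if ok:
                best = min(best, length)
    return best


def global_efficiency_bruteforce(W, f=lambda w: 1.0 / w) -> float:
    """GE from exhaustively enumerated shortest paths (ordered pairs)."""
    n = len(W)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = shortest_path_bruteforce(W, i, j, f)
            if math.isfinite(d) and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def plv_bruteforce(phase_a, phase_b) -> float:
    """Phase-locking value by direct trigonometric accumulation."""
    cs = sum(math.cos(a - b) for a, b in zip(phase_a, phase_b))
    sn = sum(math.sin(a - b) for a, b in zip(phase_a, phase_b))
    n = len(phase_a)
    return math.hypot(cs / n, sn / n)


def random_symmetric_weights(n: int, rng: np.random.Generator,
                             zero_frac: float = 0.2) -> np.ndarray:
    """Random graph weights in [0, 1], symmetric, zero diagonal, with a
    fraction of edges zeroed out."""
    W = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.uniform(size=(n, n)) < zero_frac
    W[mask] = 0.0
    W = np.triu(W, 1)
    W = W + W.T
    return W
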