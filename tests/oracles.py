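"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are checking.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(a, b, c, d) -> Fraction:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] as an exact rational.

    Direct enumeration of the hypergeometric pmf with integer binomials.
    """
    n_total = a + b + c + d
    n_annotated = a + c
    n_drawn = a + b
    den = comb(n_total, n_drawn)
    num = 0
    for x in range(a, min(n_annotated, n_drawn) + 1):
        num += comb(n_annotated, x) * comb(n_total - n_annotated, n_drawn - x)
    return Fraction(num, den)


def prufer_decode(seq, n):
    """Edge set of the labeled tree with Prufer sequence ``seq`` on n nodes."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((min(leaf, v), max(leaf, v)))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    rest = [v for v in range(n) if degree[v] == 1]
    edges.append((rest[0], rest[1]))
    return edges


def min_spanning_weight_bruteforce(weights: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhausting all labeled trees."""
    n = weights.shape[0]
    if n == 2:
        return float(weights[0, 1])
    best = np.inf
    for seq in product(range(n), repeat=n - 2):
        total = sum(weights[i, j] for i, j in prufer_decode(seq, n))
        best = min(best, total)
    return float(best)
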