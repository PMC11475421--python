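"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or closed form,
never by calling the implementation under test.
"""

from itertools import permutations

import numpy as np


def brute_force_assignment(values, feasible):
    """Minimum-total-cost one-to-one assignment by full enumeration.

    Enumerates every injective mapping of rows to columns (all subset
    sizes), skipping infeasible cells. Returns (best_cost, best_matches)
    where matches is a frozenset of (i, j). Only viable for
    max(N, M) <= ~6.
    """
    n, m = values.shape
    best_cost, best = 0.0, frozenset()
    rows = list(range(n))
    cols = list(range(m))
    k_max = min(n, m)
    from itertools import combinations

    for k in range(1, k_max + 1):
        for rsub in combinations(rows, k):
            for csub in permutations(cols, k):
                if any(not feasible[i, j] for i, j in zip(rsub, csub)):
                    continue
                cost = sum(values[i, j] for i, j in zip(rsub, csub))
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best = frozenset(zip(rsub, csub))
    return best_cost, best


def scalar_kalman_update(x, p, z, r):
    """Closed-form 1-D Kalman update."""
    k = p / (p + r)
    return x + k * (z - x), (1 - k) * p


def iou_loop(box_a, box_b):
    """IoU by explicit geometry, no vectorization."""
    ax1, ay1, aw, ah = box_a
    bx1, by1, bw, bh = box_b
    ax2, ay2 = ax1 + aw, ay1 + ah
    bx2, by2 = bx1 + bw, by1 + bh
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (aw * ah + bw * bh - inter)


def best_id_bijection_idtp(overlap):
    """Maximum total overlap over all injective id mappings, by
    enumeration (small instances only)."""
    n, m = overlap.shape
    best = 0
    k = min(n, m)
    from itertools import combinations

    for kk in range(1, k + 1):
        for rsub in combinations(range(n), kk):
            for csub in permutations(range(m), kk):
                tot = sum(overlap[i, j] for i, j in zip(rsub, csub))
                best = max(best, tot)
    return best
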