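"""Independent brute-force oracles shared across the test suite.

These deliberately avoid the vectorized implementation paths they are
used to check.
"""

import math

import numpy as np


def box_count_oracle(mask, eps):
    """Exhaustive per-box scan (top-left anchored, partial edge boxes)."""
    h, w = mask.shape
    n = 0
    for r0 in range(0, h, eps):
        for c0 in range(0, w, eps):
            if mask[r0:r0 + eps, c0:c0 + eps].any():
                n += 1
    return n


def morans_oracle(values, row_standardized=True, scheme="rook"):
    """Brute-force O(N^2) double sum over all lattice cell pairs."""
    x = np.asarray(values, dtype=float)
    rows, cols = x.shape
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    flat = x.ravel()
    z = flat - flat.mean()
    n = len(coords)
    W = np.zeros((n, n))
    for i, (r1, c1) in enumerate(coords):
        for j, (r2, c2) in enumerate(coords):
            if i == j:
                continue
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            rook = dr + dc == 1
            queen = max(dr, dc) == 1
            if (scheme == "rook" and rook) or (scheme == "queen" and queen):
                W[i, j] = 1.0
    if row_standardized:
        W = W / W.sum(axis=1, keepdims=True)
    num = z @ W @ z
    return (n / W.sum()) * num / (z @ z)


def tucker(a, b):
    """Tucker congruence (cosine similarity) of two loading vectors."""
    return abs(a @ b) / math.sqrt((a @ a) * (b @ b))


def best_congruences(truth, estimate):
    """Greedy column matching of an estimated loading matrix to the
    planted one; returns one congruence per planted factor."""
    used, out = set(), []
    for j in range(truth.shape[1]):
        c, m = max((tucker(truth[:, j], estimate[:, m]), m)
                   for m in range(estimate.shape[1]) if m not in used)
        out.append(c)
        used.add(m)
    return out
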