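"""Straight-line brute-force reference for the iterative scoring recurrence.

Deliberately unvectorized: scalar loops, literal formulas, no shortcuts.
Serves as the independent oracle the optimized implementation is checked
against on small instances.
"""

from __future__ import annotations

import math


def wpcc_ref(x, y, w):
    """Scalar weighted Pearson correlation."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y))
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x))
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y))
    if vx <= 0 or vy <= 0:
        return 0.0
    r = cov / math.sqrt(vx * vy)
    return max(-1.0, min(1.0, r))


def context_ref(rows, w):
    """Pairwise clipped weighted correlations of a list of rows; diagonal 1."""
    n = len(rows)
    R = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                R[i][j] = 1.0
            else:
                R[i][j] = max(0.0, wpcc_ref(rows[i], rows[j], w))
    return R


def inner_ref(c1, c2, w_init, tol, max_iter):
    """Fixed-point loop: scores = rowwise wPCC, next weights = clipped scores."""
    w = list(w_init)
    s = [0.0] * len(w)
    for _ in range(max_iter):
        s = [wpcc_ref(c1[i], c2[i], w) for i in range(len(w))]
        w_new = [max(0.0, si) for si in s]
        if sum(w_new) <= 0:
            raise ValueError("degenerate comparison")
        delta = max(abs(a - b) for a, b in zip(w_new, w))
        w = w_new
        if delta < tol:
            break
    return w, s


def run_ref(ms1, ms2, gs1, gs2, inner_tol=1e-4, outer_tol=1e-4, max_inner=100, max_outer=50):
    """Literal outer/inner-loop recurrence on plain nested lists.

    ms1/ms2 are mark-scaled matrices (rows = genes), gs1/gs2 the
    gene-scaled ones.  Inner loops warm-start from the weights carried
    over from the previous outer iteration, matching the implementation
    under test.  Returns the per-outer-iteration weight trace and the
    final raw scores.
    """
    n_genes = len(ms1)
    n_marks = len(ms1[0])
    w_m = [1.0] * n_marks
    w_g = [1.0] * n_genes
    trace = []
    s_g = s_m = None
    for _ in range(max_outer):
        G1 = context_ref(ms1, w_m)
        G2 = context_ref(ms2, w_m)
        w_g_new, s_g = inner_ref(G1, G2, w_g, inner_tol, max_inner)
        cols1 = [[gs1[i][j] for i in range(n_genes)] for j in range(n_marks)]
        cols2 = [[gs2[i][j] for i in range(n_genes)] for j in range(n_marks)]
        M1 = context_ref(cols1, w_g_new)
        M2 = context_ref(cols2, w_g_new)
        w_m_new, s_m = inner_ref(M1, M2, w_m, inner_tol, max_inner)
        delta = max(
            max(abs(a - b) for a, b in zip(w_g_new, w_g)),
            max(abs(a - b) for a, b in zip(w_m_new, w_m)),
        )
        w_g, w_m = w_g_new, w_m_new
        trace.append({"w_g": list(w_g), "w_m": list(w_m)})
        if delta < outer_tol:
            break
    return trace, s_g, s_m
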