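"""Independent literal transcriptions of the global and local statistics.

Deliberately naive double loops over dense weight matrices, sharing no code
with the package implementation; used as referees in oracle-equivalence
tests.
"""

import numpy as np


def moran_brute(values, w_dense):
    """Global Moran's I: Dn * sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S0 * sum_j (x_j - xbar)^2)."""
    x = np.asarray(values, float)
    w_dense = np.asarray(w_dense, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w_dense[i, j]
    den = sum((x[j] - xbar) ** 2 for j in range(n))
    return n * num / (s0 * den)


def gi_star_brute(values, w_dense):
    """Getis-Ord Gi* per cell, transcribed term by term.

    Gi* = (sum_j w_ij x_j - xbar sum_j w_ij)
          / (S * sqrt((n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1)))
    S = sqrt((1/n) sum_j x_j^2 - xbar^2)
    """
    x = np.asarray(values, float)
    w_dense = np.asarray(w_dense, float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(sum(x[j] ** 2 for j in range(n)) / n - xbar**2)
    out = np.empty(n)
    for i in range(n):
        wsum = sum(w_dense[i, j] for j in range(n))
        wsq = sum(w_dense[i, j] ** 2 for j in range(n))
        num = sum(w_dense[i, j] * x[j] for j in range(n)) - xbar * wsum
        bracket = (n * wsq - wsum**2) / (n - 1)
        out[i] = num / (s * np.sqrt(bracket)) if bracket > 0 else np.nan
    return out


def neighbors_brute(points, d):
    """All-pairs inclusive distance-band neighbor lists."""
    pts = np.asarray(points, float)
    n = len(pts)
    out = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(*(pts[i] - pts[j])) <= d:
                out[i].add(j)
    return out


def bh_adjust_brute(p):
    """Benjamini-Hochberg step-up adjusted p-values, hand-rolled."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def pearson_r2_brute(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    return r**2
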