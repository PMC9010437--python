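"""Independent brute-force oracles used to cross-check the estimators.

Deliberately written with plain Python loops and no shared code with the
package, so they stay an independent check on the vectorised routines.
"""

import numpy as np


def quasi_independent_oracle(row, col, tol=1e-10, max_iter=200000):
    """Brute-force fit of one birthplace slice: maximal fixed diagonal, then
    element-by-element Sinkhorn refinement of the off-diagonal cells."""
    m = len(row)
    diag = [min(row[i], col[i]) for i in range(m)]
    r = [row[i] - diag[i] for i in range(m)]
    c = [col[j] - diag[j] for j in range(m)]
    M = [[0.0 if i == j else 1.0 for j in range(m)] for i in range(m)]
    for _ in range(max_iter):
        worst = 0.0
        for i in range(m):
            s = sum(M[i])
            if s > 0:
                f = r[i] / s
                for j in range(m):
                    M[i][j] *= f
            elif r[i] == 0:
                for j in range(m):
                    M[i][j] = 0.0
        for j in range(m):
            s = sum(M[i][j] for i in range(m))
            if s > 0:
                f = c[j] / s
                for i in range(m):
                    M[i][j] *= f
            worst = max(worst, abs(sum(M[i][j] for i in range(m)) - c[j]))
        for i in range(m):
            worst = max(worst, abs(sum(M[i]) - r[i]))
        if worst < tol:
            break
    for i in range(m):
        M[i][i] = diag[i]
    return np.array(M)


def random_balanced_margins(rng, m):
    """Random positive row/column margin vectors with equal totals."""
    row = rng.uniform(1.0, 100.0, size=m)
    col = rng.uniform(1.0, 100.0, size=m)
    col *= row.sum() / col.sum()
    return row, col


def percentile_oracle(values, q):
    """Sort-based percentile with linear interpolation between order stats."""
    v = sorted(values)
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])
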