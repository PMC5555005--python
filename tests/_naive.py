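"""Deliberately simple reference implementations used as test oracles.

Everything here is written in the most direct way possible (explicit
loops, per-column least squares, scipy minimisation) and stays
independent of the package's vectorised code paths.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def naive_offset(loss_fn, y):
    """Numerically minimise sum_i rho(y_i, c) over the constant c."""
    res = minimize_scalar(lambda c: float(np.sum(loss_fn(y, np.full(len(y), c)))))
    return res.x


def naive_boost_path(X, y, family, nu, m):
    """Literal loop-based componentwise boosting; returns (offset, path, coef).

    path is a list of (j_star, b) pairs; family is 'gaussian'/'binomial'.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)

    if family == "gaussian":
        offset = float(np.mean(y))

        def grad(f):
            return y - f
    else:
        ybar = float(np.mean(y))
        offset = float(np.log(ybar / (1 - ybar)))

        def grad(f):
            return y - 1.0 / (1.0 + np.exp(-f))

    f = np.full(n, offset)
    coef = np.zeros(p)
    path = []
    for _ in range(m):
        u = grad(f)
        best_j, best_b, best_sse = None, None, np.inf
        for j in range(p):
            xj = Xc[:, j]
            ss = float(xj @ xj)
            if ss == 0.0:
                continue
            b = float(xj @ u) / ss
            sse = float(np.sum((u - b * xj) ** 2))
            if best_j is None or sse < best_sse - 1e-12 * max(1.0, best_sse):
                best_j, best_b, best_sse = j, b, sse
        coef[best_j] += nu * best_b
        f = f + nu * best_b * Xc[:, best_j]
        path.append((best_j, best_b))
    return offset, path, coef
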