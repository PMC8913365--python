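"""Independent oracles used by the test suite.

The brute-force non-negative least-squares solver enumerates every active
set (all 2^p column subsets), solves each unconstrained subproblem, keeps
the feasible (all-non-negative) candidates and returns the best. By the
KKT conditions the constrained optimum's support appears among the
feasible subsets, so the minimum over them is the exact NNLS optimum. It
shares no code path with the package's active-set solver.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_nnls_intercept(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact solution of min ||y - X b - g||^2 s.t. b >= 0, g free.

    Returns (beta, gamma, objective).
    """
    n, p = X.shape
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    best_obj = float(yc @ yc)
    best_beta = np.zeros(p)
    for k in range(1, p + 1):
        for idx in combinations(range(p), k):
            sub = Xc[:, idx]
            coef, *_ = np.linalg.lstsq(sub, yc, rcond=None)
            if np.all(coef >= -1e-12):
                r = yc - sub @ coef
                obj = float(r @ r)
                if obj < best_obj:
                    best_obj = obj
                    best_beta = np.zeros(p)
                    best_beta[list(idx)] = np.clip(coef, 0.0, None)
    gamma = float(y_mean - x_mean @ best_beta)
    return best_beta, gamma, best_obj
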