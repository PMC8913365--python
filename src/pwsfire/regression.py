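"""Non-negative distributed-lag regression.

The plant-water-sensitivity statistic is the sum of the slopes of a linear
regression of live-fuel-moisture anomalies on lagged dead-fuel-moisture
anomalies, with every slope constrained to be non-negative (a drier
atmosphere is never allowed to make fuels wetter) and an unconstrained
intercept. The intercept is handled exactly by centring: for any fixed
slope vector the optimal intercept is ``mean(y) - mean(X) @ beta``, so
solving NNLS on the centred problem yields the constrained optimum of the
full problem.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = ["NonNegativeLagRegressor"]


class NonNegativeLagRegressor(RegressorMixin, BaseEstimator):
    """Least squares with non-negative coefficients and a free intercept.

    Minimises ``sum((y - X @ beta - gamma)**2)`` subject to ``beta >= 0``
    with ``gamma`` unconstrained, via active-set non-negative least squares
    on the centred design. Deterministic; exact for the small (<= 11 column)
    designs used in the lag analysis.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Non-negative slopes.
    intercept_ : float
        Unconstrained intercept.
    r2_ : float
        In-sample coefficient of determination against the mean of ``y``
        (never negative here because the intercept-only model is nested).
    zero_fraction_ : float
        Share of coefficients exactly zero (active constraints).
    rank_deficient_ : bool
        True when the design had deficient column rank; the reported
        solution is then one (minimum-norm within the active set) of the
        non-unique minimisers.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=1)
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean
        yc = y - y_mean
        if not np.any(np.abs(Xc) > self.tol):
            beta = np.zeros(X.shape[1])
        else:
            beta, _ = nnls(Xc, yc)
        self.coef_ = beta
        self.intercept_ = y_mean - float(x_mean @ beta)
        sst = float(yc @ yc)
        resid = yc - Xc @ beta
        ssr = float(resid @ resid)
        self.r2_ = max(0.0, 1.0 - ssr / sst) if sst > 0 else 0.0
        self.zero_fraction_ = float(np.mean(beta == 0.0))
        self.n_obs_ = X.shape[0]
        self.rank_deficient_ = bool(np.linalg.matrix_rank(Xc) < X.shape[1])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_
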