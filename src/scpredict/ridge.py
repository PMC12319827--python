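"""Ridge regression with an unpenalized intercept, solved in closed form.

The model minimizes  sum_i (y_i - beta' x_i - b)^2 + alpha * ||beta||^2
over (beta, b). Centering features and targets by their training means
decouples the intercept: beta solves (Xc' Xc + alpha I) beta = Xc' yc and
b = mean(y) - mean(x)' beta.

``ridge_predict_path`` evaluates the same closed form for a whole grid of
alphas from one eigendecomposition (primal or dual depending on the
n-samples / n-features ratio) — used heavily inside the inner
cross-validation loop and tested to agree with the estimator exactly.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

# l2-regularization grid evaluated in the inner cross-validation loop
DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    0.001, 0.01, 1, 10, 50, 100, 500, 1000, 5000, 10000,
)


class RidgeRegressor(RegressorMixin, BaseEstimator):
    """Closed-form l2-penalized linear regression, intercept unpenalized.

    Parameters
    ----------
    alpha : float >= 0, regularization strength.
    singular : {'raise', 'lstsq'}
        Behaviour at alpha = 0 with collinear features: 'raise' propagates
        the singular-system error, 'lstsq' returns the minimum-norm
        least-squares solution.

    Attributes
    ----------
    coef_ : (n_features,) regression coefficients.
    intercept_ : float.
    """

    def __init__(self, alpha: float = 1.0, singular: str = "raise"):
        self.alpha = alpha
        self.singular = singular

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.singular not in ("raise", "lstsq"):
            raise ValueError("singular must be 'raise' or 'lstsq'")
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        xc = X - x_mean
        yc = y - y_mean
        if self.alpha == 0 and self.singular == "lstsq":
            coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        else:
            k = X.shape[1]
            gram = xc.T @ xc + self.alpha * np.eye(k)
            try:
                coef = scipy.linalg.solve(
                    gram, xc.T @ yc, assume_a="pos" if self.alpha > 0 else "gen"
                )
            except np.linalg.LinAlgError:
                raise
            except scipy.linalg.LinAlgError:
                raise
        self.coef_ = coef
        self.intercept_ = float(y_mean - x_mean @ coef)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def fit_ridge(X, y, alpha: float, singular: str = "raise") -> RidgeRegressor:
    """Functional wrapper over RidgeRegressor.fit."""
    return RidgeRegressor(alpha=alpha, singular=singular).fit(X, y)


def ridge_objective(X, y, coef, intercept, alpha) -> float:
    """The penalized least-squares objective (for oracle comparisons)."""
    resid = np.asarray(y) - np.asarray(X) @ coef - intercept
    return float(resid @ resid + alpha * coef @ coef)


def ridge_predict_path(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, alphas
) -> np.ndarray:
    """Test predictions for every alpha in one pass; rows match ``alphas``.

    Equivalent to fitting RidgeRegressor(alpha).predict(Xte) per alpha but
    sharing one eigendecomposition. Uses the primal form (eigh of X'X) when
    features are fewer than samples, otherwise the dual form (eigh of XX'),
    which coincide for alpha > 0.
    """
    Xtr = np.asarray(Xtr, dtype=float)
    Xte = np.asarray(Xte, dtype=float)
    ytr = np.asarray(ytr, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    if (alphas <= 0).any():
        raise ValueError("the alpha path requires strictly positive alphas")
    n, k = Xtr.shape
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    xc = Xtr - x_mean
    yc = ytr - y_mean
    xte_c = Xte - x_mean

    if k <= n:
        lam, v = scipy.linalg.eigh(xc.T @ xc)
        lam = np.maximum(lam, 0.0)
        rhs = v.T @ (xc.T @ yc)  # (k,)
        coefs = v @ (rhs[:, None] / (lam[:, None] + alphas[None, :]))  # (k, n_alphas)
    else:
        lam, q = scipy.linalg.eigh(xc @ xc.T)
        lam = np.maximum(lam, 0.0)
        rhs = q.T @ yc  # (n,)
        dual = q @ (rhs[:, None] / (lam[:, None] + alphas[None, :]))  # (n, n_alphas)
        coefs = xc.T @ dual
    preds = xte_c @ coefs + y_mean  # (n_te, n_alphas)
    return preds.T


def pearson_r(yhat, y, return_degenerate: bool = False):
    """Pearson correlation between predictions and observed targets.

    A constant vector makes the correlation undefined; the convention here
    is to return 0 and (optionally) flag the fold as degenerate, so fold
    averages stay defined even under extreme regularization.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape or yhat.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if yhat.size < 2:
        raise ValueError("correlation needs at least 2 values")
    a = yhat - yhat.mean()
    b = y - y.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return (0.0, True) if return_degenerate else 0.0
    r = float(np.clip((a @ b) / denom, -1.0, 1.0))
    return (r, False) if return_degenerate else r
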