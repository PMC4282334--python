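"""Maximum-likelihood network autocorrelation models.

Two classical models carry network dependence in a regression, both
analogues of spatial econometric models:

*network effects* (autoregressive in the response, spatial-lag analogue)

    Y = rho * W1 Y + X beta + eps

*network disturbances* (autoregressive in the error, spatial-error analogue)

    Y = X beta + delta,   delta = rho * W2 delta + eps

with eps ~ N(0, sigma2 I) and W a row-standardized connection matrix.  A
combined model applies both transforms with separate parameters rho1, rho2.
If rho = 0 or W = 0 each model reduces to ordinary least squares.

Estimation profiles beta and sigma2 out analytically and maximizes the
profile log-likelihood over rho (a bounded 1-D search; quasi-Newton over
(rho1, rho2) for the combined model).  Standard errors come from the
inverse observed information (numerical Hessian of the full log-likelihood
at the optimum).  Model fit is reported as AIC = 2k - 2*loglik with
k = p + (#rho) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize, minimize_scalar
from scipy.sparse.linalg import splu
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .weights import WeightMatrix

__all__ = ["NamFit", "NetworkAutocorrelation", "loglik_nam", "fit_nam"]

_RHO_BOUND = 0.9999  # open interval (-1, 1) for row-standardized W

MODEL_TYPES = ("effects", "disturbances", "combined")


def _as_sparse(W) -> sp.csr_matrix:
    if isinstance(W, WeightMatrix):
        W = W.W
    return sp.csr_matrix(W)


def _logdet_I_minus_rhoW(W: sp.csr_matrix, rho: float, method: str = "lu") -> float:
    """log det(I - rho W); raises if the transform is singular."""
    n = W.shape[0]
    if rho == 0.0 or W.nnz == 0:
        return 0.0
    A = sp.identity(n, format="csc") - rho * W.tocsc()
    if method == "lu":
        lu = splu(A, permc_spec="NATURAL", options=dict(SymmetricMode=False))
        diagU = lu.U.diagonal()
        diagL = lu.L.diagonal()
        if (diagU == 0).any():
            raise np.linalg.LinAlgError(f"I - rho W singular at rho={rho}")
        # row/col permutations have det +-1; for a row-standardized W on
        # (-1, 1) the determinant is positive, so take |.| of the product
        sign_logdet = np.sum(np.log(np.abs(diagU))) + np.sum(np.log(np.abs(diagL)))
        return float(sign_logdet)
    raise ValueError(f"unknown logdet method {method!r}")


def loglik_nam(model_type, rho, beta, sigma2, y, X, W1=None, W2=None) -> float:
    """Log-likelihood of a network autocorrelation model at given parameters.

    ``rho`` is a scalar for the effects/disturbances models and a pair
    (rho1, rho2) for the combined model.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    beta = np.asarray(beta, float).ravel()
    n = y.shape[0]
    logdet = 0.0
    if model_type == "effects":
        W1 = _as_sparse(W1)
        logdet += _logdet_I_minus_rhoW(W1, float(rho))
        resid = y - float(rho) * (W1 @ y) - X @ beta
    elif model_type == "disturbances":
        W2 = _as_sparse(W2)
        logdet += _logdet_I_minus_rhoW(W2, float(rho))
        r = y - X @ beta
        resid = r - float(rho) * (W2 @ r)
    else:
        rho1, rho2 = float(rho[0]), float(rho[1])
        W1, W2 = _as_sparse(W1), _as_sparse(W2)
        logdet += _logdet_I_minus_rhoW(W1, rho1)
        logdet += _logdet_I_minus_rhoW(W2, rho2)
        yt = y - rho1 * (W1 @ y)
        r = yt - X @ beta
        resid = r - rho2 * (W2 @ r)
    return float(
        -0.5 * n * np.log(2 * np.pi * sigma2)
        + logdet
        - 0.5 * (resid @ resid) / sigma2
    )


@dataclass
class NamFit:
    """Result of a maximum-likelihood network autocorrelation fit."""

    model_type: str
    rho: np.ndarray  # shape (1,) or (2,)
    rho_se: np.ndarray
    beta: np.ndarray
    beta_se: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    boundary: bool


def _profile(model_type, rho, y, X, W1, W2):
    """beta-hat, sigma2-hat and profile loglik at fixed rho."""
    n = y.shape[0]
    if model_type == "effects":
        yt = y - rho * (W1 @ y)
        Xt = X
        logdet = _logdet_I_minus_rhoW(W1, rho)
    elif model_type == "disturbances":
        A = sp.identity(n, format="csr") - rho * W2
        yt = A @ y
        Xt = A @ X
        logdet = _logdet_I_minus_rhoW(W2, rho)
    else:
        rho1, rho2 = rho
        A2 = sp.identity(n, format="csr") - rho2 * W2
        y1 = y - rho1 * (W1 @ y)
        yt = A2 @ y1
        Xt = A2 @ X
        logdet = _logdet_I_minus_rhoW(W1, rho1) + _logdet_I_minus_rhoW(W2, rho2)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return beta, sigma2, ll


def _num_hessian(f, x0, eps=1e-5):
    """Central-difference Hessian of scalar f at x0."""
    x0 = np.asarray(x0, float)
    m = x0.size
    H = np.empty((m, m))
    h = eps * np.maximum(np.abs(x0), 1.0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


class NetworkAutocorrelation(RegressorMixin, BaseEstimator):
    """Network effects / disturbances / combined model, fitted by ML.

    Parameters
    ----------
    model_type : {"effects", "disturbances", "combined"}
    W1, W2 : sparse matrix or WeightMatrix
        Row-standardized connection matrices for the response and error
        autocorrelation respectively; only the one(s) the model uses are
        required (``W2`` defaults to ``W1`` for the combined model).
    rho_bound : float, default 0.9999
        Half-width of the open search interval for each rho.

    Attributes
    ----------
    rho_ : ndarray           estimated autocorrelation parameter(s)
    rho_se_ : ndarray        standard error(s) from the observed information
    coef_, coef_se_ : ndarray   regression coefficients and SEs
    sigma2_ : float          ML error variance
    loglik_, aic_ : float    maximized log-likelihood and AIC
    boundary_ : bool         True if the optimum lies at the search boundary
    """

    def __init__(self, model_type="disturbances", W1=None, W2=None,
                 rho_bound=_RHO_BOUND):
        self.model_type = model_type
        self.W1 = W1
        self.W2 = W2
        self.rho_bound = rho_bound

    def fit(self, X, y):
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if n <= p:
            raise ValueError("need n > p")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed design X is rank deficient")
        W1 = _as_sparse(self.W1) if self.W1 is not None else None
        W2 = _as_sparse(self.W2) if self.W2 is not None else None
        if self.model_type == "effects" and W1 is None:
            raise ValueError("effects model requires W1")
        if self.model_type == "disturbances" and W2 is None:
            if W1 is None:
                raise ValueError("disturbances model requires W2")
            W2 = W1
        if self.model_type == "combined":
            if W1 is None:
                raise ValueError("combined model requires W1")
            if W2 is None:
                W2 = W1
        bound = self.rho_bound

        if self.model_type in ("effects", "disturbances"):
            res = minimize_scalar(
                lambda r: -_profile(self.model_type, r, y, X, W1, W2)[2],
                bounds=(-bound, bound),
                method="bounded",
                options={"xatol": 1e-7},
            )
            rho = np.array([res.x])
            converged = bool(res.success)
        else:
            # start from the two one-parameter fits
            r1 = minimize_scalar(
                lambda r: -_profile("effects", r, y, X, W1, None)[2],
                bounds=(-bound, bound), method="bounded",
                options={"xatol": 1e-6},
            ).x
            r2 = minimize_scalar(
                lambda r: -_profile("disturbances", r, y, X, None, W2)[2],
                bounds=(-bound, bound), method="bounded",
                options={"xatol": 1e-6},
            ).x
            res = minimize(
                lambda r: -_profile("combined", r, y, X, W1, W2)[2],
                x0=np.array([r1, r2]),
                method="L-BFGS-B",
                bounds=[(-bound, bound)] * 2,
            )
            rho = np.asarray(res.x)
            converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"ML optimization failed: {res}")

        rho_arg = tuple(rho) if self.model_type == "combined" else float(rho[0])
        beta, sigma2, ll = _profile(self.model_type, rho_arg, y, X, W1, W2)
        boundary = bool(np.any(np.abs(rho) > bound - 1e-4))

        # observed information from the full (rho, beta, sigma2) likelihood
        n_rho = rho.size

        def negll(theta):
            r = theta[:n_rho]
            b = theta[n_rho:n_rho + p]
            s2 = theta[-1]
            if s2 <= 0:
                return np.inf
            rr = tuple(r) if self.model_type == "combined" else float(r[0])
            return -loglik_nam(self.model_type, rr, b, s2, y, X, W1, W2)

        theta_hat = np.concatenate([rho, beta, [sigma2]])
        H = _num_hessian(negll, theta_hat)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(theta_hat.size, np.nan)

        k = p + n_rho + 1
        self.n_features_in_ = p
        self.rho_ = rho
        self.rho_se_ = se[:n_rho]
        self.coef_ = beta
        self.coef_se_ = se[n_rho:n_rho + p]
        self.sigma2_ = sigma2
        self.loglik_ = ll
        self.aic_ = 2.0 * k - 2.0 * ll
        self.boundary_ = boundary
        self.converged_ = converged
        self.n_obs_ = n
        self._W1, self._W2 = W1, W2
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_

    def result(self) -> NamFit:
        check_is_fitted(self, "coef_")
        return NamFit(
            model_type=self.model_type,
            rho=self.rho_,
            rho_se=self.rho_se_,
            beta=self.coef_,
            beta_se=self.coef_se_,
            sigma2=self.sigma2_,
            loglik=self.loglik_,
            aic=self.aic_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            boundary=self.boundary_,
        )


def fit_nam(y, X, W1=None, W2=None, model_type="disturbances") -> NamFit:
    """Fit a network autocorrelation model and return the result record."""
    est = NetworkAutocorrelation(model_type=model_type, W1=W1, W2=W2)
    est.fit(X, y)
    return est.result()
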