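"""Gibbs sampling for multiple-membership multiple-classification models.

The model for a continuous response y is

    y_i = x_i' beta + sum_k sum_{j in group_k(i)} w_ij^(k) u_j^(k) + e_i,

    u_j^(k) ~ N(0, sigma2_k),   e_i ~ N(0, sigma2_e),

with an arbitrary number of classifications k (school, area, ego-net,
dyad/clique sets ...), each linked to the response through an n x K_k weight
matrix Z_k.  Random-effect sets are a priori independent across
classifications.  Priors: flat on beta, Gamma(a, b) on every precision
(a = b = 0.001 by default, the conventional diffuse choice).

The full conditionals are conjugate, so estimation is by Gibbs sampling:

    beta | .      ~ N( (X'X)^-1 X' r,  sigma2_e (X'X)^-1 ),  r the partial
                    residual with all random-effect contributions removed;
    u_k  | .      ~ N( Q_k^-1 Z_k' r_k / sigma2_e, Q_k^-1 ),
                    Q_k = Z_k'Z_k / sigma2_e + I / sigma2_k;
    1/sigma2_k | . ~ Gamma(a + K_k/2, b + u_k'u_k / 2);
    1/sigma2_e | . ~ Gamma(a + n/2,  b + SSR/2).

Model fit is summarized by the deviance information criterion
DIC = 2 * mean(D) - D(theta_bar) with the plug-in at the posterior means of
all parameters including the random effects, and pD = mean(D) - D(theta_bar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .weights import WeightMatrix

__all__ = [
    "MMMCRegressor", "MmcmSpec", "fit_mmmc", "dic", "posterior_summary",
    "gaussian_deviance", "dic_from_deviances",
]


def gaussian_deviance(y, mu, sigma2_e) -> float:
    """D(theta) = n log(2 pi sigma2_e) + sum (y_i - mu_i)^2 / sigma2_e."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    n = y.size
    r = y - mu
    return float(n * np.log(2 * np.pi * sigma2_e) + (r @ r) / sigma2_e)


def dic_from_deviances(deviance_chain, deviance_at_posterior_mean) -> tuple[float, float]:
    """(DIC, pD) = (2 mean(D) - D(theta_bar), mean(D) - D(theta_bar))."""
    deviance_chain = np.asarray(deviance_chain, float)
    if deviance_chain.size == 0:
        raise ValueError("empty deviance chain")
    mean_D = float(deviance_chain.mean())
    pd_ = mean_D - deviance_at_posterior_mean
    return 2.0 * mean_D - deviance_at_posterior_mean, pd_


def _as_sparse(Z) -> sp.csr_matrix:
    if isinstance(Z, WeightMatrix):
        return Z.W
    return sp.csr_matrix(Z)


@dataclass
class MmcmSpec:
    """Model definition: fixed part plus an ordered list of classifications."""

    classifications: Sequence  # (name, WeightMatrix | sparse) pairs
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int | None = None


class _ClassState:
    """Per-classification sampler state (active columns, spectral factors)."""

    def __init__(self, name: str, Z: sp.csr_matrix):
        self.name = name
        col_norms = np.asarray(Z.power(2).sum(axis=0)).ravel()
        self.active = np.flatnonzero(col_norms > 0)
        self.all_zero = self.active.size == 0
        self.K_total = Z.shape[1]
        self.Z = Z[:, self.active].tocsr() if not self.all_zero else Z
        self.K = self.Z.shape[1]
        if not self.all_zero:
            G = (self.Z.T @ self.Z).toarray()
            # one-off symmetric eigendecomposition: per-iteration joint draws
            # then cost only O(K^2)
            self.evals, self.evecs = np.linalg.eigh(G)
            self.evals = np.clip(self.evals, 0.0, None)
        self.u = np.zeros(self.K)


class MMMCRegressor(RegressorMixin, BaseEstimator):
    """Bayesian multiple-membership multiple-classification linear model.

    Parameters
    ----------
    classifications : sequence of (name, weights)
        Ordered classifications entering the random part; ``weights`` is a
        :class:`~mmnet.weights.WeightMatrix` or any n x K sparse/dense array.
        May be empty (single-level regression).
    n_iter : int, default 20000
        Total chain length including burn-in.
    burn_in : int, default 2000
        Discarded initial draws.
    thin : int, default 1
        Keep every ``thin``-th retained draw.
    prior_a, prior_b : float, default 0.001
        Shape and rate of the Gamma prior on each precision.
    update : {"joint", "single"}, default "joint"
        Random-effect update strategy: one multivariate draw per
        classification (mixes better; default) or single-site updates.
    fixed_variances : mapping, optional
        Classification name -> variance held fixed (no Gamma update).
    fixed_residual_variance : float, optional
        Hold sigma2_e fixed (no Gamma update).
    random_state : int, optional
        Seed; identical seed and data give bit-identical chains.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Posterior means of the fixed coefficients.
    coef_sd_ : ndarray
        Posterior standard deviations of the fixed coefficients.
    variance_components_ : dict
        Posterior mean of sigma2_k per classification plus ``"individual"``.
    dic_, pd_ : float
        Deviance information criterion and effective number of parameters.
    chains_ : dict
        Retained draws: ``"beta"`` (S, p), ``"sigma2_<name>"`` (S,),
        ``"sigma2_e"`` (S,), ``"deviance"`` (S,).
    random_effects_ : dict
        Posterior mean random-effect vector per classification (full K,
        zeros for inactive subgroups).
    """

    def __init__(
        self,
        classifications=(),
        n_iter: int = 20_000,
        burn_in: int = 2_000,
        thin: int = 1,
        prior_a: float = 0.001,
        prior_b: float = 0.001,
        update: str = "joint",
        fixed_variances: Mapping[str, float] | None = None,
        fixed_residual_variance: float | None = None,
        random_state: int | None = None,
    ):
        self.classifications = classifications
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_a = prior_a
        self.prior_b = prior_b
        self.update = update
        self.fixed_variances = fixed_variances
        self.fixed_residual_variance = fixed_residual_variance
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y row counts differ")
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("X and y must be finite")
        if n < p:
            raise ValueError("need n >= p")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed design X is rank deficient")
        if self.update not in ("joint", "single"):
            raise ValueError("update must be 'joint' or 'single'")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")

        names = [name for name, _ in self.classifications]
        if len(set(names)) != len(names):
            raise ValueError("classification names must be unique")
        states = []
        for name, Zraw in self.classifications:
            Z = _as_sparse(Zraw)
            if Z.shape[0] != n:
                raise ValueError(f"weight matrix {name!r} has wrong row count")
            st = _ClassState(name, Z)
            if st.all_zero:
                warnings.warn(
                    f"classification {name!r} has an all-zero weight matrix; "
                    "it contributes nothing to the model"
                )
            states.append(st)

        rng = np.random.default_rng(self.random_state)
        a, b = self.prior_a, self.prior_b
        fixed_var = dict(self.fixed_variances or {})

        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        L_beta = np.linalg.cholesky(XtX_inv)
        Xty_op = XtX_inv @ X.T

        # starting values: beta at OLS, variances split the response variance
        beta = Xty_op @ y
        n_comp = len(states) + 1
        var0 = max(y.var(), 1e-8) / n_comp
        sigma2 = {
            st.name: fixed_var.get(st.name, var0) for st in states
        }
        sigma2_e = (
            self.fixed_residual_variance
            if self.fixed_residual_variance is not None
            else var0
        )

        eta = np.zeros(n)  # running sum_k Z_k u_k
        S = (self.n_iter - self.burn_in + self.thin - 1) // self.thin
        chain_beta = np.empty((S, p))
        chain_s2 = {st.name: np.empty(S) for st in states}
        chain_s2e = np.empty(S)
        chain_dev = np.empty(S)
        u_sum = {st.name: np.zeros(st.K) for st in states}
        const = n * np.log(2 * np.pi)

        s = 0
        for it in range(self.n_iter):
            # (i) fixed effects
            r = y - eta
            mean_beta = Xty_op @ r
            beta = mean_beta + np.sqrt(sigma2_e) * (L_beta @ rng.standard_normal(p))
            resid_fixed = y - X @ beta

            # (ii) random effects, one classification at a time
            for st in states:
                if st.all_zero:
                    continue
                r_k = resid_fixed - (eta - st.Z @ st.u)
                bvec = st.Z.T @ r_k / sigma2_e
                if self.update == "joint":
                    q = st.evals / sigma2_e + 1.0 / sigma2[st.name]
                    tb = st.evecs.T @ bvec
                    mean_t = tb / q
                    draw_t = mean_t + rng.standard_normal(st.K) / np.sqrt(q)
                    u_new = st.evecs @ draw_t
                else:
                    u_new = st.u.copy()
                    G = st.Z.T @ st.Z  # sparse
                    diagG = G.diagonal()
                    Zt_r = np.asarray(bvec) * sigma2_e  # Z' r_k
                    Gu = G @ u_new
                    for j in range(st.K):
                        # conditional of u_j given the others
                        q_j = diagG[j] / sigma2_e + 1.0 / sigma2[st.name]
                        b_j = (Zt_r[j] - (Gu[j] - diagG[j] * u_new[j])) / sigma2_e
                        new_val = b_j / q_j + rng.standard_normal() / np.sqrt(q_j)
                        delta = new_val - u_new[j]
                        if delta != 0.0:
                            Gu += delta * np.asarray(G[:, [j]].todense()).ravel()
                            u_new[j] = new_val
                eta += st.Z @ (u_new - st.u)
                st.u = u_new

                # (iii) classification variance
                if st.name not in fixed_var:
                    shape = a + st.K / 2.0
                    rate = b + st.u @ st.u / 2.0
                    sigma2[st.name] = 1.0 / rng.gamma(shape, 1.0 / rate)

            # (iv) residual variance
            resid = resid_fixed - eta
            ssr = resid @ resid
            if self.fixed_residual_variance is None:
                sigma2_e = 1.0 / rng.gamma(a + n / 2.0, 1.0 / (b + ssr / 2.0))

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                chain_beta[s] = beta
                for st in states:
                    chain_s2[st.name][s] = sigma2[st.name]
                    u_sum[st.name] += st.u
                chain_s2e[s] = sigma2_e
                chain_dev[s] = const + n * np.log(sigma2_e) + ssr / sigma2_e
                s += 1

        # posterior summaries
        self.n_features_in_ = p
        self.n_obs_ = n
        self.coef_ = chain_beta.mean(axis=0)
        self.coef_sd_ = chain_beta.std(axis=0, ddof=1)
        self.sigma2_e_ = float(chain_s2e.mean())
        self.variance_components_ = {
            st.name: float(chain_s2[st.name].mean()) for st in states
        }
        self.variance_components_["individual"] = self.sigma2_e_
        self.random_effects_ = {}
        self.weight_kinds_ = {}
        eta_bar = np.zeros(n)
        for st in states:
            u_full = np.zeros(st.K_total)
            if not st.all_zero:
                u_full[st.active] = u_sum[st.name] / S
            self.random_effects_[st.name] = u_full
            if not st.all_zero:
                eta_bar += st.Z @ (u_sum[st.name] / S)
        self.fitted_values_ = X @ self.coef_ + eta_bar

        # DIC with the plug-in at posterior means of beta, all u_k, sigma2_e
        D_bar_theta = gaussian_deviance(y, self.fitted_values_, self.sigma2_e_)
        self.dic_, self.pd_ = dic_from_deviances(chain_dev, D_bar_theta)
        self.mean_deviance_ = float(chain_dev.mean())

        self.chains_ = {"beta": chain_beta, "sigma2_e": chain_s2e,
                        "deviance": chain_dev}
        for name, ch in chain_s2.items():
            self.chains_[f"sigma2_{name}"] = ch
        self.classification_names_ = [st.name for st in states]
        return self

    # ------------------------------------------------------------------
    def predict(self, X):
        """Population-level prediction x'beta-hat for new individuals."""
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Posterior summary table for fixed effects and variance components."""
        check_is_fitted(self, "coef_")
        return posterior_summary(self, ci=ci)


# ----------------------------------------------------------------------
# thin functional wrappers


def fit_mmmc(
    spec: MmcmSpec,
    y,
    X,
    **kwargs,
) -> MMMCRegressor:
    """Fit an MMMC model from a spec; returns the fitted estimator."""
    est = MMMCRegressor(
        classifications=spec.classifications,
        n_iter=spec.n_iter,
        burn_in=spec.burn_in,
        thin=spec.thin,
        random_state=spec.seed,
        **kwargs,
    )
    return est.fit(X, y)


def dic(result: MMMCRegressor) -> tuple[float, float]:
    """(DIC, pD) of a fitted model."""
    check_is_fitted(result, "dic_")
    return result.dic_, result.pd_


def _ess(x: np.ndarray) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(x)[None, :]))


def posterior_summary(result: MMMCRegressor, ci: float = 0.95) -> pd.DataFrame:
    """One row per fixed coefficient and variance component.

    Quantiles are empirical (order statistics of the retained draws); ESS is
    the autocorrelation-based effective sample size.
    """
    check_is_fitted(result, "coef_")
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    beta = result.chains_["beta"]
    for j in range(beta.shape[1]):
        rows.append(("beta[%d]" % j, beta[:, j]))
    for name in result.classification_names_:
        rows.append((f"sigma2_{name}", result.chains_[f"sigma2_{name}"]))
    rows.append(("sigma2_e", result.chains_["sigma2_e"]))
    out = []
    for label, ch in rows:
        out.append(
            {
                "parameter": label,
                "mean": ch.mean(),
                "sd": ch.std(ddof=1),
                f"{lo:g}%": np.percentile(ch, lo),
                f"{hi:g}%": np.percentile(ch, hi),
                "ess": _ess(ch),
            }
        )
    return pd.DataFrame(out)
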