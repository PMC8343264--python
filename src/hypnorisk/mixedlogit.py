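"""Random-intercept logistic regression via adaptive Gauss-Hermite quadrature.

The model for binary day-level outcomes :math:`y_{ij}` of patient *i* is

.. math::

    \\mathrm{logit}\\, P(y_{ij} = 1 \\mid b_i) = x_{ij}' \\beta + b_i,
    \\qquad b_i \\sim N(0, \\sigma^2),

with the marginal likelihood integrated over the random intercepts by
adaptive Gauss-Hermite quadrature (15 nodes by default, centred and
scaled at each cluster's posterior mode). Inference is Wald-type on the
log-odds scale; confidence intervals for odds ratios are exponentiated.

The API follows the Model/Results convention: construct a
:class:`MixedLogit`, call :meth:`~MixedLogit.fit`, inspect the returned
:class:`MixedLogitResults` (``odds_ratios``, ``conf_int``, ``pvalues``,
``summary()``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, log_expit
from scipy.stats import norm

from statsmodels.tools import numdiff

from .core import ParameterError

_LOG_2PI = np.log(2 * np.pi)


class ConvergenceError(RuntimeError):
    """The marginal-likelihood optimisation failed to converge."""


class MixedLogit:
    """Logistic regression with a cluster-specific random intercept.

    Parameters
    ----------
    endog : array of 0/1
        Binary outcomes.
    exog : 2-D array
        Design matrix including the constant column.
    groups : array
        Cluster (patient) identifier per observation.
    exog_names : list of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.exog) != len(self.endog):
            raise ParameterError("exog must be 2-D and aligned with endog")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ParameterError("endog must be binary 0/1")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.nobs = len(self.endog)
        self.k_exog = self.exog.shape[1]
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.k_exog)]
        )

    # -- likelihood --------------------------------------------------------
    def _modes(self, eta: np.ndarray, sigma2: float, b0=None):
        """Posterior mode and curvature of each cluster's intercept."""
        b = np.zeros(self.n_groups) if b0 is None else b0.copy()
        g_idx = self.group_idx
        y = self.endog
        for _ in range(50):
            mu = expit(eta + b[g_idx])
            grad = np.bincount(g_idx, weights=y - mu, minlength=self.n_groups)
            grad -= b / sigma2
            hess = -np.bincount(
                g_idx, weights=mu * (1 - mu), minlength=self.n_groups
            ) - 1.0 / sigma2
            step = grad / hess
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = expit(eta + b[g_idx])
        hess = -np.bincount(
            g_idx, weights=mu * (1 - mu), minlength=self.n_groups
        ) - 1.0 / sigma2
        return b, hess

    def loglike(self, params: np.ndarray, n_quad: int = 15,
                fix_sigma: float | None = None) -> float:
        """Marginal log-likelihood at ``params = (beta, log sigma)``.

        With ``fix_sigma=0`` the model reduces exactly to ordinary
        logistic regression and ``params`` holds only ``beta``.
        """
        if fix_sigma is not None and fix_sigma == 0.0:
            beta = params
            eta = self.exog @ beta
            ll = self.endog * log_expit(eta) + (1 - self.endog) * log_expit(-eta)
            return float(ll.sum())
        if fix_sigma is not None:
            beta, sigma = params, float(fix_sigma)
        else:
            beta, sigma = params[:-1], float(np.exp(params[-1]))
        eta = self.exog @ beta
        sigma2 = sigma * sigma
        b_hat, hess = self._modes(eta, sigma2)
        tau = 1.0 / np.sqrt(-hess)

        z, w = hermgauss(n_quad)
        logw = np.log(w)
        y = self.endog
        g_idx = self.group_idx
        contrib = np.empty((self.n_groups, n_quad))
        for q in range(n_quad):
            b_q = b_hat + np.sqrt(2.0) * tau * z[q]
            eta_q = eta + b_q[g_idx]
            ll_obs = y * log_expit(eta_q) + (1 - y) * log_expit(-eta_q)
            ll_g = np.bincount(g_idx, weights=ll_obs, minlength=self.n_groups)
            log_prior = -0.5 * (b_q * b_q) / sigma2 - 0.5 * np.log(sigma2) \
                - 0.5 * _LOG_2PI
            contrib[:, q] = logw[q] + z[q] ** 2 + ll_g + log_prior
        m = contrib.max(axis=1)
        log_int = m + np.log(np.exp(contrib - m[:, None]).sum(axis=1))
        log_int += 0.5 * np.log(2.0) + np.log(tau)
        return float(log_int.sum())

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        n_quad: int = 15,
        fix_sigma: float | None = None,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
    ) -> "MixedLogitResults":
        """Maximise the marginal likelihood; Wald covariance from the
        numerical Hessian at the optimum."""
        if n_quad < 5:
            raise ParameterError("use at least 5 quadrature nodes")
        if start_params is None:
            beta0 = self._start_beta()
            if fix_sigma is None:
                start_params = np.append(beta0, np.log(0.5))
            else:
                start_params = beta0
        nll = lambda p: -self.loglike(p, n_quad=n_quad, fix_sigma=fix_sigma)
        res = optimize.minimize(nll, start_params, method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-6})
        gnorm = float(np.linalg.norm(res.jac))
        # BFGS often stops on precision loss with the gradient already tiny
        converged = bool(res.success or gnorm <= 5e-3 * max(1.0, abs(res.fun)) ** 0.5)
        if not converged and gnorm > 1e-1:
            raise ConvergenceError(
                f"optimizer failed: {res.message} (|grad|={gnorm:.3g})"
            )
        hess = numdiff.approx_hess(res.x, nll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((len(res.x), len(res.x)), np.nan)
        separation = self._check_separation()
        return MixedLogitResults(
            model=self,
            params=res.x,
            cov_params=cov,
            llf=-res.fun,
            n_quad=n_quad,
            fix_sigma=fix_sigma,
            converged=converged,
            separation=separation,
        )

    def _start_beta(self) -> np.ndarray:
        """Ridge-stabilised ordinary-logit start values."""
        beta = np.zeros(self.k_exog)
        X, y = self.exog, self.endog
        for _ in range(25):
            mu = expit(X @ beta)
            W = mu * (1 - mu) + 1e-9
            H = X.T @ (X * W[:, None]) + 1e-6 * np.eye(self.k_exog)
            g = X.T @ (y - mu) - 1e-6 * beta
            step = np.linalg.solve(H, g)
            beta += step
            if np.max(np.abs(step)) < 1e-8:
                break
        return beta

    def _check_separation(self) -> list[str]:
        """Binary predictors whose level determines the outcome."""
        flagged = []
        for j in range(self.k_exog):
            col = self.exog[:, j]
            vals = np.unique(col)
            if len(vals) != 2 or not np.isin(vals, (0.0, 1.0)).all():
                continue
            for level in (0.0, 1.0):
                ys = self.endog[col == level]
                if ys.size and (ys.min() == ys.max()):
                    flagged.append(self.exog_names[j])
                    break
        return flagged


class MixedLogitResults:
    """Estimates, Wald inference and diagnostics for :class:`MixedLogit`."""

    def __init__(self, model, params, cov_params, llf, n_quad, fix_sigma,
                 converged, separation):
        self.model = model
        self.params_full = np.asarray(params)
        self.cov_full = np.asarray(cov_params)
        self.llf = llf
        self.n_quad = n_quad
        self.fix_sigma = fix_sigma
        self.converged = converged
        self.separation = separation
        k = model.k_exog
        self.fe_params = pd.Series(self.params_full[:k], index=model.exog_names)
        self.bse = pd.Series(
            np.sqrt(np.clip(np.diag(self.cov_full)[:k], 0, None)),
            index=model.exog_names,
        )
        if fix_sigma is not None:
            self.re_sd = float(fix_sigma)
        else:
            self.re_sd = float(np.exp(self.params_full[-1]))
        self.re_var = self.re_sd**2
        self.nobs = model.nobs
        self.n_groups = model.n_groups
        if separation:
            warnings.warn(
                f"possible complete separation in predictors: {separation}"
            )

    # -- inference ---------------------------------------------------------
    @property
    def tvalues(self) -> pd.Series:
        return self.fe_params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * norm.sf(np.abs(self.tvalues)), index=self.fe_params.index
        )

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.fe_params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zc = norm.ppf(1 - alpha / 2)
        lo = self.fe_params - zc * self.bse
        hi = self.fe_params + zc * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def or_conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return np.exp(self.conf_int(alpha))

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.or_conf_int(alpha)
        lines = [
            "Random-intercept logistic regression (adaptive Gauss-Hermite, "
            f"{self.n_quad} nodes)",
            f"  observations: {self.nobs}   groups: {self.n_groups}   "
            f"log-likelihood: {self.llf:.2f}",
            f"  random-intercept SD: {self.re_sd:.4f} "
            f"(variance {self.re_var:.4f})",
            "",
            f"  {'term':<22}{'OR':>8}{'CI low':>9}{'CI high':>9}{'p':>10}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"  {name:<22}{self.odds_ratios[name]:>8.3f}"
                f"{ci.loc[name, 'lower']:>9.3f}{ci.loc[name, 'upper']:>9.3f}"
                f"{self.pvalues[name]:>10.4f}"
            )
        if self.separation:
            lines.append(f"  WARNING: possible separation in {self.separation}")
        if not self.converged:
            lines.append("  WARNING: optimizer reported non-convergence")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MixedLogitResults n={self.nobs} groups={self.n_groups} "
            f"llf={self.llf:.2f}>"
        )
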