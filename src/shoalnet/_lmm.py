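"""Gaussian linear mixed models with random intercepts, fitted by REML.

Internal engine behind :mod:`shoalnet.inference`.  The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

with each Z_k the indicator matrix of a grouping factor (population,
family, group, fish ID ...).  The REML criterion is profiled over beta and
sigma_e^2 and optimized over the variance ratios gamma_k = sigma_k^2 /
sigma_e^2 on the log scale.  All per-iteration linear algebra runs on
q x q cross-product matrices (q = total number of random levels) via the
Woodbury identity, so refitting under thousands of bootstrap or
permutation resamples is cheap; the single-factor case exploits the
diagonality of Z'Z and costs O(n + q) per criterion evaluation.

statsmodels' MixedLM fits the same family of models and serves as an
independent cross-check in the test-suite; this engine exists because the
resampling procedures (parametric bootstrap, permutation, calibration
simulations) need orders of magnitude more refits than a general-purpose
fitter can deliver in reasonable time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_GAMMA_BOUNDS = (-12.0, 12.0)


class SingularFitError(ValueError):
    """Fixed-effects design is rank deficient under GLS."""


def factor_codes(labels) -> tuple[np.ndarray, list]:
    """Integer codes and sorted unique levels for a label vector."""
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    return codes, list(levels)


@dataclass
class LMMFit:
    """Fitted variance-components model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: dict  # component name -> variance (includes "residual")
    loglik_reml: float  # -0.5 * reml criterion (up to an additive constant)
    converged: bool
    n: int
    p: int
    fixed_names: list

    def wald_chi2(self, cols) -> tuple[float, int]:
        """Wald chi-square for H0: beta[cols] = 0, with df = len(cols)."""
        cols = list(cols)
        b = self.beta[cols]
        V = self.cov_beta[np.ix_(cols, cols)]
        chi2 = float(b @ np.linalg.solve(V, b))
        return chi2, len(cols)

    @property
    def resid_df(self) -> int:
        return self.n - self.p


class VarianceComponentsLMM:
    """REML fitter for a fixed design (X, random factors); re-usable across y.

    Parameters
    ----------
    X : ndarray (n, p)
        Fixed-effects design, full column rank.
    factors : dict[str, array-like]
        Random-intercept grouping factors, name -> per-observation labels.
    weights : ndarray (n,), optional
        Observation weights (used by the PQL working model); the model is
        fitted to sqrt(w)-scaled rows so Var(e_i) = sigma_e^2 / w_i.
    """

    def __init__(self, X, factors: dict, weights=None, fixed_names=None):
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.fixed_names = list(fixed_names) if fixed_names else [
            f"x{j}" for j in range(self.p)
        ]
        self.factor_names = list(factors)
        self.codes = {}
        self.sizes = {}
        for name, labels in factors.items():
            codes, levels = factor_codes(labels)
            if len(labels) != self.n:
                raise ValueError(f"factor {name!r} length mismatch")
            self.codes[name] = codes
            self.sizes[name] = len(levels)
        if weights is None:
            self._sw = None
            Xw = X
        else:
            weights = np.asarray(weights, dtype=float)
            if np.any(weights <= 0):
                raise ValueError("weights must be positive")
            self._sw = np.sqrt(weights)
            Xw = X * self._sw[:, None]
        # dense Z (n, q): fine at the design sizes this package targets
        q = sum(self.sizes.values())
        Z = np.zeros((self.n, q))
        offsets, off = {}, 0
        for name in self.factor_names:
            Z[np.arange(self.n), off + self.codes[name]] = 1.0
            offsets[name] = (off, off + self.sizes[name])
            off += self.sizes[name]
        if self._sw is not None:
            Z = Z * self._sw[:, None]
        self.offsets = offsets
        self.q = q
        self.Z = Z
        self.X = Xw
        # y-independent cross-products
        self.C = Z.T @ Z
        self.XtX = Xw.T @ Xw
        self.XtZ = Xw.T @ Z
        self._single = len(self.factor_names) == 1 and self._sw is None
        if self._single:
            self._counts = np.diag(self.C).copy()
        if np.linalg.matrix_rank(self.XtX) < self.p:
            raise SingularFitError("fixed-effects design is rank deficient")

    # -- REML criterion pieces -------------------------------------------

    def _gamma_diag(self, gammas):
        d = np.empty(self.q)
        for name, g in zip(self.factor_names, gammas):
            a, b = self.offsets[name]
            d[a:b] = g
        return d

    def _criterion_parts(self, gammas, Xty, Zty, yty):
        """Return (logdet_R, logdet_XRX, ypy, beta, XRXinv)."""
        d = self._gamma_diag(gammas)
        if self._single:
            m = 1.0 + d * self._counts  # M = I + D^(1/2) C D^(1/2), diagonal
            logdet_R = float(np.log(m).sum())
            sMinv_s = d / m  # S M^-1 S, diagonal
            XRX = self.XtX - (self.XtZ * sMinv_s) @ self.XtZ.T
            XRy = Xty - (self.XtZ * sMinv_s) @ Zty
            yRy = yty - float(Zty @ (sMinv_s * Zty))
        else:
            s = np.sqrt(d)
            M = np.eye(self.q) + (s[:, None] * self.C) * s[None, :]
            L = np.linalg.cholesky(M)
            logdet_R = 2.0 * float(np.log(np.diag(L)).sum())
            SZt_y = s * Zty
            SZt_X = self.XtZ * s[None, :]
            w_y = np.linalg.solve(L, SZt_y)
            w_X = np.linalg.solve(L, SZt_X.T)
            XRX = self.XtX - w_X.T @ w_X
            XRy = Xty - w_X.T @ w_y
            yRy = yty - float(w_y @ w_y)
        sign, logdet_XRX = np.linalg.slogdet(XRX)
        if sign <= 0:
            raise SingularFitError("X' R^-1 X not positive definite")
        beta = np.linalg.solve(XRX, XRy)
        ypy = max(yRy - float(XRy @ beta), 1e-300)
        return logdet_R, logdet_XRX, ypy, beta, XRX

    def _criterion(self, log_gammas, Xty, Zty, yty):
        gammas = np.exp(np.clip(log_gammas, *_LOG_GAMMA_BOUNDS))
        logdet_R, logdet_XRX, ypy, _, _ = self._criterion_parts(
            gammas, Xty, Zty, yty
        )
        return (self.n - self.p) * np.log(ypy) + logdet_R + logdet_XRX

    # -- public API -------------------------------------------------------

    def fit(self, y) -> LMMFit:
        y = np.asarray(y, dtype=float)
        if self._sw is not None:
            y = y * self._sw
        Xty = self.X.T @ y
        Zty = self.Z.T @ y
        yty = float(y @ y)
        k = len(self.factor_names)
        converged = True
        if k == 1:
            res = optimize.minimize_scalar(
                lambda t: self._criterion(np.array([t]), Xty, Zty, yty),
                bounds=_LOG_GAMMA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-8},
            )
            log_g = np.array([res.x])
            converged = bool(res.success)
        else:
            res = optimize.minimize(
                self._criterion,
                x0=np.zeros(k),
                args=(Xty, Zty, yty),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            log_g = np.clip(res.x, *_LOG_GAMMA_BOUNDS)
            converged = bool(res.success)
        gammas = np.exp(log_g)
        # snap effectively-zero components to the boundary
        gammas[gammas <= 1.01 * np.exp(_LOG_GAMMA_BOUNDS[0])] = 0.0
        logdet_R, logdet_XRX, ypy, beta, XRX = self._criterion_parts(
            gammas, Xty, Zty, yty
        )
        sigma_e2 = ypy / (self.n - self.p)
        sigma2 = {
            name: float(g * sigma_e2) for name, g in zip(self.factor_names, gammas)
        }
        sigma2["residual"] = float(sigma_e2)
        crit = (self.n - self.p) * np.log(ypy) + logdet_R + logdet_XRX
        self._last_gammas = gammas
        self._last_y = y
        self._last_beta = beta
        return LMMFit(
            beta=beta,
            cov_beta=sigma_e2 * np.linalg.inv(XRX),
            sigma2=sigma2,
            loglik_reml=-0.5 * crit,
            converged=converged,
            n=self.n,
            p=self.p,
            fixed_names=self.fixed_names,
        )

    def ranef(self, fit: LMMFit) -> dict:
        """Empirical BLUPs u_k = D Z' R^-1 (y - X beta) per factor."""
        d = self._gamma_diag(self._last_gammas)
        r = self._last_y - self.X @ self._last_beta
        Ztr = self.Z.T @ r
        if self._single:
            m = 1.0 + d * self._counts
            u = d * (Ztr - (d * self._counts / m) * Ztr)
        else:
            # Z' R^-1 r = Z'r - C S M^-1 S Z'r
            s = np.sqrt(d)
            M = np.eye(self.q) + (s[:, None] * self.C) * s[None, :]
            u = d * (Ztr - self.C @ (s * np.linalg.solve(M, s * Ztr)))
        out = {}
        for name in self.factor_names:
            a, b = self.offsets[name]
            out[name] = u[a:b]
        return out

    def simulate(self, fit: LMMFit, rng: np.random.Generator, beta=None):
        """Draw a response vector from the fitted model (parametric bootstrap)."""
        if self._sw is not None:
            raise NotImplementedError("simulation with weights is not supported")
        beta = fit.beta if beta is None else beta
        y = self.X @ beta
        for name in self.factor_names:
            sd = np.sqrt(fit.sigma2[name])
            u = rng.normal(0.0, sd, size=self.sizes[name])
            y = y + u[self.codes[name]]
        return y + rng.normal(0.0, np.sqrt(fit.sigma2["residual"]), size=self.n)
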