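"""Linear mixed models with independent variance components, fit by REML.

The model is

    y = Xβ + Σ_k Z_k u_k + ε,   u_k ~ N(0, σ²_k I),   ε ~ N(0, σ²_e I)

with each random factor contributing an independent random intercept per
level (block, sampling location nested in block, optionally species).
Designs here are tiny (tens of observations), so the REML criterion is
evaluated by dense Cholesky factorisation of V(θ) = Σ σ²_k Z_k Z_kᵀ + σ²_e I
and optimised over the variance scale with box constraints; boundary
(zero) variance estimates are retained, not refit.

F-tests of fixed-effect contrasts use Satterthwaite denominator degrees of
freedom: for a one-dimensional contrast l, ν = 2f²/(∇fᵀ A ∇f) with
f(θ) = l C(θ) lᵀ, C = (XᵀV⁻¹X)⁻¹ and A the asymptotic covariance of θ̂
(inverse observed REML information); multi-dimensional contrasts are
reduced to independent one-dimensional contrasts through the eigenvectors
of L C Lᵀ and combined through the standard moment-matching formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


def indicator_matrix(codes: np.ndarray) -> np.ndarray:
    """n × q 0/1 design of a factor given integer or string level codes."""
    codes = np.asarray(codes)
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((codes.shape[0], levels.shape[0]))
    Z[np.arange(codes.shape[0]), idx] = 1.0
    return Z


@dataclass
class VarCompResult:
    """A fitted variance-components model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    varcomps: dict[str, float]  # random-factor name -> σ²_k
    sigma2_resid: float
    loglik_reml: float
    converged: bool
    n_obs: int
    rank_x: int
    _model: "VarCompModel" = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _cov_theta: np.ndarray = field(repr=False, default=None)

    def contrast_variance(self, l: np.ndarray, theta: np.ndarray | None = None) -> float:
        th = self._theta if theta is None else theta
        C = self._model._cov_beta(th)
        return float(l @ C @ l)

    def satterthwaite_df(self, l: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast lᵀβ."""
        m = self._model
        f0 = self.contrast_variance(l)
        grad = m._fd_gradient(lambda th: self.contrast_variance(l, th), self._theta)
        denom = float(grad @ self._cov_theta @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n_obs - self.rank_x)
        df = 2.0 * f0 * f0 / denom
        return float(df)

    def t_test(self, l: np.ndarray) -> tuple[float, float, float]:
        """(estimate, se, Satterthwaite df) for lᵀβ."""
        est = float(l @ self.beta)
        se = float(np.sqrt(self.contrast_variance(l)))
        return est, se, self.satterthwaite_df(l)

    def f_test(self, L: np.ndarray) -> tuple[float, int, float, float]:
        """Type-III style F-test of H0: Lβ = 0.

        Returns (F, numerator df, Satterthwaite denominator df, p).
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        C = self._model._cov_beta(self._theta)
        M = L @ C @ L.T
        evals, evecs = np.linalg.eigh(M)
        tol = max(M.shape) * np.finfo(float).eps * max(evals.max(), 0.0)
        keep = evals > tol
        q = int(keep.sum())
        if q == 0:
            return 0.0, 0, float(self.n_obs - self.rank_x), 1.0
        t2 = np.zeros(q)
        nus = np.zeros(q)
        for i, j in enumerate(np.flatnonzero(keep)):
            li = evecs[:, j] @ L
            est = float(li @ self.beta)
            t2[i] = est * est / evals[j]
            nus[i] = self.satterthwaite_df(li)
        F = float(t2.sum() / q)
        good = nus > 2.0
        if good.any():
            E = float(np.sum(nus[good] / (nus[good] - 2.0)))
            df_den = 2.0 * E / (E - q) if E > q else float(self.n_obs - self.rank_x)
        else:
            df_den = float(self.n_obs - self.rank_x)
        p = float(stats.f.sf(F, q, df_den)) if F > 0 else 1.0
        return F, q, df_den, p


class VarCompModel:
    """REML estimation of a fixed design plus independent random intercepts."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        random_factors: dict[str, np.ndarray],
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        self.names = list(random_factors)
        self.Z = [indicator_matrix(np.asarray(random_factors[k])) for k in self.names]
        self.ZZt = [Z @ Z.T for Z in self.Z]
        self.n = self.y.shape[0]
        self.p = np.linalg.matrix_rank(self.X)
        if self.p >= self.n:
            raise ValueError("singular design: no residual degrees of freedom")

    # -- REML machinery -------------------------------------------------

    def _build_v(self, theta: np.ndarray) -> np.ndarray:
        V = np.diag(np.full(self.n, max(theta[-1], 1e-12)))
        for k, ZZ in enumerate(self.ZZt):
            if theta[k] != 0.0:
                V = V + theta[k] * ZZ
        return V

    def _neg_reml(self, theta: np.ndarray) -> float:
        try:
            V = self._build_v(theta)
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf)))
        Vi_y = np.linalg.solve(V, self.y)
        Vi_X = np.linalg.solve(V, self.X)
        XtViX = self.X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        resid = self.y - self.X @ beta
        y_p_y = float(resid @ np.linalg.solve(V, resid))
        return 0.5 * (logdet_v + logdet_x + y_p_y)

    def _cov_beta(self, theta: np.ndarray) -> np.ndarray:
        V = self._build_v(theta)
        Vi_X = np.linalg.solve(V, self.X)
        return np.linalg.pinv(self.X.T @ Vi_X)

    def _beta(self, theta: np.ndarray) -> np.ndarray:
        V = self._build_v(theta)
        Vi_y = np.linalg.solve(V, self.y)
        Vi_X = np.linalg.solve(V, self.X)
        return np.linalg.solve(self.X.T @ Vi_X, self.X.T @ Vi_y)

    def _fd_gradient(self, fun, theta: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(theta)
        scale = max(theta[-1], 1e-8)
        for i in range(theta.size):
            h = 1e-5 * max(theta[i], scale)
            lo = theta[i] - h
            e = np.zeros_like(theta)
            e[i] = 1.0
            if lo >= 0:
                grad[i] = (fun(theta + h * e) - fun(theta - h * e)) / (2 * h)
            else:  # boundary component: one-sided
                grad[i] = (fun(theta + h * e) - fun(theta)) / h
        return grad

    def _fd_hessian(self, theta: np.ndarray, active: np.ndarray) -> np.ndarray:
        """Hessian of the REML criterion on the active-parameter subspace.

        Variance components estimated at the zero boundary are held fixed
        (their rows/columns are zero), so they contribute no uncertainty
        to Satterthwaite denominators — the fit has collapsed to the
        submodel without them.
        """
        k = theta.size
        idx = np.flatnonzero(active)
        h = np.array([1e-4 * theta[i] for i in idx])
        H_act = np.zeros((idx.size, idx.size))
        f0 = self._neg_reml(theta)
        for a, i in enumerate(idx):
            ei = np.zeros(k)
            ei[i] = h[a]
            for bpos, j in enumerate(idx[a:], start=a):
                ej = np.zeros(k)
                ej[j] = h[bpos]
                if i == j:
                    fpp = self._neg_reml(theta + ei)
                    fmm = self._neg_reml(theta - ei)
                    H_act[a, a] = (fpp - 2 * f0 + fmm) / (h[a] ** 2)
                else:
                    fpp = self._neg_reml(theta + ei + ej)
                    fpm = self._neg_reml(theta + ei - ej)
                    fmp = self._neg_reml(theta - ei + ej)
                    fmm = self._neg_reml(theta - ei - ej)
                    H_act[a, bpos] = H_act[bpos, a] = (fpp - fpm - fmp + fmm) / (
                        4 * h[a] * h[bpos]
                    )
        H = np.zeros((k, k))
        H[np.ix_(idx, idx)] = H_act
        return H

    def fit(self) -> VarCompResult:
        # standardise the response so the optimiser sees O(1) variances
        ols_beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ ols_beta
        s2 = float(resid @ resid) / max(self.n - self.p, 1)
        scale = s2 if s2 > 0 else 1.0
        nk = len(self.Z)

        y_orig = self.y
        self.y = y_orig / np.sqrt(scale)
        try:
            starts = [
                np.r_[np.full(nk, 0.2), 1.0],
                np.r_[np.full(nk, 1.0), 0.5],
                np.r_[np.full(nk, 1e-3), 1.0],
            ]
            best = None
            for x0 in starts:
                res = optimize.minimize(
                    self._neg_reml,
                    x0,
                    method="L-BFGS-B",
                    bounds=[(0.0, None)] * nk + [(1e-10, None)],
                    options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            theta = np.asarray(best.x, dtype=float)
            tol = 1e-7 * max(theta.max(), 1e-10)
            theta[:nk][theta[:nk] < tol] = 0.0
            active = np.r_[theta[:nk] > 0.0, True]
            hess = self._fd_hessian(theta, active)
            cov_theta = np.linalg.pinv(hess)
            beta = self._beta(theta)
            cov_beta = self._cov_beta(theta)
            loglik = -self._neg_reml(theta)
        finally:
            self.y = y_orig

        # undo standardisation: variances scale by `scale`, β and cov(β) too
        theta_o = theta * scale
        result = VarCompResult(
            beta=beta * np.sqrt(scale),
            cov_beta=cov_beta * scale,
            varcomps={k: float(theta_o[i]) for i, k in enumerate(self.names)},
            sigma2_resid=float(theta_o[-1]),
            loglik_reml=float(loglik),
            converged=bool(best.success),
            n_obs=self.n,
            rank_x=self.p,
            _model=self,
            _theta=theta_o,
            _cov_theta=cov_theta * scale * scale,
        )
        return result


__all__ = ["VarCompModel", "VarCompResult", "indicator_matrix"]
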