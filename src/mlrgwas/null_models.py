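"""Null-model fitting for binary-trait mixed-model association.

Two null models are fitted once per genome scan:

* the mixed logistic regression (MLR)  logit E(y) = X beta + omega,
  omega ~ MVN(0, tau K), fitted by penalized quasi-likelihood (PQL):
  a sequence of working linear mixed models with response
  z = eta + W^{-1}(y - mu) and known residual covariance W^{-1};
* the linear mixed model (LMM) treating the 0/1 status as quantitative,
  y = X beta + omega + e, e ~ N(0, sigma2_e I), fitted by REML.

Both fits expose the projection matrix P = Sigma^{-1} - Sigma^{-1} X
(X' Sigma^{-1} X)^{-1} X' Sigma^{-1} that the fast per-variant tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from scipy.special import expit, logit
from scipy.stats import chi2

from .genotypes import GRM

__all__ = [
    "NullModelFit",
    "LmmNullFit",
    "fit_pql_null",
    "fit_pql_snp",
    "fit_lmm_null",
    "ConvergenceError",
    "save_null_model",
    "load_null_model",
]

MU_CLIP = 1e-8        # fitted probabilities kept in [MU_CLIP, 1-MU_CLIP]
TAU_MAX = 50.0
ETA_DIVERGE = 35.0    # |linear predictor| beyond this signals separation


class ConvergenceError(RuntimeError):
    """Fit failed to converge; carries the last iterate in ``last_state``."""

    def __init__(self, message: str, last_state: dict | None = None):
        super().__init__(message)
        self.last_state = last_state or {}


def _as_matrix(k: GRM | np.ndarray, n: int) -> np.ndarray:
    mat = k.matrix if isinstance(k, GRM) else np.asarray(k, dtype=float)
    if mat.shape != (n, n):
        raise ValueError(f"GRM has shape {mat.shape}, expected ({n}, {n})")
    return mat


def _check_design(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < x.shape[1]:
        raise ValueError("more covariates than samples")
    r = np.linalg.qr(x, mode="r")
    d = np.abs(np.diag(r))
    if d.min() <= 1e-10 * max(d.max(), 1.0):
        raise ValueError("covariate matrix is rank deficient")
    return x


@dataclass
class NullModelFit:
    """Converged PQL fit of the null mixed logistic regression.

    Attributes ending in ``0`` are evaluated under gamma = 0.  ``weights`` is
    the diagonal of W = diag(mu0 (1 - mu0)).  ``sigma`` is the working-model
    covariance tau K + W^{-1}; ``projection`` (lazy) is the associated P.
    """

    beta0: np.ndarray
    omega0: np.ndarray
    tau: float
    mu0: np.ndarray
    eta0: np.ndarray
    weights: np.ndarray
    sigma: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0
    _chol: np.ndarray = field(default=None, repr=False)      # lower Cholesky of sigma
    _sinv_x: np.ndarray = field(default=None, repr=False)    # Sigma^{-1} X
    _xtsx_inv: np.ndarray = field(default=None, repr=False)  # (X' Sigma^{-1} X)^{-1}

    def __post_init__(self) -> None:
        if self._chol is None:
            self._chol = sla.cholesky(self.sigma, lower=True)
        if self._sinv_x is None:
            self._sinv_x = sla.cho_solve((self._chol, True), self.x)
        if self._xtsx_inv is None:
            self._xtsx_inv = np.linalg.inv(self.x.T @ self._sinv_x)

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def sigma_solve(self, v: np.ndarray) -> np.ndarray:
        """Sigma^{-1} v without forming the inverse."""
        return sla.cho_solve((self._chol, True), v)

    def project(self, v: np.ndarray) -> np.ndarray:
        """P v in O(n^2) per column (O(n p) beyond the Sigma solve)."""
        sv = self.sigma_solve(v)
        return sv - self._sinv_x @ (self._xtsx_inv @ (self._sinv_x.T @ v))

    @cached_property
    def projection(self) -> np.ndarray:
        """Dense P = Sigma^{-1} - Sigma^{-1} X (X'Sigma^{-1}X)^{-1} X'Sigma^{-1}."""
        n = self.sigma.shape[0]
        sinv = sla.cho_solve((self._chol, True), np.eye(n))
        p = sinv - self._sinv_x @ self._xtsx_inv @ self._sinv_x.T
        return (p + p.T) / 2.0


@dataclass
class LmmNullFit:
    """REML fit of the linear mixed model on the (numeric) status."""

    beta0: np.ndarray
    omega0: np.ndarray
    tau: float
    sigma2_e: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    projection: np.ndarray = field(repr=False)
    converged: bool = True

    @cached_property
    def py(self) -> np.ndarray:
        return self.projection @ self.y


# ---------------------------------------------------------------------------
# PQL
# ---------------------------------------------------------------------------

def _logistic_irls(y: np.ndarray, x: np.ndarray, max_iter: int = 30,
                   tol: float = 1e-10) -> np.ndarray:
    """Plain logistic regression by IRLS; raises on divergence."""
    beta = np.zeros(x.shape[1])
    beta[0] = logit(np.clip(y.mean(), MU_CLIP, 1 - MU_CLIP))
    for _ in range(max_iter):
        eta = x @ beta
        if np.max(np.abs(eta)) > ETA_DIVERGE:
            raise ConvergenceError(
                "logistic regression diverged (possible complete separation)",
                {"beta": beta},
            )
        mu = np.clip(expit(eta), MU_CLIP, 1 - MU_CLIP)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        xw = x * w[:, None]
        new = np.linalg.solve(x.T @ xw, xw.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def _reml_tau_step(tau, k_mat, w, z, x, *, chol, sinv_x, xtsx_inv, resid_s):
    """One safeguarded Newton (average-information) update of tau.

    Inputs are the current working-model quantities: ``chol`` the lower
    Cholesky of Sigma(tau), ``sinv_x`` = Sigma^{-1}X, ``resid_s`` =
    Sigma^{-1}(z - X beta_gls) = P z.  Returns the updated tau.
    """
    r = resid_s                       # P z
    kr = k_mat @ r
    # tr(Sigma^{-1} K): for tau > 0 use K = (Sigma - W^{-1})/tau and
    # diag(Sigma^{-1}); at the tau = 0 boundary Sigma = W^{-1} exactly.
    if tau > 1e-8:
        linv, info = sla.lapack.dtrtri(chol, lower=1)
        if info != 0:
            raise ConvergenceError("singular working covariance")
        diag_sinv = np.einsum("ij,ij->j", linv, linv)
        tr_sinv_k = (z.shape[0] - float(diag_sinv @ (1.0 / w))) / tau
    else:
        tr_sinv_k = float(w @ np.diag(k_mat))
    aka = sinv_x.T @ (k_mat @ sinv_x)
    tr_pk = tr_sinv_k - float(np.trace(xtsx_inv @ aka))
    grad = -0.5 * (tr_pk - float(r @ kr))
    # average information for the single variance component
    pkr = sla.cho_solve((chol, True), kr) - sinv_x @ (xtsx_inv @ (sinv_x.T @ kr))
    ai = 0.5 * float(kr @ pkr)
    if ai <= 1e-12:
        return max(0.0, tau if grad >= 0 else tau / 2.0)
    step = grad / ai
    limit = 2.0 * (tau + 0.1)         # trust region: avoid wild early steps
    step = np.clip(step, -limit, limit)
    return float(np.clip(tau + step, 0.0, TAU_MAX))


def fit_pql_null(
    y: np.ndarray,
    x: np.ndarray,
    k: GRM | np.ndarray,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
    tau0: float = 0.1,
    fix_tau: float | None = None,
    beta0: np.ndarray | None = None,
) -> NullModelFit:
    """Fit the null mixed logistic regression by PQL.

    Alternates (a) the working response z = eta + W^{-1}(y - mu) with weights
    W from the current linear predictor and (b) a REML update of the working
    linear mixed model z = X beta + omega + e, omega ~ N(0, tau K),
    e ~ N(0, W^{-1}).  The variance component is updated by one
    average-information Newton step per outer iteration; convergence is
    declared when max |change in (beta, tau)| < tol.

    ``tau0`` / ``beta0`` allow warm starts (used heavily by the simulation
    harnesses); ``fix_tau`` pins the variance component (0 gives plain
    logistic regression).
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("phenotype is constant: both classes required")
    x = _check_design(x)
    n = y.shape[0]
    k_mat = _as_matrix(k, n)

    beta = _logistic_irls(y, x) if beta0 is None else np.asarray(beta0, float).copy()
    tau = float(fix_tau) if fix_tau is not None else float(tau0)
    omega = np.zeros(n)
    eta = x @ beta + omega
    w_inv_diag_idx = np.diag_indices(n)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = np.clip(expit(eta), MU_CLIP, 1 - MU_CLIP)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w

        sigma = tau * k_mat
        sigma[w_inv_diag_idx] += 1.0 / w
        try:
            chol = sla.cholesky(sigma, lower=True)
        except sla.LinAlgError as exc:
            raise ConvergenceError(
                f"working covariance not positive definite at iteration {n_iter}",
                {"beta": beta, "tau": tau},
            ) from exc
        sinv_x = sla.cho_solve((chol, True), x)
        xtsx_inv = np.linalg.inv(x.T @ sinv_x)
        beta_new = xtsx_inv @ (sinv_x.T @ z)
        resid_s = sla.cho_solve((chol, True), z - x @ beta_new)  # = P z

        if fix_tau is None:
            tau_new = _reml_tau_step(
                tau, k_mat, w, z, x,
                chol=chol, sinv_x=sinv_x, xtsx_inv=xtsx_inv, resid_s=resid_s,
            )
        else:
            tau_new = tau

        omega = tau_new * (k_mat @ resid_s)
        eta = x @ beta_new + omega
        if np.max(np.abs(eta)) > ETA_DIVERGE:
            raise ConvergenceError(
                "linear predictor diverged (possible complete separation)",
                {"beta": beta_new, "tau": tau_new},
            )
        delta = max(np.max(np.abs(beta_new - beta)), abs(tau_new - tau))
        beta, tau = beta_new, tau_new
        if delta < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"PQL did not converge in {max_iter} iterations (last change {delta:.3g})",
            {"beta": beta, "tau": tau, "omega": omega},
        )

    mu = np.clip(expit(eta), MU_CLIP, 1 - MU_CLIP)
    w = mu * (1 - mu)
    sigma = tau * k_mat
    sigma[w_inv_diag_idx] += 1.0 / w
    chol = sla.cholesky(sigma, lower=True)
    sinv_x = sla.cho_solve((chol, True), x)
    xtsx_inv = np.linalg.inv(x.T @ sinv_x)
    return NullModelFit(
        beta0=beta, omega0=omega, tau=tau, mu0=mu, eta0=eta, weights=w,
        sigma=sigma, x=x, y=y, converged=True, n_iter=n_iter,
        _chol=chol, _sinv_x=sinv_x, _xtsx_inv=xtsx_inv,
    )


def fit_pql_snp(
    y: np.ndarray,
    x: np.ndarray,
    g: np.ndarray,
    k: GRM | np.ndarray,
    **kwargs,
) -> tuple[float, float, float]:
    """Reference (slow) per-variant estimator: full PQL refit with the SNP.

    Returns (gamma_hat, se, p) for the SNP coefficient, the standard error
    coming from the converged working linear mixed model.
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.min() == g.max():
        raise ValueError("constant genotype vector")
    xg = np.column_stack([x, g])
    fit = fit_pql_null(y, xg, k, **kwargs)
    gamma = float(fit.beta0[-1])
    se = float(np.sqrt(fit._xtsx_inv[-1, -1]))
    stat = (gamma / se) ** 2
    p = float(chi2.sf(stat, 1))
    return gamma, se, p


# ---------------------------------------------------------------------------
# linear mixed model comparator
# ---------------------------------------------------------------------------

def fit_lmm_null(
    y: np.ndarray,
    x: np.ndarray,
    k: GRM | np.ndarray,
    *,
    k_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> LmmNullFit:
    """REML fit of y = X beta + omega + e with omega ~ N(0, tau K).

    The variance ratio lambda = tau / sigma2_e is profiled on the spectrum of
    K (one eigendecomposition, reusable across phenotype replicates via
    ``k_eig``); sigma2_e is then the REML residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = _check_design(x)
    n, p = x.shape
    k_mat = _as_matrix(k, n)
    if k_eig is None:
        d, u = np.linalg.eigh(k_mat)
    else:
        d, u = k_eig
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ x

    def neg_reml(lam: float) -> float:
        v = lam * d + 1.0
        xtv = xt / v[:, None]
        xtx = xt.T @ xtv
        beta = np.linalg.solve(xtx, xtv.T @ yt)
        r = yt - xt @ beta
        rss = float(r @ (r / v))
        s2 = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        return (n - p) * np.log(s2) + float(np.sum(np.log(v))) + logdet_xtx

    # coarse log-grid then local refinement: robust over many decades
    grid = np.concatenate([[0.0], np.logspace(-4, 4, 33)])
    vals = [neg_reml(l) for l in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_reml, bounds=(lo, max(hi, lo + 1e-8)),
                          method="bounded", options={"xatol": 1e-8})
    lam = float(res.x) if res.fun <= vals[i] else float(grid[i])

    v = lam * d + 1.0
    xtv = xt / v[:, None]
    xtx = xt.T @ xtv
    beta = np.linalg.solve(xtx, xtv.T @ yt)
    r = yt - xt @ beta
    s2 = float(r @ (r / v)) / (n - p)
    tau = lam * s2
    sigma2_e = s2
    # P = Sigma^{-1} - Sigma^{-1}X (X'Sigma^{-1}X)^{-1} X'Sigma^{-1}, Sigma = s2 (lam K + I)
    sinv = (u / v[None, :]) @ u.T / s2
    sx = sinv @ x
    proj = sinv - sx @ np.linalg.solve(x.T @ sx, sx.T)
    proj = (proj + proj.T) / 2.0
    omega = tau * (k_mat @ (proj @ y))
    return LmmNullFit(
        beta0=beta, omega0=omega, tau=tau, sigma2_e=sigma2_e,
        x=x, y=y, projection=proj, converged=True,
    )


# ---------------------------------------------------------------------------
# dump / restore
# ---------------------------------------------------------------------------

def save_null_model(fit: NullModelFit, path: str | Path) -> None:
    """Dump a converged PQL null model so a scan can resume without refitting."""
    np.savez_compressed(
        path,
        beta0=fit.beta0, omega0=fit.omega0, tau=fit.tau, mu0=fit.mu0,
        eta0=fit.eta0, weights=fit.weights, sigma=fit.sigma, x=fit.x,
        y=fit.y, n_iter=fit.n_iter,
    )


def load_null_model(path: str | Path) -> NullModelFit:
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as dat:
        return NullModelFit(
            beta0=dat["beta0"], omega0=dat["omega0"], tau=float(dat["tau"]),
            mu0=dat["mu0"], eta0=dat["eta0"], weights=dat["weights"],
            sigma=dat["sigma"], x=dat["x"], y=dat["y"], converged=True,
            n_iter=int(dat["n_iter"]),
        )
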