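"""Per-variant association tests and the genome-scan driver.

All tests share the two-step design: an O(n^3) null-model fit done once
(:mod:`mlrgwas.null_models`), then a cheap per-variant step:

* ``amle_test`` — score/Wald test in the working linear approximation of the
  mixed logistic regression: U = g'(y - mu0), v = g'Pg, gamma_hat = U/v,
  stat = U^2/v.  O(n^2) per variant (one P-vector product).  The Wald test so
  defined is numerically identical to the mixed-model score test.
* ``offset_test`` — one-parameter logistic IRLS of y on the
  covariate-residualized genotype with the null linear predictor held as an
  offset.  O(n) per IRLS iteration.
* ``lr_test`` — plain logistic regression Wald test (no random effect).
* ``mlm_score_test`` — linear-mixed-model score test on the 0/1 status
  (deliberately misspecified comparator; effect on the probability scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .genotypes import GenotypeMatrix
from .null_models import ConvergenceError, LmmNullFit, NullModelFit, _logistic_irls

import pandas as pd

__all__ = [
    "AssociationResult",
    "amle_test",
    "offset_test",
    "offset_linear_gamma",
    "lr_test",
    "mlm_score_test",
    "gwas_scan",
    "write_association_table",
]

OFFSET_MAX_ITER = 50
OFFSET_TOL = 1e-10


@dataclass
class AssociationResult:
    variant_id: str
    gamma_hat: float
    se: float
    stat: float
    p: float
    method: str
    score_u: float | None = None
    status: str = "ok"

    @classmethod
    def failed(cls, variant_id: str, method: str, reason: str) -> "AssociationResult":
        return cls(variant_id, np.nan, np.nan, np.nan, np.nan, method, status=reason)


def _chi2_p(stat: float) -> float:
    return float(chi2.sf(stat, 1))


def _check_g(g: np.ndarray, n: int) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    if g.shape[0] != n:
        raise ValueError(f"genotype vector length {g.shape[0]} != {n} samples")
    if g.min() == g.max():
        raise ValueError("constant genotype vector")
    return g


# ---------------------------------------------------------------------------
# AMLE (== score test)
# ---------------------------------------------------------------------------

def amle_test(null: NullModelFit, g: np.ndarray,
              variant_id: str = "") -> AssociationResult:
    """Approximate-MLE effect estimate and score/Wald test for one variant.

    In the converged working model the log-likelihood in gamma has first
    derivative U = g'(y - mu0) and curvature -v with v = g'Pg, so the
    second-order approximation maximizes at gamma_hat = U/v with variance
    1/v.  T = U^2/v = (gamma_hat/se)^2: the Wald and score statistics are the
    same number.
    """
    g = _check_g(g, null.n_samples)
    u = float(g @ (null.y - null.mu0))
    v = float(g @ null.project(g))
    if v <= 0 or not np.isfinite(v):
        raise ValueError("non-positive score variance: degenerate variant")
    gamma = u / v
    se = 1.0 / np.sqrt(v)
    stat = u * u / v
    return AssociationResult(variant_id, gamma, se, stat, _chi2_p(stat),
                             "amle", score_u=u)


# ---------------------------------------------------------------------------
# Offset method
# ---------------------------------------------------------------------------

def _residualize(g: np.ndarray, x: np.ndarray) -> np.ndarray:
    delta, *_ = np.linalg.lstsq(x, g, rcond=None)
    return g - x @ delta


def _offset_irls_1d(gt: np.ndarray, y: np.ndarray, offset: np.ndarray,
                    max_iter: int = OFFSET_MAX_ITER,
                    tol: float = OFFSET_TOL) -> tuple[float, float]:
    """One-parameter logistic regression of y on gt with a fixed offset.

    Returns (gamma_hat, se); each iteration is O(n).
    """
    gamma = 0.0
    for _ in range(max_iter):
        mu = expit(offset + gt * gamma)
        w = mu * (1.0 - mu)
        denom = float(gt * gt @ w)
        if denom <= 0:
            raise ConvergenceError("degenerate weights in offset regression")
        step = float(gt @ (y - mu)) / denom
        gamma += step
        if abs(step) < tol:
            mu = expit(offset + gt * gamma)
            w = mu * (1.0 - mu)
            return gamma, 1.0 / np.sqrt(float(gt * gt @ w))
    raise ConvergenceError(f"offset IRLS did not converge in {max_iter} iterations")


def offset_test(null: NullModelFit, g: np.ndarray, x: np.ndarray | None = None,
                variant_id: str = "") -> AssociationResult:
    """Two-step offset estimator for one variant.

    The genotype is residualized on the covariates (g_tilde = g - X delta_hat,
    delta_hat by least squares) and gamma is fitted in the one-parameter
    logistic regression logit E(y) = eta0 + g_tilde gamma, the null linear
    predictor eta0 = X beta0 + omega0 entering as a constant offset.
    """
    x = null.x if x is None else np.asarray(x, dtype=float)
    g = _check_g(g, null.n_samples)
    gt = _residualize(g, x)
    gamma, se = _offset_irls_1d(gt, null.y, null.eta0)
    stat = (gamma / se) ** 2
    return AssociationResult(variant_id, gamma, se, stat, _chi2_p(stat), "offset")


def offset_linear_gamma(y: np.ndarray, x: np.ndarray, g: np.ndarray) -> float:
    """Identity-link analogue of the offset two-step procedure.

    Step 1: OLS of y on X alone gives the offset X beta0_hat; step 2: OLS of
    the offset-corrected response on the residualized genotype.  Equals the
    multiple-regression OLS coefficient of g (Frisch–Waugh–Lovell).
    """
    y = np.asarray(y, dtype=float).ravel()
    beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
    gt = _residualize(np.asarray(g, dtype=float).ravel(), x)
    return float(gt @ (y - x @ beta0)) / float(gt @ gt)


# ---------------------------------------------------------------------------
# comparators
# ---------------------------------------------------------------------------

def lr_test(y: np.ndarray, x: np.ndarray, g: np.ndarray,
            variant_id: str = "") -> AssociationResult:
    """Plain logistic-regression Wald test of the genotype coefficient."""
    y = np.asarray(y, dtype=float).ravel()
    g = _check_g(g, y.shape[0])
    xg = np.column_stack([x, g])
    r = np.linalg.qr(xg, mode="r")
    d = np.abs(np.diag(r))
    if d.min() <= 1e-10 * max(d.max(), 1.0):
        raise ValueError("genotype collinear with covariates")
    beta = _logistic_irls(y, xg, max_iter=50)
    mu = expit(xg @ beta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(xg.T @ (xg * w[:, None]))
    gamma = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    stat = (gamma / se) ** 2
    return AssociationResult(variant_id, gamma, se, stat, _chi2_p(stat), "lr")


def mlm_score_test(null: LmmNullFit, g: np.ndarray,
                   variant_id: str = "") -> AssociationResult:
    """Score test in the linear mixed model on the 0/1 status.

    U = g' P_lmm y with variance g' P_lmm g; the reported effect U/var is on
    the linear (probability) scale, not a log-odds ratio.
    """
    g = _check_g(g, null.y.shape[0])
    u = float(g @ null.py)
    v = float(g @ (null.projection @ g))
    if v <= 0 or not np.isfinite(v):
        raise ValueError("non-positive score variance: degenerate variant")
    gamma = u / v
    se = 1.0 / np.sqrt(v)
    stat = u * u / v
    return AssociationResult(variant_id, gamma, se, stat, _chi2_p(stat),
                             "mlm", score_u=u)


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------

def _scan_amle(null: NullModelFit, dosages: np.ndarray) -> dict[str, np.ndarray]:
    resid = null.y - null.mu0
    u = dosages.T @ resid
    pg = null.projection @ dosages          # O(n^2) per variant
    v = np.einsum("ij,ij->j", dosages, pg)
    gamma = np.where(v > 0, u / np.where(v > 0, v, 1.0), np.nan)
    se = np.where(v > 0, 1.0 / np.sqrt(np.where(v > 0, v, 1.0)), np.nan)
    stat = np.where(v > 0, u * u / np.where(v > 0, v, 1.0), np.nan)
    return {"gamma_hat": gamma, "se": se, "stat": stat, "score_u": u}


def _scan_offset(null: NullModelFit, dosages: np.ndarray,
                 x: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized offset scan: all variants iterate IRLS simultaneously.

    Per-variant work per iteration is O(n); variants that converge stop
    moving (their step is frozen), matching the per-variant procedure.
    """
    y = null.y
    eta0 = null.eta0
    q, _ = np.linalg.qr(x)
    gt = dosages - q @ (q.T @ dosages)      # residualized genotypes
    m = gt.shape[1]
    gamma = np.zeros(m)
    active = np.ones(m, dtype=bool)
    ok = np.ones(m, dtype=bool)
    for it in range(OFFSET_MAX_ITER):
        ga = gt[:, active]
        mu = expit(eta0[:, None] + ga * gamma[active])
        w = mu * (1.0 - mu)
        denom = np.einsum("ij,ij->j", ga * ga, w)
        bad = denom <= 0
        step = np.where(bad, 0.0, (np.einsum("ij,ij->j", ga, y[:, None] - mu))
                        / np.where(bad, 1.0, denom))
        gamma[active] = gamma[active] + step
        idx = np.where(active)[0]
        ok[idx[bad]] = False
        done = (np.abs(step) < OFFSET_TOL) | bad
        active[idx[done]] = False
        if not active.any():
            break
    ok &= ~active                           # still-active variants: no convergence
    mu = expit(eta0[:, None] + gt * gamma)
    w = mu * (1.0 - mu)
    v = np.einsum("ij,ij->j", gt * gt, w)
    se = np.where(ok & (v > 0), 1.0 / np.sqrt(np.where(v > 0, v, 1.0)), np.nan)
    gamma = np.where(ok, gamma, np.nan)
    stat = (gamma / se) ** 2
    return {"gamma_hat": gamma, "se": se, "stat": stat}


def gwas_scan(
    null: NullModelFit | LmmNullFit,
    g: GenotypeMatrix,
    method: str = "amle",
    x: np.ndarray | None = None,
    k: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every variant with the requested method; one result row each.

    Per-variant failures (monomorphic, collinear, non-converged) are recorded
    in the ``status`` column, never fatal.  No O(n^3) work happens inside the
    per-variant loop: amle is O(n^2)/variant, offset O(n)/variant.
    """
    if method in ("amle", "offset", "pql") and not isinstance(null, NullModelFit):
        raise TypeError(f"method {method!r} needs a PQL NullModelFit")
    if method == "mlm" and not isinstance(null, LmmNullFit):
        raise TypeError("method 'mlm' needs an LmmNullFit")
    n = null.y.shape[0]
    if g.n_samples != n:
        raise ValueError(
            f"sample mismatch: null model has {n} samples, genotypes {g.n_samples}"
        )
    x = null.x if x is None else np.asarray(x, dtype=float)
    dosages = g.imputed()
    m = g.n_variants
    freq = g.alt_freq if m else np.empty(0)
    out = {
        "chrom": g.variants["chrom"].to_numpy() if m else np.empty(0, object),
        "pos": g.variants["pos"].to_numpy() if m else np.empty(0, int),
        "id": g.variants["id"].to_numpy() if m else np.empty(0, object),
        "ref": g.variants["ref"].to_numpy() if m else np.empty(0, object),
        "alt": g.variants["alt"].to_numpy() if m else np.empty(0, object),
        "freq": freq,
    }
    status = np.full(m, "ok", dtype=object)
    poly = np.array([dosages[:, j].min() != dosages[:, j].max() for j in range(m)]) \
        if m else np.zeros(0, bool)
    status[~poly] = "monomorphic"

    if method == "amle" and m:
        res = _scan_amle(null, dosages)
    elif method == "offset" and m:
        res = _scan_offset(null, dosages, x)
    else:
        res = {"gamma_hat": np.full(m, np.nan), "se": np.full(m, np.nan),
               "stat": np.full(m, np.nan)}
        for j in range(m):
            if not poly[j]:
                continue
            try:
                if method == "lr":
                    r = lr_test(null.y, x, dosages[:, j])
                elif method == "mlm":
                    r = mlm_score_test(null, dosages[:, j])
                elif method == "pql":
                    from .null_models import fit_pql_snp
                    k_mat = _grm_of(null) if k is None else k
                    gam, se, _ = fit_pql_snp(null.y, x, dosages[:, j], k_mat)
                    r = AssociationResult("", gam, se, (gam / se) ** 2,
                                          _chi2_p((gam / se) ** 2), "pql")
                else:
                    raise ValueError(f"unknown method {method!r}")
            except (ValueError, ConvergenceError) as exc:
                status[j] = f"error: {exc}"
                continue
            res["gamma_hat"][j] = r.gamma_hat
            res["se"][j] = r.se
            res["stat"][j] = r.stat

    for key in ("gamma_hat", "se", "stat"):
        arr = res[key].astype(float)
        arr[~poly] = np.nan
        out[key] = arr
    with np.errstate(invalid="ignore"):
        out["p"] = chi2.sf(out["stat"], 1)
    bad = poly & ~np.isfinite(out["stat"])
    status[bad & (status == "ok")] = "failed"
    out["method"] = method
    out["status"] = status
    return pd.DataFrame(out)


def _grm_of(null: NullModelFit) -> np.ndarray:
    # recover tau*K + W^{-1} -> K; only used by the slow reference scan
    w_inv = 1.0 / null.weights
    k = null.sigma - np.diag(w_inv)
    if null.tau > 0:
        k = k / null.tau
    return k


def write_association_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
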