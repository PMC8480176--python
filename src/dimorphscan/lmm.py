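"""EMMA-style mixed-model machinery shared by phenotype adjustment and MLMA.

The model is ``y = X b + u + e`` with ``u ~ N(0, sigma_u2 K)`` and
``e ~ N(0, sigma_e2 I)``.  One eigendecomposition ``K = U D U'`` turns the
covariance into a diagonal ``sigma_e2 (lambda D + I)`` in the rotated basis,
so REML reduces to a 1-D profile optimization over the variance ratio
``lambda = sigma_u2 / sigma_e2`` and every downstream GLS solve is a weighted
least squares in rotated coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_LAMBDA_LO = -8.0
_LOG_LAMBDA_HI = 8.0


@dataclass
class EigenContext:
    """Rotation shared by the REML fit and the per-SNP scan."""

    U: np.ndarray  # eigenvectors of K, columns
    d: np.ndarray  # eigenvalues of K, clipped at 0


def eigen_context(K: np.ndarray) -> EigenContext:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("relationship matrix must be square")
    d, U = np.linalg.eigh(K)
    return EigenContext(U=U, d=np.clip(d, 0.0, None))


def _profile_reml(
    lam: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """REML log-likelihood profiled over sigma_e2 at fixed ratio ``lam``.

    Returns ``(loglik, beta_hat, sigma_e2_hat)``.
    """
    n, p = Xt.shape
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    sigma_e2 = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    if sign <= 0 or sigma_e2 <= 0:
        return -np.inf, beta, max(sigma_e2, 0.0)
    ll = -0.5 * (
        (n - p) * np.log(sigma_e2)
        + float(np.sum(np.log(w)))
        + logdet_xx
        + (n - p)
    )
    return ll, beta, sigma_e2


@dataclass
class RemlResult:
    sigma_u2: float
    sigma_e2: float
    log_likelihood: float
    beta: np.ndarray
    lam: float
    ctx: EigenContext


def reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    ctx: EigenContext | None = None,
) -> RemlResult:
    """Restricted-maximum-likelihood fit of the single-kernel mixed model.

    Parameters
    ----------
    y : phenotype vector, finite.
    X : fixed-effect design matrix, full column rank.
    K : relationship matrix (ignored when ``ctx`` is given).
    ctx : precomputed eigendecomposition of ``K``.

    The profile likelihood is maximized over ``log10(lambda)`` on a bounded
    interval with the boundary ``lambda = 0`` (no genetic variance) checked
    explicitly, so a null heritability is an attainable optimum rather than a
    numerical limit.  The optimizer is deterministic: identical inputs yield
    identical estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and phenotype length differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    if ctx is None:
        if K is None:
            raise ValueError("either K or a precomputed eigen context is required")
        ctx = eigen_context(K)
    yt = ctx.U.T @ y
    Xt = ctx.U.T @ X

    def neg_ll(log_lam: float) -> float:
        return -_profile_reml(10.0**log_lam, yt, Xt, ctx.d)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = 10.0 ** float(res.x)
    ll, beta, sigma_e2 = _profile_reml(lam, yt, Xt, ctx.d)
    ll0, beta0, sigma_e20 = _profile_reml(0.0, yt, Xt, ctx.d)
    if ll0 >= ll:
        lam, ll, beta, sigma_e2 = 0.0, ll0, beta0, sigma_e20
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite REML likelihood")
    return RemlResult(
        sigma_u2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        log_likelihood=ll,
        beta=beta,
        lam=lam,
        ctx=ctx,
    )


def gls_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    ctx: EigenContext,
    sigma_u2: float,
    sigma_e2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP GLS allele substitution effects with fixed variance components.

    Fits ``y = mu + x b`` under ``V = sigma_u2 K + sigma_e2 I`` for every
    column of ``dosages`` (no missing values; impute upstream) and returns
    ``(beta, se)`` arrays.  Variance components are NOT re-estimated per SNP.
    The whole scan is vectorized through the 2x2 normal equations of the
    rotated weighted regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("dosage rows must match the phenotype length")
    if np.isnan(X).any():
        raise ValueError("scan requires imputed (non-missing) dosages")
    w = sigma_u2 * ctx.d + sigma_e2
    yt = ctx.U.T @ y
    ones_t = ctx.U.T @ np.ones_like(y)
    Xt = ctx.U.T @ X
    inv_w = 1.0 / w
    a11 = float(ones_t @ (ones_t * inv_w))
    b1 = float(ones_t @ (yt * inv_w))
    a12 = (ones_t * inv_w) @ Xt
    a22 = inv_w @ (Xt * Xt)
    b2 = (yt * inv_w) @ Xt
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        var_b = a11 / det
        se = np.sqrt(var_b)
    return beta, se
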