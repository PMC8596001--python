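"""Mean vectors and covariance matrices of the candidate trait models.

Seven Gaussian models of continuous-trait evolution on a (possibly
fossil-tip) phylogeny: Brownian motion (BM), BM with a directional trend,
single-optimum Ornstein–Uhlenbeck (OU), Pagel's lambda, kappa and delta
branch-length transforms, and a clade-mixed trend+BM model in which one
designated clade evolves by plain BM while the rest of the tree carries the
directional trend.

Every model induces a multivariate normal tip distribution
``x ~ N(D beta, sigma2 * V0(shape))`` where ``D`` is a small design matrix
(all-ones, plus a time/exposure column for the trend models), ``V0`` depends
only on the single shape parameter, and ``sigma2`` scales the whole
covariance.  This factorization is what lets the fitting module profile the
mean and rate analytically and optimize each model in one dimension.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .tree import Phylogeny, RegimePainting

__all__ = [
    "MODEL_NAMES",
    "SHAPE_PARAM",
    "DEFAULT_BOUNDS",
    "transform_lambda",
    "transform_kappa",
    "transform_delta",
    "ou_covariance",
    "model_mean_design_cov",
    "mvn_loglik",
    "gls_coefficients",
]

MODEL_NAMES = ("BM", "trend", "OU", "lambda", "kappa", "delta", "trend_BM")

#: name of the single shape/trend parameter per model (None for BM)
SHAPE_PARAM = {
    "BM": None,
    "trend": "mu",
    "OU": "alpha",
    "lambda": "lambda",
    "kappa": "kappa",
    "delta": "delta",
    "trend_BM": "mu",
}

#: default optimization bounds for the shape parameters; alpha's upper
#: bound is expressed per unit tree depth and rescaled at fit time
DEFAULT_BOUNDS = {
    "lambda": (0.0, 1.0),
    "kappa": (0.0, 1.0),
    "delta": (1e-5, 3.0),
    "alpha": (1e-9, 50.0),
}


def transform_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: shrink off-diagonal covariances toward a star tree."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def transform_kappa(tree: Phylogeny, kappa: float) -> Phylogeny:
    """Raise every branch length to the power kappa (0^kappa := 0).

    kappa -> 0 makes all change speciational: each branch contributes one
    unit regardless of its duration.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    return tree.with_branch_lengths(_kappa_weights(tree, kappa))


def _kappa_weights(tree: Phylogeny, kappa: float) -> np.ndarray:
    b = tree.blen
    w = np.zeros_like(b)
    pos = b > 0
    w[pos] = b[pos] ** kappa
    return w


def transform_delta(tree: Phylogeny, delta: float) -> Phylogeny:
    """Raise node ages-from-root to the power delta, then rescale.

    delta < 1 concentrates change early in the tree, delta > 1 late.  After
    the age transform the tree is rescaled so its maximum tip depth equals
    the original, keeping sigma^2 comparable across delta values.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    return tree.with_branch_lengths(_delta_weights(tree, delta))


def _delta_weights(tree: Phylogeny, delta: float) -> np.ndarray:
    ages = tree.node_depths()
    T = ages[tree.tips].max()
    scale = T / T**delta if T > 0 else 1.0
    new_ages = ages**delta * scale
    w = np.zeros(tree.n_nodes)
    w[1:] = new_ages[1:] - new_ages[tree.parent[1:]]
    return w


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float = 1.0) -> np.ndarray:
    """Tip covariance of a single-optimum OU process, root at the optimum.

    Valid on non-ultrametric trees:
    ``V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha C_ij))``
    with ``d_ij`` the patristic distance and ``C`` the shared path matrix.
    Exponentials are clamped so large ``alpha * T`` cannot overflow.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    C = tree.vcv()
    T = np.diag(C)
    d = T[:, None] + T[None, :] - 2.0 * C
    with np.errstate(over="ignore", under="ignore"):
        V = (
            (sigma2 / (2.0 * alpha))
            * np.exp(np.clip(-alpha * d, -745.0, 0.0))
            * (-np.expm1(np.clip(-2.0 * alpha * C, -745.0, 0.0)))
        )
    return 0.5 * (V + V.T)


def model_mean_design_cov(
    name: str,
    tree: Phylogeny,
    shape: float | None = None,
    painting: RegimePainting | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix D and unit-rate covariance V0 for one model.

    The tip distribution is ``N(D beta, sigma2 V0)``.  For BM/lambda/kappa/
    delta/OU the design is the all-ones column (beta = z0, the root state;
    for OU the root sits at the single optimum).  For trend, D gains the
    tip-depth column; for trend_BM, the trend-exposure column from the
    painting (time spent on trend-regime branches).
    """
    n = tree.n_tips
    ones = np.ones((n, 1))
    if name == "BM":
        return ones, tree.vcv()
    if name == "lambda":
        return ones, transform_lambda(tree.vcv(), shape)
    if name == "kappa":
        return ones, tree.vcv(weights=_kappa_weights(tree, shape))
    if name == "delta":
        return ones, tree.vcv(weights=_delta_weights(tree, shape))
    if name == "OU":
        return ones, ou_covariance(tree, shape)
    if name == "trend":
        D = np.column_stack([np.ones(n), tree.tip_depths()])
        return D, tree.vcv()
    if name == "trend_BM":
        if painting is None:
            raise ValueError("trend_BM requires a regime painting")
        D = np.column_stack([np.ones(n), painting.trend_exposure()])
        return D, tree.vcv()
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


class NotPositiveDefiniteError(linalg.LinAlgError):
    pass


def _cholesky(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        w_min = float(linalg.eigvalsh(V, subset_by_index=(0, 0))[0])
        raise NotPositiveDefiniteError(
            f"covariance is not positive definite (smallest eigenvalue "
            f"{w_min:.3e}); zero-length or duplicated branches may need jitter"
        ) from None


def mvn_loglik(x: np.ndarray, m: np.ndarray, V: np.ndarray) -> float:
    """Exact multivariate-normal log density via Cholesky factorization."""
    x = np.asarray(x, float)
    m = np.broadcast_to(np.asarray(m, float), x.shape)
    n = x.size
    L = _cholesky(V)
    u = linalg.solve_triangular(L, x - m, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + u @ u))


def gls_coefficients(
    x: np.ndarray, V: np.ndarray, D: np.ndarray, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Generalized least squares of x on design D under covariance V.

    Returns ``(beta, cov_unit, rss, logdet)`` where ``beta`` solves the GLS
    normal equations via the Cholesky-whitened problem, ``cov_unit`` is
    ``(D' V^-1 D)^-1`` (multiply by sigma^2 for the coefficient covariance),
    ``rss = (x - D beta)' V^-1 (x - D beta)``, and ``logdet = ln|V|``.

    A rank-deficient whitened design signals a confounded model (e.g. the
    trend slope on an ultrametric tree, where tip depth is constant).
    """
    x = np.asarray(x, float)
    D = np.atleast_2d(np.asarray(D, float))
    L = _cholesky(V)
    Dw = linalg.solve_triangular(L, D, lower=True)
    xw = linalg.solve_triangular(L, x, lower=True)
    q, r = np.linalg.qr(Dw)
    diag = np.abs(np.diag(r))
    if diag.min() <= rank_tol * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError(
            "design is rank deficient under this covariance (confounded "
            "mean parameters, e.g. a trend slope on an ultrametric tree)"
        )
    beta = linalg.solve_triangular(r, q.T @ xw, lower=False)
    resid = xw - Dw @ beta
    rss = float(resid @ resid)
    rinv = linalg.solve_triangular(r, np.eye(r.shape[0]), lower=False)
    cov_unit = rinv @ rinv.T
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, cov_unit, rss, logdet


def profile_loglik(
    x: np.ndarray, V0: np.ndarray, D: np.ndarray
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Maximize the Gaussian likelihood over sigma2 and the mean analytically.

    For ``x ~ N(D beta, sigma2 V0)`` the ML estimates are the GLS ``beta``
    and ``sigma2 = rss / n``; returns ``(loglik, beta, sigma2_hat, cov_unit)``.
    """
    n = x.size
    beta, cov_unit, rss, logdet = gls_coefficients(x, V0, D)
    if rss <= 0:
        # degenerate: data exactly in the column span of D
        rss = np.finfo(float).tiny
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(ll), beta, float(sigma2), cov_unit
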