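"""n-branch Gaussian mixture: density evaluation, EM fitting, sampling.

The branch density is the standard d-variate normal
(2*pi)^(-d/2) |S|^(-1/2) exp(-1/2 (a-mu)^T S^-1 (a-mu)); the mixture is the
weight-weighted sum of branch densities.  Covariances are kept invertible by
flooring: eigenvalues are clipped to at least COV_FLOOR after every M-step,
and parameters whose covariance has an eigenvalue below the floor are
rejected at validation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .util import ValidationError, as_rng

__all__ = ["GMMParams", "COV_FLOOR", "gmm_pdf", "gmm_logpdf", "fit_gmm_em", "sample_gmm"]

COV_FLOOR = 1e-6


@dataclass(frozen=True)
class GMMParams:
    weights: np.ndarray  # (n,)
    means: np.ndarray  # (n, d)
    covariances: np.ndarray  # (n, d, d)
    fit_log_likelihoods: tuple[float, ...] | None = None  # set by fit_gmm_em

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        mu = np.asarray(self.means, dtype=np.float64)
        cov = np.asarray(self.covariances, dtype=np.float64)
        if w.ndim != 1 or mu.ndim != 2 or cov.ndim != 3:
            raise ValidationError("wrong parameter array ranks")
        n, d = mu.shape
        if w.shape != (n,) or cov.shape != (n, d, d):
            raise ValidationError("inconsistent mixture parameter shapes")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must be non-negative and sum to 1")
        for k in range(n):
            if not np.allclose(cov[k], cov[k].T, atol=1e-10):
                raise ValidationError(f"covariance {k} not symmetric")
            if np.linalg.eigvalsh(cov[k]).min() < COV_FLOOR * (1 - 1e-6):
                raise ValidationError(f"covariance {k} below the {COV_FLOOR} eigenvalue floor")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)

    @property
    def n(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _branch_logpdf(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mu.shape[0]
    L = np.linalg.cholesky(cov)
    diff = X - mu
    sol = np.linalg.solve(L, diff.T)  # (d, N)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _all_branch_logpdf(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """(N, n) matrix of log branch densities."""
    return np.stack(
        [_branch_logpdf(X, params.means[k], params.covariances[k]) for k in range(params.n)],
        axis=1,
    )


def gmm_logpdf(X: np.ndarray, params: GMMParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != params.d:
        raise ValidationError(f"points have dimension {X.shape[1]}, mixture has {params.d}")
    lb = _all_branch_logpdf(X, params)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    return logsumexp(lb + logw, axis=1)


def gmm_pdf(a: np.ndarray, params: GMMParams) -> float:
    """Mixture density at a single point."""
    return float(np.exp(gmm_logpdf(np.atleast_2d(a), params))[0])


def _floor_cov(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and clip eigenvalues to at least COV_FLOOR."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, COV_FLOOR)
    return (vecs * vals) @ vecs.T


def _kmeanspp_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(len(X))]]
    for _ in range(1, k):
        d2 = np.min(
            np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
        )
        if d2.sum() <= 0:
            centers.append(X[rng.integers(len(X))])
            continue
        probs = d2 / d2.sum()
        centers.append(X[rng.choice(len(X), p=probs)])
    return np.stack(centers)


def fit_gmm_em(
    samples: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GMMParams:
    """Fit a mixture by EM with a k-means++-style seeded initialisation.

    The per-iteration mean log-likelihood trace is attached to the result as
    ``fit_log_likelihoods`` (non-decreasing up to floating-point slack).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    N, d = X.shape
    if N < n_components:
        raise ValidationError(f"{N} samples < {n_components} components")
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    rng = as_rng(seed)

    centers = _kmeanspp_centers(X, n_components, rng)
    assign = np.argmin(
        np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
    )
    weights = np.full(n_components, 1.0 / n_components)
    means = centers.copy()
    global_cov = _floor_cov(np.cov(X, rowvar=False).reshape(d, d))
    covs = np.stack([global_cov.copy() for _ in range(n_components)])
    for k in range(n_components):
        pts = X[assign == k]
        if len(pts) >= 2:
            means[k] = pts.mean(axis=0)
            covs[k] = _floor_cov(np.cov(pts, rowvar=False).reshape(d, d))
            weights[k] = len(pts) / N

    weights = weights / weights.sum()
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        params = GMMParams(weights=weights, means=means, covariances=covs)
        lb = _all_branch_logpdf(X, params)
        with np.errstate(divide="ignore"):
            joint = lb + np.log(weights)
        norm = logsumexp(joint, axis=1)
        ll = float(np.mean(norm))
        ll_trace.append(ll)
        resp = np.exp(joint - norm[:, None])  # (N, n)

        nk = resp.sum(axis=0)
        weights = nk / N
        weights = np.clip(weights, 1e-12, None)
        weights = weights / weights.sum()
        means = (resp.T @ X) / np.clip(nk, 1e-12, None)[:, None]
        covs = np.empty_like(covs)
        for k in range(n_components):
            diff = X - means[k]
            covs[k] = _floor_cov(
                (resp[:, k][:, None] * diff).T @ diff / max(nk[k], 1e-12)
            )

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    return GMMParams(
        weights=weights,
        means=means,
        covariances=covs,
        fit_log_likelihoods=tuple(ll_trace),
    )


def sample_gmm(params: GMMParams, n_draws: int, seed: int = 0) -> np.ndarray:
    """Draw (n_draws, d) points: branch chosen by weight, then a Gaussian draw."""
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = as_rng(seed)
    branches = rng.choice(params.n, size=n_draws, p=params.weights)
    out = np.empty((n_draws, params.d))
    for k in range(params.n):
        idx = np.where(branches == k)[0]
        if len(idx):
            out[idx] = rng.multivariate_normal(
                params.means[k], params.covariances[k], size=len(idx), method="cholesky"
            )
    return out
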