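"""EM-optimized Gaussian-mixture refinement of a curve-tree skeleton.

The skeleton points S = {s_1..s_m} of the resampled curve tree are treated
as centroids of isotropic Gaussians, and the original cloud P = {p_1..p_n}
as observations of the mixture; a uniform component of weight eps absorbs
outliers.  Correspondence priors alpha_ij = exp(-alpha*|mu_i - mu_j|)
compare local-PCA shape descriptors mu = lambda_0 / (lambda_0+lambda_1+
lambda_2) of the neighbourhoods of the two sets.  Minimizing the negative
log-likelihood

    L = -sum_j log( eps/n + (1-eps) * sum_i alpha_ij * N(p_j; s_i, sigma^2 I) )

by EM, with the displacement field parameterized coherently as
s' = s + G*W over the Gaussian kernel G[i,i'] = exp(-||s_i - s_i'||^2 /
(2 beta^2)) and penalized by (lambda/2) tr(W^T G W), moves every skeleton
point toward the local centroid of its supporting cloud points — i.e. onto
the centerline of tube-like branches — while keeping the displacement field
smooth along the skeleton.  The M-step has the closed form

    (G + lambda*sigma^2*diag(P1)^(-1)) W = diag(P1)^(-1) (Ppost @ P) - S0

with P1 the posterior row sums, after which sigma^2 and eps are re-estimated
from the posterior-weighted residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .tree import CurveTree

__all__ = [
    "GMMParams",
    "init_sigma2",
    "local_pca_mu",
    "membership",
    "e_step",
    "m_step",
    "negative_log_likelihood",
    "refine",
    "GMMSkeletonRefiner",
]

_D = 3  # ambient dimension


@dataclass
class GMMParams:
    """Parameters of the refinement mixture and EM loop.

    sigma2 is the (shared, isotropic) Gaussian variance in mm^2; epsilon the
    uniform outlier weight; lambda_reg and beta_kernel weight and widen the
    displacement smoothness penalty; alpha_tune scales the membership decay;
    knn is the cloud neighbourhood size for the local-PCA descriptors.
    """

    lambda_reg: float = 5.0
    beta_kernel: float = 5.0
    alpha_tune: float = 1.0
    epsilon0: float = 0.1
    tol: float = 1e-4
    max_iter: int = 100
    knn: int = 20
    epsilon_bounds: tuple[float, float] = (0.01, 0.99)
    sigma2_min_rel: float = 1e-8  # times squared bbox diagonal

    def validate(self) -> None:
        if not (0 <= self.epsilon0 < 1):
            raise ValueError("epsilon0 must be in [0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.beta_kernel <= 0 or self.lambda_reg < 0:
            raise ValueError("beta_kernel must be > 0, lambda_reg >= 0")


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(|A|, |B|) matrix of squared Euclidean distances."""
    d = A[:, None, :] - B[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def init_sigma2(P: np.ndarray, S: np.ndarray) -> float:
    """Initial shared variance: mean squared pairwise distance over d=3.

    sigma_0^2 = (1 / (d m n)) * sum_i sum_j ||p_j - s_i||^2.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n, m = P.shape[0], S.shape[0]
    if n == 0 or m == 0:
        raise ValueError("empty point set")
    # expand the double sum through first/second moments (O(n + m))
    total = (
        m * float(np.sum(P * P))
        + n * float(np.sum(S * S))
        - 2.0 * float(np.dot(S.sum(axis=0), P.sum(axis=0)))
    )
    return total / (_D * m * n)


def local_pca_mu(
    points: np.ndarray,
    query: np.ndarray | None = None,
    k: int = 20,
    radius: float | None = None,
) -> np.ndarray:
    """Normalized smallest covariance eigenvalue of each local neighbourhood.

    For each query point, the neighbourhood is the k nearest points of
    ``points`` (default) or all points within ``radius`` of it; mu =
    lambda_0/(lambda_0+lambda_1+lambda_2) of the neighbourhood's 3x3
    covariance, in [0, 1/3].  Surface-like neighbourhoods give mu ~ 0,
    volumetric ones mu ~ 1/3.  Degenerate neighbourhoods (fewer than 3
    points, or zero total variance) give mu = 0 with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    Q = pts if query is None else np.atleast_2d(np.asarray(query, dtype=float))
    tree = cKDTree(pts)
    mu = np.zeros(Q.shape[0])
    if radius is not None:
        warned = False
        for qi, groups in enumerate(tree.query_ball_point(Q, r=radius)):
            neigh = pts[groups]
            if neigh.shape[0] < 3:
                if not warned:
                    warnings.warn("degenerate neighbourhood (<3 points); mu set to 0")
                    warned = True
                continue
            ev = np.linalg.eigvalsh(np.cov(neigh.T, bias=True))
            tot = ev.sum()
            if tot > 0:
                mu[qi] = ev[0] / tot
        return np.clip(mu, 0.0, 1.0 / 3.0)
    k_eff = min(k, pts.shape[0])
    if k_eff < 3:
        warnings.warn("degenerate neighbourhood (<3 points); mu set to 0")
        return mu
    _, idx = tree.query(Q, k=k_eff)
    neigh = pts[idx]  # (q, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("qki,qkj->qij", centered, centered) / k_eff
    ev = np.linalg.eigvalsh(cov)  # ascending
    tot = ev.sum(axis=1)
    ok = tot > 0
    mu[ok] = ev[ok, 0] / tot[ok]
    return np.clip(mu, 0.0, 1.0 / 3.0)


def membership(
    mu_s: np.ndarray, mu_p: np.ndarray, alpha_tune: float = 1.0
) -> np.ndarray:
    """Correspondence prior alpha_ij = exp(-alpha * |mu_i - mu_j|), (m, n)."""
    return np.exp(-alpha_tune * np.abs(mu_s[:, None] - mu_p[None, :]))


def _log_outlier_const(sigma2: float, epsilon: float, n: int) -> float:
    """log of eps*(2*pi*sigma^2)^(d/2) / (n*(1-eps)); -inf when eps = 0."""
    if epsilon >= 1.0:
        raise ValueError("epsilon must be < 1")
    if epsilon == 0.0:
        return -np.inf
    return (
        np.log(epsilon)
        + (_D / 2.0) * np.log(2.0 * np.pi * sigma2)
        - np.log(n * (1.0 - epsilon))
    )


def e_step(
    P: np.ndarray,
    S: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior responsibilities of skeleton points for each cloud point.

    Returns (p_old, outlier_mass): p_old[i, j] is the posterior that cloud
    point j came from centroid i, outlier_mass[j] the posterior of the
    uniform component; each column plus its outlier mass sums to 1.
    Computed in log space (max-subtraction) so arbitrarily far points are
    safe.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    P = np.atleast_2d(P)
    S = np.atleast_2d(S)
    n = P.shape[0]
    logE = np.log(np.maximum(alpha, 1e-300)) - _sqdist(S, P) / (2.0 * sigma2)
    log_c = _log_outlier_const(sigma2, epsilon, n)
    M = np.maximum(logE.max(axis=0), log_c if np.isfinite(log_c) else -np.inf)
    denom = np.exp(logE - M).sum(axis=0)
    if np.isfinite(log_c):
        denom = denom + np.exp(log_c - M)
    p_old = np.exp(logE - M) / denom
    outlier = (np.exp(log_c - M) / denom) if np.isfinite(log_c) else np.zeros(n)
    return p_old, outlier


def negative_log_likelihood(
    P: np.ndarray,
    S: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
    epsilon: float,
) -> float:
    """Mixture energy L = -sum_j log(eps/n + (1-eps) sum_i alpha_ij N_ij)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    P = np.atleast_2d(P)
    S = np.atleast_2d(S)
    n = P.shape[0]
    log_norm = -(_D / 2.0) * np.log(2.0 * np.pi * sigma2)
    logE = (
        np.log(np.maximum(alpha, 1e-300))
        - _sqdist(S, P) / (2.0 * sigma2)
        + log_norm
        + (np.log1p(-epsilon) if epsilon < 1 else -np.inf)
    )
    log_u = np.log(epsilon / n) if epsilon > 0 else -np.inf
    M = np.maximum(logE.max(axis=0), log_u)
    M = np.where(np.isfinite(M), M, 0.0)
    inner = np.exp(logE - M).sum(axis=0)
    if np.isfinite(log_u):
        inner = inner + np.exp(log_u - M)
    return float(-(np.log(inner) + M).sum())


def gaussian_kernel(S0: np.ndarray, beta_kernel: float) -> np.ndarray:
    """Smoothness kernel G[i, i'] = exp(-||s_i - s_i'||^2 / (2 beta^2))."""
    return np.exp(-_sqdist(S0, S0) / (2.0 * beta_kernel**2))


def m_step(
    P: np.ndarray,
    S0: np.ndarray,
    p_old: np.ndarray,
    G: np.ndarray,
    sigma2: float,
    params: GMMParams,
    sigma2_min: float = 1e-12,
) -> tuple[np.ndarray, float, float]:
    """Closed-form update of (W, sigma2, epsilon) from the posteriors.

    W solves (G + lambda*sigma2*diag(P1)^(-1)) W = diag(P1)^(-1)(p_old @ P) - S0,
    the stationarity condition of the expected complete negative
    log-likelihood plus (lambda/2) tr(W^T G W).  The new variance is the
    posterior-weighted mean squared residual over d*xi, and
    epsilon = clip(1 - xi/n, eps_min, eps_max) with xi = sum(p_old).
    """
    P = np.atleast_2d(P)
    S0 = np.atleast_2d(S0)
    n, m = P.shape[0], S0.shape[0]
    P1 = p_old.sum(axis=1)  # (m,)
    xi = float(P1.sum())
    P1s = np.maximum(P1, 1e-12)
    A = G + params.lambda_reg * sigma2 * np.diag(1.0 / P1s)
    rhs = (p_old @ P) / P1s[:, None] - S0
    try:
        W = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular M-step system; adding regularization jitter")
        W = np.linalg.solve(A + 1e-8 * np.trace(A) / m * np.eye(m), rhs)
    T = S0 + G @ W
    Pt1 = p_old.sum(axis=0)  # (n,)
    if xi <= 0:
        return W, max(sigma2, sigma2_min), params.epsilon_bounds[1]
    resid = (
        float(np.dot(Pt1, np.einsum("ij,ij->i", P, P)))
        - 2.0 * float(np.sum((p_old @ P) * T))
        + float(np.dot(P1, np.einsum("ij,ij->i", T, T)))
    )
    sigma2_new = max(resid / (xi * _D), sigma2_min)
    eps_lo, eps_hi = params.epsilon_bounds
    epsilon_new = float(np.clip(1.0 - xi / n, eps_lo, eps_hi))
    return W, sigma2_new, epsilon_new


@dataclass
class RefineTrace:
    """Per-iteration EM diagnostics."""

    nll: list[float] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)  # nll + smoothness penalty
    sigma2: list[float] = field(default_factory=list)
    epsilon: list[float] = field(default_factory=list)
    mean_displacement: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def refine(
    P: np.ndarray, ct: CurveTree, params: GMMParams | None = None
) -> tuple[CurveTree, RefineTrace]:
    """Run the full EM loop and return the refined curve tree plus a trace.

    The membership matrix is computed once on the initial geometry (both
    descriptor sets use cloud neighbourhoods) and frozen; the loop
    alternates responsibilities (E) and the coherent-displacement /
    variance / outlier-weight update (M) until the largest relative change
    among sigma^2, epsilon and mean displacement drops below ``tol``.
    """
    if params is None:
        params = GMMParams()
    params.validate()
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] == 0:
        raise ValueError("cloud must be a non-empty (n, 3) array")
    S0 = ct.all_points
    m, n = S0.shape[0], P.shape[0]
    if m == 0:
        raise ValueError("curve tree has no points")

    diag = float(np.linalg.norm(P.max(axis=0) - P.min(axis=0)))
    sigma2_min = params.sigma2_min_rel * max(diag, 1e-6) ** 2

    mu_p = local_pca_mu(P, k=params.knn)
    mu_s = local_pca_mu(P, query=S0, k=params.knn)
    alpha = membership(mu_s, mu_p, params.alpha_tune)

    G = gaussian_kernel(S0, params.beta_kernel)
    W = np.zeros_like(S0)
    T = S0.copy()
    sigma2 = max(init_sigma2(P, S0), sigma2_min)
    epsilon = params.epsilon0

    trace = RefineTrace()
    for it in range(params.max_iter):
        p_old, _ = e_step(P, T, alpha, sigma2, epsilon)
        W, sigma2_new, epsilon_new = m_step(
            P, S0, p_old, G, sigma2, params, sigma2_min
        )
        T_new = S0 + G @ W
        disp = float(np.mean(np.linalg.norm(T_new - T, axis=1)))
        penalty = 0.5 * params.lambda_reg * float(np.sum(W * (G @ W)))
        trace.nll.append(negative_log_likelihood(P, T_new, alpha, sigma2_new, epsilon_new))
        trace.objective.append(trace.nll[-1] + penalty)
        trace.sigma2.append(sigma2_new)
        trace.epsilon.append(epsilon_new)
        trace.mean_displacement.append(disp)

        rel = max(
            abs(sigma2_new - sigma2) / max(sigma2, sigma2_min),
            abs(epsilon_new - epsilon) / max(epsilon, 1e-12),
            disp / max(diag, 1e-12),
        )
        sigma2, epsilon, T = sigma2_new, epsilon_new, T_new
        trace.n_iter = it + 1
        if rel < params.tol:
            trace.converged = True
            break
    if not trace.converged:
        warnings.warn(
            f"EM did not converge within {params.max_iter} iterations "
            f"(last relative change {rel:.2e})"
        )
    return ct.with_points(T), trace


class GMMSkeletonRefiner(BaseEstimator):
    """Refine a curve-tree skeleton against a point cloud by EM.

    sklearn-style front end to :func:`refine`: parameters mirror
    :class:`GMMParams`; ``fit(X, curve_tree=ct)`` runs the EM loop on the
    cloud ``X`` (n, 3).

    Attributes
    ----------
    curve_tree_ : CurveTree
        Refined skeleton with identical topology.
    trace_ : RefineTrace
        Per-iteration (NLL, sigma^2, epsilon, displacement) history.
    sigma2_, epsilon_ : float
        Final mixture parameters.
    n_iter_ : int
    """

    def __init__(
        self,
        lambda_reg: float = 5.0,
        beta_kernel: float = 5.0,
        alpha_tune: float = 1.0,
        epsilon0: float = 0.1,
        tol: float = 1e-4,
        max_iter: int = 100,
        knn: int = 20,
    ):
        self.lambda_reg = lambda_reg
        self.beta_kernel = beta_kernel
        self.alpha_tune = alpha_tune
        self.epsilon0 = epsilon0
        self.tol = tol
        self.max_iter = max_iter
        self.knn = knn

    def _params(self) -> GMMParams:
        return GMMParams(
            lambda_reg=self.lambda_reg,
            beta_kernel=self.beta_kernel,
            alpha_tune=self.alpha_tune,
            epsilon0=self.epsilon0,
            tol=self.tol,
            max_iter=self.max_iter,
            knn=self.knn,
        )

    def fit(self, X: np.ndarray, y=None, *, curve_tree: CurveTree) -> "GMMSkeletonRefiner":
        ct, trace = refine(np.asarray(X, dtype=float), curve_tree, self._params())
        self.curve_tree_ = ct
        self.trace_ = trace
        self.sigma2_ = trace.sigma2[-1]
        self.epsilon_ = trace.epsilon[-1]
        self.n_iter_ = trace.n_iter
        return self
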