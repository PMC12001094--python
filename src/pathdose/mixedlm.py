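"""Maximum-likelihood fitting of the pathway linear mixed model.

The model, for gene j = 1..J observed at the same n samples:

    y_j = X beta + Z b_j + e_j,
    b_j ~ N(0, sigma^2 * Lambda),   Lambda = diag(theta_1^2, ..., theta_q^2)
    e_j ~ N(0, sigma^2 * W_j^{-1})

with a shared fixed-effect design X (intercept + dose terms), a per-gene
random-effect design Z (intercept and, for mixed dose models, the dose
terms), independent random effects across genes and coordinates (diagonal
covariance, parameterized relative to the residual variance), and optional
per-observation precision weights W_j.

Fitting is by maximum likelihood (not REML) so that likelihood-ratio tests
and AIC comparisons across different fixed-effect structures are valid.
beta and sigma^2 are profiled out analytically; the q relative
random-effect standard deviations theta are optimized on the log scale
with L-BFGS-B. All per-gene linear algebra is batched (gene blocks share
the sample design, so V_j differs between genes only through the weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["LMMFit", "fit_weighted_lmm"]

_LOG_THETA_BOUNDS = (-10.0, 8.0)
_SIGMA2_FLOOR = 1e-12
_PINV_RCOND = 1e-10


@dataclass
class LMMFit:
    """A fitted mixed model (ML) for one gene set."""

    beta: np.ndarray               # fixed effects, length p
    theta: np.ndarray              # relative random-effect SDs, length q
    sigma2: float                  # residual variance
    random_effects: np.ndarray     # empirical-Bayes means, (J, q)
    log_likelihood: float
    n_params: int                  # rank(X) + q + 1
    fixed_rank: int
    converged: bool
    n_obs: int
    n_groups: int
    fitted: np.ndarray             # (J, n) fitted values incl. random effects
    data_fingerprint: int          # identifies the (Y, X-shape) the fit saw

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def sigma_resid(self) -> float:
        return float(np.sqrt(self.sigma2))


def _profiled_nll(
    log_theta: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    inv_w: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Negative profiled log-likelihood, its gradient, and profiled pieces.

    Returns (nll, grad, beta, sigma2, Vinv_resid, theta2) where Vinv_resid
    is Vtilde_j^{-1} (y_j - X beta) per gene, needed for the EB random
    effects. The gradient w.r.t. log theta_m uses the envelope theorem for
    the profiled beta and sigma^2:

        d nll / d log theta_m
          = theta_m^2 * sum_j [ z_m' V_j^{-1} z_m - (z_m' u_j)^2 / sigma^2 ]

    with u_j = V_j^{-1} r_j.
    """
    J, n = Y.shape
    p = X.shape[1]
    theta2 = np.exp(2.0 * np.clip(log_theta, *_LOG_THETA_BOUNDS))
    ZLZ = (Z * theta2) @ Z.T                       # (n, n), shared
    V = np.broadcast_to(ZLZ, (J, n, n)).copy()
    idx = np.arange(n)
    V[:, idx, idx] += inv_w                        # + W_j^{-1} on the diagonal
    L = np.linalg.cholesky(V)
    logdets = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    # Solve V_j^{-1} [X | y_j | Z] in one batched call.
    rhs = np.concatenate(
        [
            np.broadcast_to(X, (J, n, p)),
            Y[:, :, None],
            np.broadcast_to(Z, (J, n, Z.shape[1])),
        ],
        axis=2,
    )
    sol = np.linalg.solve(V, rhs)
    VinvX = sol[:, :, :p]                          # (J, n, p)
    Vinvy = sol[:, :, p]                           # (J, n)
    VinvZ = sol[:, :, p + 1:]                      # (J, n, q)
    A = np.einsum("np,jnq->pq", X, VinvX)
    b = np.einsum("np,jn->p", X, Vinvy)
    beta = np.linalg.pinv(A, rcond=_PINV_RCOND, hermitian=True) @ b
    resid = Y - X @ beta
    Vinv_resid = Vinvy - VinvX @ beta
    quad = float(np.einsum("jn,jn->", resid, Vinv_resid))
    N = J * n
    sigma2 = max(quad / N, _SIGMA2_FLOOR)
    ll = -0.5 * (logdets.sum() + N * np.log(sigma2) + quad / sigma2
                 + N * np.log(2.0 * np.pi))
    zVz = np.einsum("nq,jnq->q", Z, VinvZ)         # sum_j z_m' V_j^{-1} z_m
    s = Vinv_resid @ Z                             # (J, q): z_m' u_j
    grad = theta2 * (zVz - (s**2).sum(axis=0) / sigma2)
    return -ll, grad, beta, sigma2, Vinv_resid, theta2


def fit_weighted_lmm(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    extra_starts: bool = True,
    max_iter: int = 200,
) -> LMMFit:
    """Fit the blocked mixed model by profiled ML.

    Parameters
    ----------
    Y : (J, n) responses, one row per gene.
    X : (n, p) fixed-effect design shared by all genes.
    Z : (n, q) random-effect design shared by all genes.
    weights : (J, n) positive precision weights, or None for unweighted.
    theta0 : optional warm start for the relative random-effect SDs.
    extra_starts : also try fixed default starts and keep the best optimum
        (disable for speed in warm-started refits such as bootstraps).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    J, n = Y.shape
    if J < 2:
        raise ValueError("mixed model needs >= 2 genes (random effects across genes)")
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("design row count must match the number of samples")
    q = Z.shape[1]
    inv_w = (
        np.ones_like(Y) if weights is None else 1.0 / np.asarray(weights, dtype=float)
    )
    fingerprint = hash((Y.shape, Y.tobytes()[:4096], float(Y.sum())))

    starts: list[np.ndarray] = []
    if theta0 is not None:
        starts.append(np.log(np.clip(np.asarray(theta0, float), 1e-6, None)))
    if theta0 is None or extra_starts:
        starts.append(np.full(q, np.log(0.5)))
        starts.append(np.full(q, np.log(0.05)))

    best = None
    converged = False
    for s in starts:
        res = minimize(
            lambda lt: _profiled_nll(lt, Y, X, Z, inv_w)[:2],
            s,
            jac=True,
            method="L-BFGS-B",
            bounds=[_LOG_THETA_BOUNDS] * q,
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            converged = bool(res.success)
    nll, _, beta, sigma2, Vinv_resid, theta2 = _profiled_nll(best.x, Y, X, Z, inv_w)
    re = (Vinv_resid @ Z) * theta2                # (J, q) EB means
    fitted = (X @ beta)[None, :] + re @ Z.T
    fixed_rank = int(np.linalg.matrix_rank(X))
    return LMMFit(
        beta=beta,
        theta=np.sqrt(theta2),
        sigma2=sigma2,
        random_effects=re,
        log_likelihood=-nll,
        n_params=fixed_rank + q + 1,
        fixed_rank=fixed_rank,
        converged=converged,
        n_obs=J * n,
        n_groups=J,
        fitted=fitted,
        data_fingerprint=fingerprint,
    )
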