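"""Profiled REML for linear mixed models with independent scalar random effects.

Fits y = X beta + sum_k u_k z_k + e where each subject has one
independent random coefficient per component (e.g. a random intercept
and a random slope with zero covariance), u_ik ~ N(0, sigma2 * lam_k)
and e ~ N(0, sigma2).  The residual variance is profiled out and the
restricted likelihood is maximized over the log variance ratios
log(lam_k) with a derivative-free simplex search from several starts,
which is robust at the boundary (lam -> 0) where gradient-based
optimizers of the unprofiled problem report spurious failures.

Groups with equal numbers of observations are processed as one batched
solve, so an objective evaluation is a handful of small stacked
Cholesky factorizations and a fit costs milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_LAM_BOUNDS = (-14.0, 14.0)
#: Variance ratios below this are reported as exactly zero (boundary).
_ZERO_RATIO = 1e-5


@dataclass
class REMLResult:
    """REML estimates for one fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    vcomp: tuple[float, ...]  # variance of each random component
    loglik: float  # restricted log-likelihood (up to an additive constant)
    converged: bool
    n_obs: int
    n_groups: int
    ranef: dict  # group label -> array of BLUPs, one per component


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    z_columns: list[np.ndarray],
    xtol: float = 1e-8,
) -> REMLResult:
    """Fit the mixed model by profiled REML.

    ``z_columns`` holds one design column per independent random
    component (a column of ones for a random intercept, the time values
    for a random slope).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    K = len(z_columns)
    Z = np.column_stack([np.asarray(z, dtype=float) for z in z_columns])
    labels, inverse = np.unique(np.asarray(groups), return_inverse=True)
    blocks = [np.flatnonzero(inverse == i) for i in range(len(labels))]

    # batch groups of equal size for stacked linear algebra
    by_size: dict[int, list[int]] = {}
    for gi, ix in enumerate(blocks):
        by_size.setdefault(len(ix), []).append(gi)
    batches = []
    for size, gis in sorted(by_size.items()):
        idx = np.stack([blocks[gi] for gi in gis])  # (g, size)
        batches.append(
            (gis, y[idx], X[idx], Z[idx])  # (g,s), (g,s,p), (g,s,K)
        )

    eye_cache = {s: np.eye(s) for s in by_size}

    def assemble(lam: np.ndarray, keep_solves: bool = False):
        """Accumulate GLS pieces for V_i = I + Z_i diag(lam) Z_i'."""
        A = np.zeros((p, p))
        b = np.zeros(p)
        c = 0.0
        logdet = 0.0
        solves = [] if keep_solves else None
        for gis, Ys, Xs, Zs in batches:
            s = Ys.shape[1]
            V = eye_cache[s][None] + (Zs * lam) @ Zs.transpose(0, 2, 1)
            L = np.linalg.cholesky(V)  # raises LinAlgError if not PD
            logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
            rhs = np.concatenate([Xs, Ys[:, :, None]], axis=2)
            sol = np.linalg.solve(V, rhs)
            A += np.einsum("gsp,gsq->pq", Xs, sol[:, :, :p])
            b += np.einsum("gsp,gs->p", Xs, sol[:, :, p])
            c += float(np.einsum("gs,gs->", Ys, sol[:, :, p]))
            if keep_solves:
                solves.append(sol)
        return A, b, c, logdet, solves

    def neg2_restricted(theta: np.ndarray) -> float:
        lam = np.exp(np.clip(theta, *_LOG_LAM_BOUNDS))
        try:
            A, b, c, logdet, _ = assemble(lam)
        except np.linalg.LinAlgError:
            return np.inf
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        quad = c - b @ np.linalg.solve(A, b)
        if quad <= 0:
            return np.inf
        return (n - p) * np.log(quad) + logdet + logdetA

    starts = [np.full(K, s) for s in (-6.0, 0.0, 3.0)]
    if K > 1:
        starts += [np.array(s) for s in ([-6.0] * (K - 1) + [0.0], [0.0] + [-6.0] * (K - 1))]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            neg2_restricted,
            x0,
            method="Nelder-Mead",
            options={"xatol": xtol ** 0.5, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)

    theta = np.clip(best.x, *_LOG_LAM_BOUNDS)
    lam = np.exp(theta)
    lam[lam < _ZERO_RATIO] = 0.0
    A, b, c, _, solves = assemble(lam, keep_solves=True)
    beta = np.linalg.solve(A, b)
    quad = c - b @ beta
    sigma2 = float(quad / (n - p))
    cov_beta = sigma2 * np.linalg.inv(A)

    ranef = {}
    for (gis, Ys, Xs, Zs), sol in zip(batches, solves):
        # BLUP: lam_k * z_k' V^-1 (y - X beta); sol solves V x = [X, y]
        resid_solved = sol[:, :, p] - np.einsum("gsp,p->gs", sol[:, :, :p], beta)
        blups = lam * np.einsum("gsk,gs->gk", Zs, resid_solved)
        for gi, u in zip(gis, blups):
            ranef[labels[gi]] = u

    return REMLResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        vcomp=tuple(float(sigma2 * l) for l in lam),
        loglik=-0.5 * float(best.fun),
        converged=converged and np.isfinite(best.fun),
        n_obs=n,
        n_groups=len(labels),
        ranef=ranef,
    )
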