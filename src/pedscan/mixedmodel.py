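"""Maximum-likelihood variance-components fitting on pedigree blocks.

Fits the Gaussian mixed model

    y ~ Normal(X beta,  sum_k theta_k V_k + theta_e I)

where the covariance is block-diagonal over pedigrees and each block's
structuring matrices ``V_k`` are supplied by the caller (2*Phi for the
polygenic component, a marker-specific Pi for a QTL component).  Fixed
effects are profiled out by generalized least squares at every variance
evaluation, so the optimization runs over variances only.  Plain ML (not
REML) is used throughout: LOD scores and likelihood-ratio tests need full
likelihoods.

Blocks of equal size are stacked and solved with batched linear algebra,
which keeps per-marker scans over many small pedigrees fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

_LOG_2PI = float(np.log(2.0 * np.pi))
BOUNDARY_TOL = 1e-7  # variance (on unit-variance scale) treated as at the 0 boundary


class MixedModelError(RuntimeError):
    pass


Block = tuple[np.ndarray, np.ndarray, Sequence[np.ndarray]]
# (y_b, X_b, [V_b1, ..., V_bK]); the residual identity component is implicit.


@dataclass
class VcFitResult:
    """ML solution: variance components (last entry = residual), GLS fixed effects."""

    variances: np.ndarray  # (K + 1,), residual last
    beta: np.ndarray  # (p,)
    loglik: float
    converged: bool
    boundary: np.ndarray  # (K + 1,) bool; True where a variance sits at 0
    n_obs: int

    @property
    def sigma2_e(self) -> float:
        return float(self.variances[-1])


class BlockedDesign:
    """Pre-stacked representation of pedigree blocks grouped by size."""

    def __init__(self, blocks: Sequence[Block]):
        if not blocks:
            raise MixedModelError("no data blocks")
        self.n_vc = len(blocks[0][2])
        self.p = blocks[0][1].shape[1]
        self.n_obs = sum(len(b[0]) for b in blocks)
        groups: dict[int, list[Block]] = {}
        for y, X, Vs in blocks:
            y = np.asarray(y, float)
            X = np.asarray(X, float)
            if len(Vs) != self.n_vc or X.shape != (len(y), self.p):
                raise MixedModelError("inconsistent block shapes")
            groups.setdefault(len(y), []).append((y, X, Vs))
        self.groups = []
        for size, blks in sorted(groups.items()):
            ys = np.stack([b[0] for b in blks])  # (B, n)
            Xs = np.stack([b[1] for b in blks])  # (B, n, p)
            Vs = np.stack(
                [np.stack([np.asarray(v, float) for v in b[2]]) for b in blks],
                axis=1,
            ) if self.n_vc else np.zeros((0, len(blks), size, size))
            # Vs: (K, B, n, n)
            self.groups.append((ys, Xs, Vs, np.eye(size)))

    def structure_is_identity(self, k: int, tol: float = 1e-12) -> bool:
        """True if component k's structuring matrix is I in every block."""
        return all(
            np.abs(Vs[k] - eye).max() <= tol for _, _, Vs, eye in self.groups
        )

    def profiled_negloglik(self, theta: np.ndarray):
        """Negative profiled log-likelihood and the GLS beta at theta."""
        K = self.n_vc
        xtx = np.zeros((self.p, self.p))
        xty = np.zeros(self.p)
        yty = 0.0
        logdet = 0.0
        for ys, Xs, Vs, eye in self.groups:
            sigma = np.tensordot(theta[:K], Vs, axes=1) + theta[K] * eye
            sign, ld = np.linalg.slogdet(sigma)
            if np.any(sign <= 0):
                return np.inf, None
            logdet += ld.sum()
            rhs = np.concatenate([Xs, ys[:, :, None]], axis=2)
            try:
                A = np.linalg.solve(sigma, rhs)  # (B, n, p+1)
            except np.linalg.LinAlgError:
                return np.inf, None
            xtx += np.einsum("bni,bnj->ij", Xs, A[:, :, : self.p])
            xty += np.einsum("bni,bn->i", Xs, A[:, :, self.p])
            yty += float(np.einsum("bn,bn->", ys, A[:, :, self.p]))
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            return np.inf, None
        quad = yty - xty @ beta
        nll = 0.5 * (self.n_obs * _LOG_2PI + logdet + quad)
        return nll, beta


def fit_ml(
    blocks: Sequence[Block],
    start: np.ndarray | None = None,
    n_restarts: int = 3,
    drop_identity_components: bool = True,
    seed: int = 0,
) -> VcFitResult:
    """Maximize the profiled ML over non-negative variance components.

    ``start`` optionally warm-starts the variances (residual last, original
    scale).  Structure components whose matrix is the identity in every
    block are unidentifiable against the residual and are pinned to 0 when
    ``drop_identity_components`` is set.
    """
    design = BlockedDesign(blocks)
    K = design.n_vc
    y_all = np.concatenate([b[0] for b in blocks])
    scale = float(np.std(y_all))
    if scale <= 0:
        scale = 1.0
    sdesign = BlockedDesign([(y / scale, X, Vs) for y, X, Vs in blocks])

    pinned = np.zeros(K, dtype=bool)
    if drop_identity_components:
        for k in range(K):
            if sdesign.structure_is_identity(k):
                pinned[k] = True
    free = np.flatnonzero(~pinned)

    def obj(free_theta: np.ndarray) -> float:
        theta = np.zeros(K + 1)
        theta[free] = free_theta[:-1]
        theta[K] = free_theta[-1]
        nll, _ = sdesign.profiled_negloglik(theta)
        return nll

    nf = len(free)
    bounds = [(0.0, 10.0)] * nf + [(1e-8, 10.0)]
    starts = []
    if start is not None:
        s = np.asarray(start, float) / scale ** 2
        starts.append(np.append(np.maximum(s[free], 0.0), max(s[-1], 1e-6)))
    even = np.full(nf + 1, 1.0 / (nf + 1))
    starts.append(even)
    rng = np.random.default_rng(seed)
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.clip(even * rng.uniform(0.2, 2.0, nf + 1), 1e-6, 5.0))

    best = None
    for x0 in starts:
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
    if best is None:
        raise MixedModelError("variance-components optimization failed on all starts")

    theta_s = np.zeros(K + 1)
    theta_s[free] = best.x[:-1]
    theta_s[K] = best.x[-1]
    nll, beta_s = sdesign.profiled_negloglik(theta_s)
    if beta_s is None:
        raise MixedModelError("likelihood degenerate at optimum")
    boundary = np.append(theta_s[:K] <= BOUNDARY_TOL, theta_s[K] <= 2e-8)
    variances = theta_s * scale ** 2
    loglik = -(nll + design.n_obs * np.log(scale))
    return VcFitResult(
        variances=variances,
        beta=beta_s * scale,
        loglik=float(loglik),
        converged=bool(best.success),
        boundary=boundary,
        n_obs=design.n_obs,
    )


def loglik_at(
    blocks: Sequence[Block], variances: np.ndarray, beta: np.ndarray
) -> float:
    """Exact log-likelihood at given parameters (no optimization)."""
    total = 0.0
    K = len(variances) - 1
    for y, X, Vs in blocks:
        n = len(y)
        sigma = variances[K] * np.eye(n)
        for k in range(K):
            sigma = sigma + variances[k] * np.asarray(Vs[k], float)
        r = np.asarray(y, float) - np.asarray(X, float) @ beta
        sign, ld = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        total += -0.5 * (n * _LOG_2PI + ld + r @ np.linalg.solve(sigma, r))
    return float(total)
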