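"""Restricted-maximum-likelihood machinery for single-random-effect models.

Model: y = X b + g + e with g ~ N(0, sigma_u2 * K) and e ~ N(0, sigma_e2 * I).
The REML criterion is profiled down to a one-dimensional search over the
variance ratio delta = sigma_e2 / sigma_u2 on the eigenbasis of S K S
(S the projection removing fixed effects), the classic spectral trick that
makes each evaluation O(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

DELTA_MIN = 1e-6
DELTA_MAX = 1e8


@dataclass
class RemlResult:
    sigma_u2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_u2
    loglik: float
    eigenvalues: np.ndarray  # of K (full), for downstream GLS transforms
    eigenvectors: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0


def reml_fit(y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None) -> RemlResult:
    """REML estimates of (sigma_u2, sigma_e2) for one genomic random effect.

    ``X`` defaults to an intercept. Raises on a K that is materially non-PSD.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    K = np.asarray(K, float)
    if K.shape != (n, n):
        raise ValueError(f"K shape {K.shape} incompatible with n={n}")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, float))
    p = X.shape[1]

    dK = np.linalg.eigvalsh(K)
    if dK.min() < -1e-6 * max(1.0, dK.max()):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {dK.min():.3g})")

    # eigenbasis of S K S restricted to the (n - p)-dim residual space
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    lam_all, U_all = np.linalg.eigh(S @ K @ S)
    idx = np.argsort(lam_all)[::-1][: n - p]
    lam = np.clip(lam_all[idx], 0.0, None)
    eta = U_all[:, idx].T @ y
    eta2 = eta**2
    q = n - p

    def neg_restricted_ll(log_delta: float) -> float:
        d = 10.0**log_delta
        denom = lam + d
        r = float((eta2 / denom).sum())
        return -0.5 * (
            q * math.log(q / (2 * math.pi)) - q - q * math.log(r)
            - float(np.log(denom).sum())
        )

    grid = np.linspace(math.log10(DELTA_MIN), math.log10(DELTA_MAX), 101)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        best_log = grid[i]
    else:
        res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
        best_log = float(res.x)
    delta = 10.0**best_log
    r = float((eta2 / (lam + delta)).sum())
    sigma_u2 = r / q
    sigma_e2 = delta * sigma_u2

    d_full, U_full = np.linalg.eigh(K)
    return RemlResult(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        delta=delta,
        loglik=-neg_restricted_ll(best_log),
        eigenvalues=np.clip(d_full, 0.0, None),
        eigenvectors=U_full,
    )
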