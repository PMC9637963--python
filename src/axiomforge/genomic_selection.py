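"""Genomic selection: rrBLUP with cross-validated predictive ability, plus a
minimal 1D-CNN regressor.

rrBLUP fits y = mu + Z u + e with i.i.d. normal marker effects
u ~ N(0, I sigma_u2). The variance ratio lambda = sigma_e2 / sigma_u2 is
estimated by REML through the equivalent kinship-form mixed model on the
eigenbasis of Z Z', and the marker effects follow from the ridge identity
u = Z'(Z Z' + lambda I)^(-1) (y - mu). Predictive ability is the Pearson
correlation between observed phenotypes and cross-validated GEBVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._cnn import CNNRegressor, CNNSpec  # re-exported
from ._reml import reml_fit

__all__ = [
    "RRBLUP", "RRBLUPResults", "CVScheme", "CVResult",
    "fit_rrblup", "predict_gebv", "cross_validate",
    "CNNSpec", "CNNRegressor", "fit_cnn",
]


def _prepare_markers(Z) -> tuple[np.ndarray, list | None]:
    """Impute missing to marker means; accept {-1,0,1} or {0,1,2} coding."""
    ids = list(Z.columns) if isinstance(Z, pd.DataFrame) else None
    Z = np.array(Z, float)
    col_mean = np.nanmean(Z, axis=0)
    nan = np.isnan(Z)
    if nan.any():
        Z[nan] = np.take(col_mean, np.where(nan)[1])
    return Z, ids


@dataclass
class RRBLUPResults:
    """Fitted rrBLUP model: overall mean, marker effects and variance ratio."""

    mu: float
    u: np.ndarray
    lam: float  # sigma_e2 / sigma_u2
    sigma_u2: float
    sigma_e2: float
    marker_ids: list | None = None
    _col_means: np.ndarray | None = field(default=None, repr=False)

    def predict(self, Z_new) -> np.ndarray:
        """GEBVs mu + Z_new u for aligned marker columns."""
        ids = list(Z_new.columns) if isinstance(Z_new, pd.DataFrame) else None
        if self.marker_ids is not None and ids is not None:
            missing = [m for m in self.marker_ids if m not in set(ids)]
            if missing:
                raise ValueError(
                    f"{len(missing)} fitted markers absent from new data, "
                    f"e.g. {missing[:5]}"
                )
            Z_new = Z_new[self.marker_ids]
        Z, _ = _prepare_markers(Z_new)
        if Z.shape[1] != self.u.size:
            raise ValueError(
                f"marker mismatch: fit has {self.u.size}, input {Z.shape[1]}"
            )
        return self.mu + (Z - self._col_means) @ self.u

    def summary(self) -> str:
        tot = self.sigma_u2 + self.sigma_e2
        lines = [
            "rrBLUP fit",
            "=" * 30,
            f"markers: {self.u.size}",
            f"mu: {self.mu:.4f}",
            f"lambda (sigma_e2/sigma_u2): {self.lam:.4g}",
            f"sigma_u2: {self.sigma_u2:.4g}    sigma_e2: {self.sigma_e2:.4g}",
            f"genomic variance fraction: {self.sigma_u2 / tot if tot else 0:.3f}",
        ]
        return "\n".join(lines)


class RRBLUP:
    """Ridge-regression BLUP model over a marker matrix.

    Parameters
    ----------
    y : (n,) phenotype vector.
    Z : (n, m) marker matrix coded {-1, 0, 1} or {0, 1, 2}; missing values
        are imputed to the marker mean. Columns are centred internally
        (which leaves the effects u unchanged and folds coding offsets into
        the intercept).
    """

    def __init__(self, y, Z):
        self.y = np.asarray(y, float).ravel()
        self.Z, self.marker_ids = _prepare_markers(Z)
        if self.Z.shape[0] != self.y.size:
            raise ValueError("y and Z have different sample counts")

    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, geno: pd.DataFrame,
                       trait: str) -> "RRBLUP":
        pheno = pheno.set_index("sample_id") if "sample_id" in pheno else pheno
        common = pheno.index.intersection(geno.index)
        return cls(pheno.loc[common, trait].to_numpy(), geno.loc[common])

    def fit(self, lam: float | None = None) -> RRBLUPResults:
        """Estimate lambda by REML unless a fixed value is supplied."""
        y, Z = self.y, self.Z
        n = y.size
        col_means = Z.mean(axis=0)
        Zc = Z - col_means
        if np.ptp(y) == 0.0:
            warnings.warn("zero-variance phenotype: marker effects set to 0")
            return RRBLUPResults(float(y[0]), np.zeros(Z.shape[1]), np.inf,
                                 0.0, 0.0, self.marker_ids, col_means)
        K = Zc @ Zc.T
        if lam is None:
            if n < 10:
                raise ValueError("need at least 10 samples for REML")
            r = reml_fit(y, K, np.ones((n, 1)))
            lam, sigma_u2, sigma_e2 = r.delta, r.sigma_u2, r.sigma_e2
        else:
            sigma_u2 = sigma_e2 = float("nan")
        H = K + lam * np.eye(n)
        Hinv_y = np.linalg.solve(H, y)
        Hinv_1 = np.linalg.solve(H, np.ones(n))
        mu = float(np.ones(n) @ Hinv_y / (np.ones(n) @ Hinv_1))
        u = Zc.T @ np.linalg.solve(H, y - mu)
        return RRBLUPResults(mu, u, float(lam), sigma_u2, sigma_e2,
                             self.marker_ids, col_means)


def fit_rrblup(y, Z, lam: float | None = None) -> RRBLUPResults:
    """Functional wrapper around :class:`RRBLUP`."""
    return RRBLUP(y, Z).fit(lam=lam)


def predict_gebv(fit: RRBLUPResults, Z_new) -> np.ndarray:
    return fit.predict(Z_new)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVScheme:
    """k-fold cross-validation scheme with seeded replication.

    The default is fourfold (75% training per split); ``fivefold_80_20``
    gives the 80/20 variant. Each replicate re-randomizes fold membership;
    every sample is predicted exactly once per replicate.
    """

    k: int = 4
    replications: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need k >= 2 folds")

    @property
    def train_fraction(self) -> float:
        return 1.0 - 1.0 / self.k

    @classmethod
    def fivefold_80_20(cls, replications: int = 50, seed: int = 0) -> "CVScheme":
        return cls(k=5, replications=replications, seed=seed)


@dataclass
class CVResult:
    """Per-replicate predictive abilities r and their mean/sd."""

    r: np.ndarray
    scheme: CVScheme
    model: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.r))

    @property
    def sd(self) -> float:
        return float(np.std(self.r, ddof=1)) if self.r.size > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.model} {self.scheme.k}-fold CV, "
            f"{self.scheme.replications} replicates: "
            f"r = {self.mean:.3f} +/- {self.sd:.3f}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot(self.r, tick_labels=[self.model])
        ax.set_ylabel("predictive ability r")
        return ax


def cross_validate(
    y,
    Z,
    scheme: CVScheme = CVScheme(),
    model: str = "rrblup",
    lam: float | None = None,
    cnn_spec: CNNSpec | None = None,
) -> CVResult:
    """Cross-validated predictive ability r = cor(observed, predicted GEBV).

    Per replicate, samples are partitioned into k seeded folds; each fold is
    predicted from a model trained on the rest, and r is the Pearson
    correlation over all held-out predictions. Reproducible from
    ``scheme.seed``.
    """
    y = np.asarray(y, float).ravel()
    Zmat, ids = _prepare_markers(Z)
    n = y.size
    if n // scheme.k < 3:
        raise ValueError(f"folds of <3 samples with n={n}, k={scheme.k}")
    rs = np.empty(scheme.replications)
    for rep in range(scheme.replications):
        rng = np.random.default_rng(scheme.seed + rep)
        perm = rng.permutation(n)
        folds = np.array_split(perm, scheme.k)
        pred = np.empty(n)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            if model == "rrblup":
                fit = RRBLUP(y[train_idx], Zmat[train_idx]).fit(lam=lam)
                pred[test_idx] = fit.predict(Zmat[test_idx])
            elif model == "cnn":
                reg = CNNRegressor(cnn_spec, seed=int(rng.integers(2**31)))
                reg.fit(Zmat[train_idx], y[train_idx])
                pred[test_idx] = reg.predict(Zmat[test_idx])
            else:
                raise ValueError(f"unknown model {model!r}")
        rs[rep] = stats.pearsonr(y, pred)[0]
    return CVResult(rs, scheme, model)


def fit_cnn(
    y, Z, spec: CNNSpec | None = None, seed: int = 0
) -> CNNRegressor:
    """Train the 1D-CNN regressor on a full cohort (validation split drawn
    internally for early stopping)."""
    Zmat, _ = _prepare_markers(Z)
    return CNNRegressor(spec, seed=seed).fit(Zmat, np.asarray(y, float).ravel())
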