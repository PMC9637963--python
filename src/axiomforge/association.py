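"""Kinship construction and mixed-linear-model GWAS.

The scan follows the EMMAX/P3D recipe: variance components are estimated
once under the null model y = mu + g + e, g ~ N(0, sigma_u2 K), and each
marker is then tested by generalized least squares under the fitted
covariance V = sigma_u2 K + sigma_e2 I, which the spectral decomposition of
K turns into ordinary least squares on rotated data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import RemlResult, reml_fit

DEFAULT_THRESHOLD = 3.16e-7  # genome-wide significance (-log10 p = 6.5)


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix among samples (symmetric PSD)."""

    values: np.ndarray
    method: str = "vanraden"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _impute_mean(G: np.ndarray) -> np.ndarray:
    G = np.array(G, float)
    col_mean = np.nanmean(G, axis=0)
    nan = np.isnan(G)
    if nan.any():
        G[nan] = np.take(col_mean, np.where(nan)[1])
    return G


def compute_kinship(genotypes: np.ndarray, method: str = "vanraden") -> KinshipMatrix:
    """Genomic relationship matrix from 0/1/2-coded genotypes (NaN = missing).

    ``vanraden``: K = W W' / (2 sum_j p_j (1 - p_j)) with W the matrix of
    dosages centred by twice the allele frequency — the standard
    variance-covariance estimator for a polygenic random effect.
    ``ibs``: mean allele-sharing proportion, offered as an alternative.
    Missing dosages are imputed to the marker mean. A panel with only
    monomorphic markers is an error (zero denominator).
    """
    G = _impute_mean(np.asarray(genotypes, float))
    p = G.mean(axis=0) / 2.0
    if method == "vanraden":
        denom = 2.0 * float(np.sum(p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("all markers monomorphic: kinship denominator is zero")
        W = G - 2.0 * p
        K = (W @ W.T) / denom
    elif method == "ibs":
        n, m = G.shape
        K = np.empty((n, n))
        for i in range(n):
            K[i] = 1.0 - np.mean(np.abs(G - G[i]), axis=1) / 2.0
        K = (K + K.T) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return KinshipMatrix(K, method)


@dataclass
class MixedModelFit:
    """Null-model variance components and the kinship eigendecomposition."""

    sigma_u2: float
    sigma_e2: float
    loglik: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n: int

    @property
    def heritability(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0

    @classmethod
    def _from_reml(cls, r: RemlResult, n: int) -> "MixedModelFit":
        return cls(r.sigma_u2, r.sigma_e2, r.loglik, r.eigenvalues,
                   r.eigenvectors, n)


def fit_null_mlm(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
) -> MixedModelFit:
    """REML fit of the no-marker mixed model y = X b + g + e.

    X is an intercept plus any supplied covariate columns. The search is a
    one-dimensional optimization over sigma_e2/sigma_u2 on the eigenbasis of
    the kinship matrix, so the fit is deterministic for fixed inputs.
    """
    y = np.asarray(y, float).ravel()
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    X = np.ones((y.size, 1))
    if covariates is not None:
        X = np.column_stack([X, np.atleast_2d(covariates)])
    return MixedModelFit._from_reml(reml_fit(y, Kv, X), y.size)


def _transform(fit: MixedModelFit, *arrays):
    """Rotate/whiten arrays by V^(-1/2) using the kinship eigenbasis."""
    w = 1.0 / np.sqrt(fit.sigma_u2 * fit.eigenvalues + fit.sigma_e2)
    U = fit.eigenvectors
    out = []
    for a in arrays:
        a = np.asarray(a, float)
        if a.ndim == 1:
            out.append(w * (U.T @ a))
        else:
            out.append(w[:, None] * (U.T @ a))
    return out


def test_marker(
    y: np.ndarray,
    x_marker: np.ndarray,
    null_fit: MixedModelFit,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """GLS effect, standard error and Wald p-value for one marker (P3D).

    Monomorphic or intercept-collinear markers return (0, nan, 1) with a
    warning in the collinear case.
    """
    eff, se, p = _scan_matrix(
        y, np.asarray(x_marker, float).reshape(-1, 1), null_fit, covariates
    )
    return float(eff[0]), float(se[0]), float(p[0])


def _scan_matrix(y, G, fit: MixedModelFit, covariates=None):
    n = fit.n
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.atleast_2d(covariates)])
    ys, Xs, Gs = _transform(fit, y, X, G)
    # Frisch-Waugh: residualize y and every marker on the rotated covariates
    Q, _ = np.linalg.qr(Xs)
    yr = ys - Q @ (Q.T @ ys)
    Gr = Gs - Q @ (Q.T @ Gs)
    xtx = np.einsum("ij,ij->j", Gr, Gr)
    xty = Gr.T @ yr
    dof = n - X.shape[1] - 1
    ok = xtx > 1e-12 * max(1.0, float(np.max(xtx, initial=0.0)))
    effect = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.nan)
    pval = np.ones(G.shape[1])
    if (~ok).any():
        n_bad = int((~ok).sum())
        warnings.warn(
            f"{n_bad} marker(s) monomorphic or collinear with covariates; p set to 1"
        )
    effect[ok] = xty[ok] / xtx[ok]
    rss = float(yr @ yr)
    rss_j = np.maximum(rss - effect[ok] ** 2 * xtx[ok], 0.0)
    s2 = rss_j / dof
    se[ok] = np.sqrt(s2 / xtx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(t), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return effect, se, pval


@dataclass
class AssociationResult:
    """Per-marker GWAS results table with significance flags."""

    table: pd.DataFrame
    null_fit: MixedModelFit
    threshold: float = DEFAULT_THRESHOLD

    def summary(self) -> str:
        nf = self.null_fit
        hits = self.table["significant"].sum()
        top = self.table.nsmallest(min(5, len(self.table)), "p")
        lines = [
            "Mixed linear model GWAS (P3D/EMMAX)",
            "=" * 42,
            f"samples: {nf.n}    markers: {len(self.table)}",
            f"sigma_u2: {nf.sigma_u2:.4g}    sigma_e2: {nf.sigma_e2:.4g}",
            f"pseudo-heritability: {nf.heritability:.3f}",
            f"threshold: p < {self.threshold:.3g}"
            f" (-log10 p > {-math.log10(self.threshold):.2f})",
            f"significant markers: {int(hits)}",
            "",
            "top markers:",
            top[["marker_id", "chrom", "pos", "effect", "se", "p"]].to_string(
                index=False
            ),
        ]
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Manhattan plot of -log10 p by genome position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for i, (chrom, sub) in enumerate(self.table.groupby("chrom", sort=True)):
            ax.scatter(sub["pos"] + offset, sub["neglog10p"], s=6,
                       color=f"C{i % 2}", label=None)
            offset += sub["pos"].max() + 1
        ax.axhline(-math.log10(self.threshold), ls="--", color="red", lw=1)
        ax.set_xlabel("genome position")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax


def gwas_scan(
    y: np.ndarray,
    genotypes: np.ndarray,
    K: KinshipMatrix | np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    marker_info: pd.DataFrame | None = None,
    covariates: np.ndarray | None = None,
    null_fit: MixedModelFit | None = None,
) -> AssociationResult:
    """Mixed-model association scan over all markers.

    ``genotypes`` is (n_samples, n_markers) 0/1/2 dosage (NaN imputed to the
    marker mean); K defaults to the VanRaden kinship of the scanned markers.
    ``marker_info`` may carry marker_id/chrom/pos columns for the output.
    """
    G = _impute_mean(np.asarray(genotypes, float))
    if K is None:
        K = compute_kinship(G)
    if null_fit is None:
        null_fit = fit_null_mlm(y, K, covariates)
    effect, se, p = _scan_matrix(y, G, null_fit, covariates)
    m = G.shape[1]
    if marker_info is None:
        marker_info = pd.DataFrame(
            {"marker_id": [f"M{j}" for j in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1)}
        )
    table = marker_info.reset_index(drop=True).copy()
    table["effect"] = effect
    table["se"] = se
    table["p"] = p
    table["neglog10p"] = -np.log10(p)
    table["significant"] = p < threshold
    return AssociationResult(table, null_fit, threshold)


class MixedModelGWAS:
    """Model object for kinship-based mixed-linear-model GWAS.

    Parameters
    ----------
    y : (n,) phenotype.
    genotypes : (n, m) dosage matrix coded 0/1/2 (NaN missing).
    kinship : optional precomputed :class:`KinshipMatrix`; defaults to the
        VanRaden matrix of ``genotypes``.
    covariates : optional fixed-effect columns (no intercept).
    marker_info : optional DataFrame with marker_id/chrom/pos.

    ``fit()`` estimates the null variance components by REML and runs the
    P3D scan, returning an :class:`AssociationResult`.
    """

    def __init__(self, y, genotypes, kinship=None, covariates=None,
                 marker_info=None):
        self.y = np.asarray(y, float).ravel()
        self.genotypes = np.asarray(genotypes, float)
        if self.genotypes.shape[0] != self.y.size:
            raise ValueError("y and genotypes have different sample counts")
        self.kinship = kinship
        self.covariates = covariates
        self.marker_info = marker_info

    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, geno: pd.DataFrame,
                       trait: str, **kw) -> "MixedModelGWAS":
        """Align a phenotype table (sample_id, trait...) with a genotype table
        (samples in rows, markers in columns)."""
        pheno = pheno.set_index("sample_id") if "sample_id" in pheno else pheno
        common = pheno.index.intersection(geno.index)
        if len(common) == 0:
            raise ValueError("no shared samples between phenotype and genotypes")
        info = pd.DataFrame({"marker_id": geno.columns, "chrom": "1",
                             "pos": np.arange(1, geno.shape[1] + 1)})
        return cls(pheno.loc[common, trait].to_numpy(),
                   geno.loc[common].to_numpy(), marker_info=info, **kw)

    def fit_null(self) -> MixedModelFit:
        G = _impute_mean(self.genotypes)
        if self.kinship is None:
            self.kinship = compute_kinship(G)
        return fit_null_mlm(self.y, self.kinship, self.covariates)

    def fit(self, threshold: float = DEFAULT_THRESHOLD) -> AssociationResult:
        return gwas_scan(
            self.y, self.genotypes, self.kinship, threshold,
            self.marker_info, self.covariates,
        )
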