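"""Post-genotyping QC: intensity transform, cluster fitting, SNP metrics,
six-category classification and conversion summaries.

The signal space is Axiom-like: per sample and marker, ``contrast`` is the
log2 ratio of the two allele channels and ``size`` their mean log2 intensity.
Homozygotes sit at positive (AA) and negative (BB) contrast, heterozygotes
near zero. Marker quality is judged by call rate (CR), Fisher's linear
discriminant (FLD), heterozygous strength offset (HetSO), homozygote ratio
offset (HomRO) and an off-target-variant (OTV) heuristic, and each marker is
assigned exactly one of six categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AA, AB, BB, MISSING

GENOTYPES = (AA, AB, BB)

CAT_POLY = "PolyHighResolution"
CAT_MONO = "MonoHighResolution"
CAT_NO_MINOR_HOM = "NoMinorHom"
CAT_OTV = "OTV"
CAT_CRBT = "CallRateBelowThreshold"
CAT_OTHER = "Other"
CATEGORIES = (CAT_POLY, CAT_MONO, CAT_NO_MINOR_HOM, CAT_OTV, CAT_CRBT, CAT_OTHER)

DEFAULT_CONVERTED = frozenset({CAT_POLY, CAT_NO_MINOR_HOM, CAT_MONO})


@dataclass(frozen=True)
class QCThresholds:
    """Marker QC cut-offs: CR >= 97%, FLD >= 3.6, HetSO >= -0.1, HomRO >= 0.3."""

    call_rate: float = 97.0
    fld: float = 3.6
    hetso: float = -0.1
    homro: float = 0.3


@dataclass(frozen=True)
class SampleQC:
    """Per-sample QC: pass iff DQC >= 0.83 and call rate >= 0.97.

    DQC is the platform's dish quality metric, consumed as a given number.
    """

    sample_id: str
    dqc: float
    call_rate: float

    @property
    def passed(self) -> bool:
        return self.dqc >= 0.83 and self.call_rate >= 0.97


def transform_intensities(channel_a, channel_b) -> tuple[np.ndarray, np.ndarray]:
    """(contrast, size) = (log2(a/b), (log2 a + log2 b)/2). Channels must be > 0."""
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be strictly positive")
    la, lb = np.log2(a), np.log2(b)
    return la - lb, (la + lb) / 2.0


@dataclass
class ClusterStats:
    n: int
    mean_contrast: float
    sd_contrast: float
    mean_size: float
    sd_size: float


@dataclass
class ClusterFit:
    """Per-genotype summary of the (contrast, size) cloud."""

    clusters: dict = field(default_factory=dict)  # genotype -> ClusterStats

    def present(self, g: str) -> bool:
        return g in self.clusters

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def __getitem__(self, g: str) -> ClusterStats:
        return self.clusters[g]


def fit_clusters(contrast, size, calls) -> ClusterFit:
    """Sample mean/sd (ddof=1; sd 0 for singleton clusters) per called genotype."""
    contrast = np.asarray(contrast, float)
    size = np.asarray(size, float)
    calls = np.asarray(calls, dtype=object)
    fit = ClusterFit()
    for g in GENOTYPES:
        mask = calls == g
        n = int(mask.sum())
        if n == 0:
            continue
        c, s = contrast[mask], size[mask]
        fit.clusters[g] = ClusterStats(
            n=n,
            mean_contrast=float(c.mean()),
            sd_contrast=float(c.std(ddof=1)) if n > 1 else 0.0,
            mean_size=float(s.mean()),
            sd_size=float(s.std(ddof=1)) if n > 1 else 0.0,
        )
    return fit


# ---------------------------------------------------------------------------
# genotype calling (stands in for the platform's proprietary caller)
# ---------------------------------------------------------------------------


def call_genotypes(
    contrast,
    confidence_threshold: float = 0.95,
    label_deadzone: float = 0.2,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-mixture genotype calls in contrast space.

    Fits 1-3 component mixtures, picks the component count by BIC, assigns
    each point to its maximum-posterior component, and blanks calls whose
    posterior falls below ``confidence_threshold``. Components are labelled
    AA / AB / BB by their contrast mean: above ``label_deadzone`` -> AA,
    below its negative -> BB, else AB (falling back to rank order if two
    components collide on a label). Returns (calls, confidence).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(contrast, float).reshape(-1, 1)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0.0:
        calls = np.array([_label_by_mean(float(x[0, 0]), label_deadzone)] * n, dtype=object)
        return calls, np.ones(n)

    best, best_bic = None, np.inf
    for k in range(1, min(3, n) + 1):
        gm = GaussianMixture(
            n_components=k, n_init=3, random_state=random_state, reg_covar=1e-6
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    means = best.means_.ravel()
    order = np.argsort(-means)  # descending contrast: AA side first
    labels = [_label_by_mean(means[i], label_deadzone) for i in order]
    if len(set(labels)) < len(labels):  # collision -> rank-order fallback
        labels = list(GENOTYPES[: len(order)]) if len(order) < 3 else list(GENOTYPES)
    comp_label = {}
    for rank, i in enumerate(order):
        comp_label[i] = labels[rank]
    post = best.predict_proba(x)
    assign = post.argmax(axis=1)
    conf = post[np.arange(n), assign]
    calls = np.array([comp_label[i] for i in assign], dtype=object)
    calls[conf < confidence_threshold] = MISSING
    return calls, conf


def _label_by_mean(mean: float, deadzone: float) -> str:
    if mean > deadzone:
        return AA
    if mean < -deadzone:
        return BB
    return AB


# ---------------------------------------------------------------------------
# marker metrics
# ---------------------------------------------------------------------------


def compute_fld(fit: ClusterFit) -> float:
    """Separation of the het cluster from the nearest hom cluster.

    ``min over present hom clusters of |mean_contrast(hom) - mean_contrast(AB)|
    / pooled_sd`` with pooled_sd the sqrt of the n-weighted mean of all
    present clusters' contrast variances. NaN when AB or both homs are
    absent; +inf when the pooled sd is exactly zero.
    """
    if not fit.present(AB):
        return math.nan
    homs = [g for g in (AA, BB) if fit.present(g)]
    if not homs:
        return math.nan
    stats = list(fit.clusters.values())
    w = np.array([s.n for s in stats], float)
    v = np.array([s.sd_contrast**2 for s in stats])
    pooled = math.sqrt(float((w * v).sum() / w.sum()))
    gap = min(abs(fit[g].mean_contrast - fit[AB].mean_contrast) for g in homs)
    if pooled == 0.0:
        return math.inf
    return gap / pooled


def compute_hetso(fit: ClusterFit) -> float:
    """Vertical offset of the het centre from the hom-hom chord in (contrast, size).

    Undefined (NaN) unless all three clusters are present or the two hom
    contrasts coincide. Negative values mean the het cluster sits below the
    chord (weak heterozygote signal).
    """
    if not all(fit.present(g) for g in GENOTYPES):
        return math.nan
    aa, ab, bb = fit[AA], fit[AB], fit[BB]
    dx = bb.mean_contrast - aa.mean_contrast
    if dx == 0.0:
        return math.nan
    chord = aa.mean_size + (ab.mean_contrast - aa.mean_contrast) * (
        bb.mean_size - aa.mean_size
    ) / dx
    return ab.mean_size - chord


def compute_homro(fit: ClusterFit) -> float:
    """Signed contrast distance from zero of the hom cluster nearest zero.

    With AA expected at positive contrast and BB at negative: both homs
    present -> ``min(contrast(AA), -contrast(BB))``; one hom -> its signed
    distance on the expected side. Negative values flag a hom cluster on the
    wrong side of zero. NaN when no hom cluster exists.
    """
    has_aa, has_bb = fit.present(AA), fit.present(BB)
    if has_aa and has_bb:
        return min(fit[AA].mean_contrast, -fit[BB].mean_contrast)
    if has_aa:
        return fit[AA].mean_contrast
    if has_bb:
        return -fit[BB].mean_contrast
    return math.nan


def detect_otv(
    fit: ClusterFit,
    contrast,
    size,
    calls,
    min_fraction: float = 0.05,
    size_drop: float = 0.3,
) -> bool:
    """Heuristic off-target-variant flag.

    True iff at least ``min_fraction`` of all samples form a sub-cluster
    within the heterozygote contrast band at a size at least ``size_drop``
    below the expected het size — the signature of an extra low-intensity
    cluster caused by an unassayed interfering variant. The expected het
    size is the AB cluster's mean size when present, or the hom–hom chord
    evaluated at the band centre when both hom clusters exist — whichever
    is larger, so that an AB cluster dragged down by the contamination
    itself cannot mask the sub-cluster. False when neither reference is
    computable.
    """
    contrast = np.asarray(contrast, float)
    size = np.asarray(size, float)
    refs = []
    if fit.present(AB):
        band_centre = fit[AB].mean_contrast
        band_half = max(3.0 * fit[AB].sd_contrast, 0.3)
        refs.append(fit[AB].mean_size)
    elif fit.present(AA) and fit.present(BB):
        band_centre = 0.5 * (fit[AA].mean_contrast + fit[BB].mean_contrast)
        band_half = 0.3
    else:
        return False
    if fit.present(AA) and fit.present(BB):
        aa, bb = fit[AA], fit[BB]
        dx = bb.mean_contrast - aa.mean_contrast
        if dx != 0.0:
            refs.append(
                aa.mean_size
                + (band_centre - aa.mean_contrast)
                * (bb.mean_size - aa.mean_size) / dx
            )
    ref = max(refs)
    in_band = np.abs(contrast - band_centre) <= band_half
    low = size <= ref - size_drop
    return float(np.mean(in_band & low)) >= min_fraction


@dataclass
class SNPQCMetrics:
    """Per-marker QC metrics; ``category`` is set only by :func:`classify_snp`."""

    marker_id: str = ""
    call_rate: float = math.nan  # percent, [0, 100]
    fld: float = math.nan
    hetso: float = math.nan
    homro: float = math.nan
    n_clusters: int = 0
    n_minor_allele_samples: int = 0
    n_minor_hom: int = 0
    otv_flag: bool = False
    category: str | None = None


def compute_snp_metrics(
    contrast,
    size,
    calls,
    marker_id: str = "",
    otv_kwargs: Mapping | None = None,
) -> SNPQCMetrics:
    """Assemble all marker QC metrics from intensities and calls."""
    calls = np.asarray(calls, dtype=object)
    n = len(calls)
    n_called = int(np.sum(calls != MISSING))
    fit = fit_clusters(contrast, size, calls)
    counts = {g: int(np.sum(calls == g)) for g in GENOTYPES}
    n_a = 2 * counts[AA] + counts[AB]
    n_b = 2 * counts[BB] + counts[AB]
    if n_a <= n_b:
        minor_hom, minor_carriers = counts[AA], counts[AA] + counts[AB]
    else:
        minor_hom, minor_carriers = counts[BB], counts[BB] + counts[AB]
    if n_a == n_b == 0:
        minor_hom = minor_carriers = 0
    return SNPQCMetrics(
        marker_id=marker_id,
        call_rate=100.0 * n_called / n if n else math.nan,
        fld=compute_fld(fit),
        hetso=compute_hetso(fit),
        homro=compute_homro(fit),
        n_clusters=fit.n_clusters,
        n_minor_allele_samples=minor_carriers,
        n_minor_hom=minor_hom,
        otv_flag=detect_otv(fit, contrast, size, calls, **(otv_kwargs or {})),
    )


def classify_snp(
    metrics: SNPQCMetrics, thresholds: QCThresholds = QCThresholds()
) -> str:
    """Assign exactly one of the six marker categories.

    Decision order: (1) call rate below threshold -> CallRateBelowThreshold;
    (2) any *defined* resolution metric (FLD / HetSO / HomRO) below its
    threshold -> Other; (3) OTV flag -> OTV; (4) a single genotype cluster ->
    MonoHighResolution; (5) no minor homozygote -> NoMinorHom; (6) at least
    two minor-allele samples -> PolyHighResolution; otherwise Other.
    Undefined (NaN) metrics — e.g. FLD for a marker with no het cluster —
    do not fail step (2).
    """
    if metrics.call_rate < thresholds.call_rate:
        cat = CAT_CRBT
    elif (
        (not math.isnan(metrics.fld) and metrics.fld < thresholds.fld)
        or (not math.isnan(metrics.hetso) and metrics.hetso < thresholds.hetso)
        or (not math.isnan(metrics.homro) and metrics.homro < thresholds.homro)
    ):
        cat = CAT_OTHER
    elif metrics.otv_flag:
        cat = CAT_OTV
    elif metrics.n_clusters <= 1:
        cat = CAT_MONO
    elif metrics.n_minor_hom == 0:
        cat = CAT_NO_MINOR_HOM
    elif metrics.n_minor_allele_samples >= 2:
        cat = CAT_POLY
    else:
        cat = CAT_OTHER
    metrics.category = cat
    return cat


def conversion_summary(
    categories: Sequence[str],
    converted_set: frozenset = DEFAULT_CONVERTED,
) -> tuple[pd.DataFrame, float]:
    """Per-category counts/percentages and the converted fraction.

    "Converted" markers are those in ``converted_set`` (default: the three
    good-cluster categories PolyHighResolution, NoMinorHom and
    MonoHighResolution). Returns (table, converted_percent).
    """
    s = pd.Series(categories, dtype=object)
    total = len(s)
    counts = s.value_counts().reindex(list(CATEGORIES), fill_value=0)
    counts = counts[counts.index.isin(set(s)) | (counts > 0)] if total else counts
    table = pd.DataFrame(
        {
            "count": counts,
            "percent": (100.0 * counts / total).round(2) if total else 0.0,
        }
    )
    converted = int(s.isin(converted_set).sum())
    pct = 100.0 * converted / total if total else math.nan
    return table, pct


def sample_qc(
    sample_ids: Sequence[str], dqc: Sequence[float], call_rate: Sequence[float]
) -> list[SampleQC]:
    return [
        SampleQC(s, float(d), float(c))
        for s, d, c in zip(sample_ids, dqc, call_rate, strict=True)
    ]
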