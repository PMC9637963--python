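"""Array-design pipeline: variant filtering, probe evaluation, tiling, GMO screen.

The pipeline order is filter -> score -> recommend -> tile. A probe candidate
is a 71-mer flank (35 bases each side of the target SNP) on one strand;
marker/strand recommendation follows a fixed rule table over the probe
metrics (convertibility score, wobbles, poly/duplicate counts, interfering
polymorphisms within 24 bases), and density tiling keeps at most one marker
per fixed 200-bp genomic window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord, compute_frequency

logger = logging.getLogger(__name__)

FLANK = 35
FLANK_LEN = 2 * FLANK + 1  # 71-mer, target base at 1-based index 36

RECOMMENDED = "recommended"
NEUTRAL = "neutral"
NOT_RECOMMENDED = "not_recommended"
NOT_POSSIBLE = "not_possible"
_STATUS_ORDER = {RECOMMENDED: 0, NEUTRAL: 1, NOT_RECOMMENDED: 2, NOT_POSSIBLE: 3}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeCandidate:
    """One strand's probe candidate for a variant, with its design metrics."""

    variant: VariantRecord
    strand: str  # "forward" | "reverse"
    flank_71mer: str | None
    pconvert: float = math.nan
    interfering_within_24: int = 0
    wobble_count: int = 0
    wobble_distance: float = math.inf
    poly_count: int = 0
    duplicate_count: int = 0
    recommendation: str | None = None  # set only by recommend_probe

    def __post_init__(self):
        if self.flank_71mer is not None and len(self.flank_71mer) != FLANK_LEN:
            raise ValueError(
                f"flank must be {FLANK_LEN} bases, got {len(self.flank_71mer)}"
            )


@dataclass(frozen=True)
class TilingConfig:
    """Fixed-window density tiling: at most one marker per ``window_bp``.

    Windows are 1-anchored, non-overlapping ([1, w], [w+1, 2w], ...). Ties
    within a window break by priority (desc), then pconvert (desc), then
    position (asc).
    """

    window_bp: int = 200

    def __post_init__(self):
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")


# ---------------------------------------------------------------------------
# filtering / priority
# ---------------------------------------------------------------------------


def filter_variants(
    records: Sequence[VariantRecord],
    maf_min: float = 0.05,
    missing_max: float = 0.1,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Remove sites with MAF below ``maf_min`` or missing rate above ``missing_max``.

    The removal inequalities are strict, so a site at exactly MAF 0.05 and
    missing rate 0.1 is retained. Returns (retained, log) where the log has
    one row per input record with its removal reason (empty if retained).
    """
    retained, rows = [], []
    for r in records:
        freq = compute_frequency(r)
        reasons = []
        if freq.maf < maf_min:
            reasons.append(f"maf<{maf_min}")
        if freq.missing_rate > missing_max:
            reasons.append(f"missing>{missing_max}")
        if not reasons:
            retained.append(r)
        rows.append(
            {
                "marker_id": r.marker_id,
                "maf": freq.maf,
                "missing_rate": freq.missing_rate,
                "retained": not reasons,
                "reason": ";".join(reasons),
            }
        )
    return retained, pd.DataFrame(rows)


def assign_priority(record: VariantRecord, priority_spec: Mapping[str, int]) -> int:
    """Highest tier among the record's tags found in ``priority_spec`` (default 0).

    ``priority_spec`` maps a source tag or gene label to a tier in {0, 1, 2};
    agronomically important gene tags are the canonical tier-2 entries.
    """
    tiers = [priority_spec[t] for t in record.source_tags if t in priority_spec]
    record.priority = max(tiers, default=0)
    return record.priority


# ---------------------------------------------------------------------------
# probe construction & metrics
# ---------------------------------------------------------------------------


def extract_flank(
    record: VariantRecord,
    genome: Mapping[str, str],
    flank: int = FLANK,
) -> tuple[str | None, str | None]:
    """(forward, reverse) flanks of ``2*flank + 1`` bases centred on the target.

    Forward is the reference subsequence; reverse its reverse complement.
    ``None`` is returned for a strand when fewer than ``flank`` reference
    bases exist on either side (the candidate is then not buildable).
    """
    seq = genome.get(record.chrom)
    if seq is None:
        return None, None
    lo = record.pos - 1 - flank
    hi = record.pos + flank
    if lo < 0 or hi > len(seq):
        return None, None
    fwd = seq[lo:hi].upper()
    return fwd, reverse_complement(fwd)


def count_interfering(
    record: VariantRecord,
    cohort_positions: Mapping[str, np.ndarray],
    radius: int = 24,
) -> int:
    """Number of other variant sites within ``radius`` bases (inclusive)."""
    pos = np.asarray(cohort_positions.get(record.chrom, ()))
    if pos.size == 0:
        return 0
    lo = np.searchsorted(pos, record.pos - radius, side="left")
    hi = np.searchsorted(pos, record.pos + radius, side="right")
    n = int(hi - lo)
    # exclude the target site itself if indexed
    i = np.searchsorted(pos, record.pos)
    if i < pos.size and pos[i] == record.pos:
        n -= 1
    return n


def cohort_position_index(records: Iterable[VariantRecord]) -> dict[str, np.ndarray]:
    """Sorted per-chromosome position arrays for interference counting."""
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    return {c: np.array(sorted(p)) for c, p in by_chrom.items()}


def _longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = None
    for b in seq:
        run = run + 1 if b == prev else 1
        best = max(best, run)
        prev = b
    return best


def score_probe(flank_71mer: str) -> float:
    """Deterministic convertibility surrogate in [0, 1] for a 71-mer.

    Penalises GC content outside 0.3-0.7, homopolymer runs of six or more,
    and N bases (N within the central 25 bases costs three times as much as
    a peripheral N, and adding an N never raises the score). A user-supplied
    per-marker score table bypasses this function entirely.
    """
    seq = flank_71mer.upper()
    if len(seq) != FLANK_LEN:
        raise ValueError(f"expected a {FLANK_LEN}-mer, got length {len(seq)}")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"bases outside ACGTN in flank: {set(seq) - set('ACGTN')}")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    gc_pen = 2.0 * max(0.0, abs(gc - 0.5) - 0.2)
    hp_pen = 0.1 * max(0, _longest_homopolymer(seq) - 5)
    centre = range(FLANK - 12, FLANK + 13)  # central 25 bases
    n_pen = sum(0.15 if i in centre else 0.05 for i, b in enumerate(seq) if b == "N")
    return float(np.clip(1.0 - gc_pen - hp_pen - n_pen, 0.0, 1.0))


def wobble_metrics(flank_71mer: str) -> tuple[int, float]:
    """(wobble_count, wobble_distance) from IUPAC ambiguity codes in a flank.

    Distance is in bases from the central (target) base to the nearest
    ambiguity code; ``inf`` when there are none.
    """
    positions = [
        i for i, b in enumerate(flank_71mer.upper()) if b in IUPAC_AMBIGUOUS
    ]
    if not positions:
        return 0, math.inf
    return len(positions), float(min(abs(i - FLANK) for i in positions))


def duplicate_count(flank_71mer: str, genome: Mapping[str, str]) -> int:
    """Exact occurrences of the flank in the genome (either strand) minus one."""
    total = 0
    rc = reverse_complement(flank_71mer)
    for seq in genome.values():
        seq = seq.upper()
        for probe in {flank_71mer.upper(), rc}:
            start = 0
            while (i := seq.find(probe, start)) != -1:
                total += 1
                start = i + 1
    return max(0, total - 1)


# ---------------------------------------------------------------------------
# recommendation rule table
# ---------------------------------------------------------------------------


def _strand_status(
    c: ProbeCandidate,
    pconvert_min_recommend: float = 0.6,
    pconvert_min: float = 0.4,
    wobble_distance_min: float = 21.0,
    wobble_count_max: int = 3,
) -> str:
    """Rule table for one strand.

    not_possible: no probe buildable. not_recommended: duplicate count > 0,
    or poly count > 0, or pconvert < 0.4, or wobble distance < 21, or wobble
    count >= 3, or any other polymorphism within 24 bases. recommended:
    pconvert > 0.6, no wobbles and poly count 0. Otherwise neutral (the
    closure gap between the two clause sets).
    """
    if c.flank_71mer is None:
        return NOT_POSSIBLE
    if (
        c.duplicate_count > 0
        or c.poly_count > 0
        or c.pconvert < pconvert_min
        or c.wobble_distance < wobble_distance_min
        or c.wobble_count >= wobble_count_max
        or c.interfering_within_24 >= 1
    ):
        return NOT_RECOMMENDED
    if c.pconvert > pconvert_min_recommend and c.wobble_count == 0 and c.poly_count == 0:
        return RECOMMENDED
    return NEUTRAL


def recommend_probe(
    forward: ProbeCandidate,
    reverse: ProbeCandidate,
    **thresholds,
) -> tuple[str, ProbeCandidate | None]:
    """Apply the rule table per strand and choose the marker's strand.

    Each strand receives a status; the marker takes the best status, and when
    both strands share it the strand with the higher pconvert is tiled.
    Returns ``(marker_status, chosen_candidate)``; the chosen candidate is
    ``None`` when no probe is buildable on either strand.
    """
    for c in (forward, reverse):
        c.recommendation = _strand_status(c, **thresholds)
    ranked = sorted(
        (forward, reverse),
        key=lambda c: (
            _STATUS_ORDER[c.recommendation],
            -(c.pconvert if math.isfinite(c.pconvert) else -1.0),
        ),
    )
    best = ranked[0]
    if best.recommendation == NOT_POSSIBLE:
        return NOT_POSSIBLE, None
    return best.recommendation, best


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def tile_variants(
    candidates: Sequence[ProbeCandidate],
    config: TilingConfig = TilingConfig(),
) -> list[ProbeCandidate]:
    """Keep at most one candidate per fixed window of ``window_bp`` per chromosome.

    Only recommended/neutral candidates are eligible; within a window the
    winner maximises (priority, pconvert, -position) in that order.
    """
    eligible = [
        c for c in candidates if c.recommendation in (RECOMMENDED, NEUTRAL)
    ]
    winners: dict[tuple[str, int], ProbeCandidate] = {}
    for c in eligible:
        key = (c.variant.chrom, (c.variant.pos - 1) // config.window_bp)
        cur = winners.get(key)
        if cur is None or _tile_rank(c) < _tile_rank(cur):
            winners[key] = c
    return sorted(winners.values(), key=lambda c: (c.variant.chrom, c.variant.pos))


def _tile_rank(c: ProbeCandidate) -> tuple:
    p = c.pconvert if math.isfinite(c.pconvert) else -1.0
    return (-c.variant.priority, -p, c.variant.pos)


# ---------------------------------------------------------------------------
# GMO host-exclusion screen
# ---------------------------------------------------------------------------


def gmo_screen(
    probe_sequences: Sequence[str],
    host_genome: Mapping[str, str],
    k: int = 25,
) -> list[str]:
    """Retain probes with no exact k-mer match to the host genome (either strand).

    A probe is rejected as soon as any of its k-mers occurs exactly in the
    host genome on either strand; probes sharing at most k-1 consecutive
    bases with the host are retained. Probes shorter than k are an error.
    """
    host_kmers: set[str] = set()
    for seq in host_genome.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            host_kmers.add(km)
            host_kmers.add(reverse_complement(km))
    retained = []
    for probe in probe_sequences:
        if len(probe) < k:
            raise ValueError(f"probe shorter than k={k}: {len(probe)} bases")
        p = probe.upper()
        if any(p[i : i + k] in host_kmers for i in range(len(p) - k + 1)):
            continue
        retained.append(probe)
    return retained


# ---------------------------------------------------------------------------
# manifest & summaries
# ---------------------------------------------------------------------------


@dataclass
class DesignManifest:
    """Selected markers with their design attributes, as a DataFrame."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_candidates(cls, selected: Sequence[ProbeCandidate]) -> "DesignManifest":
        rows = []
        for c in selected:
            v = c.variant
            rows.append(
                {
                    "marker_id": v.marker_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "strand": c.strand,
                    "recommendation": c.recommendation,
                    "pconvert": c.pconvert,
                    "priority": v.priority,
                    "source_tags": ",".join(sorted(v.source_tags)),
                    "variant_class": v.variant_class,
                    "region": v.region,
                }
            )
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.table)


def summarize_design(
    manifest: DesignManifest | pd.DataFrame,
    partitions: Sequence[str] = ("region", "variant_class"),
) -> dict[str, pd.DataFrame]:
    """Count-and-percentage table per partition column.

    Percentages are ``100 * count / total`` rounded to two decimals; counts
    in every partition sum to the manifest total.
    """
    table = manifest.table if isinstance(manifest, DesignManifest) else manifest
    total = len(table)
    out = {}
    for col in partitions:
        counts = table[col].value_counts().sort_index()
        out[col] = pd.DataFrame(
            {
                "count": counts,
                "percent": (100.0 * counts / total).round(2) if total else 0.0,
            }
        )
    return out


def summarize_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Count/percentage arithmetic on pre-tabulated category counts."""
    s = pd.Series(counts, dtype=float)
    total = s.sum()
    return pd.DataFrame(
        {"count": s.astype(int), "percent": (100.0 * s / total).round(2)}
    )
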