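"""Variant/annotation data model and readers/writers for VCF, GFF3 and FASTA.

Genotype calls are held as the four-symbol alphabet ``AA / AB / BB / missing``
(A = reference allele, B = alternate allele, unphased). All coordinates are
1-based closed, following the VCF/GFF3 convention; any half-open structure
used internally (interval trees) is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

AA = "AA"
AB = "AB"
BB = "BB"
MISSING = "missing"
CALL_ALPHABET = (AA, AB, BB, MISSING)

REGION_EXON = "exon"
REGION_UTR = "UTR"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"
REGION_UNANNOTATED = "unannotated"
REGION_LABELS = (
    REGION_EXON,
    REGION_UTR,
    REGION_INTRON,
    REGION_INTERGENIC,
    REGION_UNANNOTATED,
)


class VcfFormatError(ValueError):
    """Raised for malformed VCF input (bad header, missing GT field)."""


class UndefinedFrequencyError(ValueError):
    """Raised when allele frequencies are requested for an all-missing site."""


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotype calls.

    Parameters
    ----------
    chrom, pos : locus (1-based).
    ref_allele, alt_allele : REF/ALT strings; equal length 1 means a SNP,
        anything else an indel.
    calls : per-sample calls in ``CALL_ALPHABET``.
    source_tags : provenance labels (e.g. ``japonica``, ``indica``,
        ``rufipogon``, ``plastid``, ``gmo``, trait-gene names).
    priority : design-priority tier, 0 (lowest) to 2 (highest).
    region : genomic-region label, one of ``REGION_LABELS``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    calls: np.ndarray
    source_tags: frozenset = field(default_factory=frozenset)
    priority: int = 0
    region: str = REGION_UNANNOTATED
    marker_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        self.calls = np.asarray(self.calls, dtype=object)
        bad = set(self.calls) - set(CALL_ALPHABET)
        if bad:
            raise ValueError(f"calls outside {CALL_ALPHABET}: {sorted(bad)}")
        self.source_tags = frozenset(self.source_tags)
        if not self.marker_id:
            self.marker_id = f"{self.chrom}_{self.pos}"

    @property
    def variant_class(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "indel"

    @property
    def n_samples(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class FrequencySummary:
    """Minor-allele frequency, missingness and heterozygosity of one site."""

    maf: float
    missing_rate: float
    het_rate: float

    def __post_init__(self):
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"maf out of [0, 0.5]: {self.maf}")
        for name in ("missing_rate", "het_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")


def compute_frequency(record: VariantRecord) -> FrequencySummary:
    """Allele-frequency summary over non-missing calls.

    The alternate-allele count is ``#AB + 2*#BB`` over non-missing calls;
    ``maf = min(f, 1 - f)``. Raises :class:`UndefinedFrequencyError` when
    every call is missing.
    """
    calls = record.calls
    n = len(calls)
    n_missing = int(np.sum(calls == MISSING))
    n_obs = n - n_missing
    if n_obs == 0:
        raise UndefinedFrequencyError(
            f"all {n} calls missing at {record.chrom}:{record.pos}"
        )
    n_het = int(np.sum(calls == AB))
    n_alt_hom = int(np.sum(calls == BB))
    f_alt = (n_het + 2 * n_alt_hom) / (2 * n_obs)
    return FrequencySummary(
        maf=min(f_alt, 1.0 - f_alt),
        missing_rate=n_missing / n,
        het_rate=n_het / n_obs,
    )


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------


class GenomeAnnotation:
    """Gene models with exon/UTR sub-intervals, queried per position.

    Intervals are 1-based closed. Region precedence is exon > UTR > intron
    so that the three genic labels are disjoint.
    """

    def __init__(self):
        self._genes: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._utrs: dict[str, IntervalTree] = {}

    @staticmethod
    def _add(trees: dict, chrom: str, start: int, end: int, data=None):
        if end < start:
            raise ValueError(f"negative-length interval {start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, data)

    def add_gene(
        self,
        chrom: str,
        start: int,
        end: int,
        exons: Sequence[tuple[int, int]] = (),
        utrs: Sequence[tuple[int, int]] = (),
        gene_id: str | None = None,
    ):
        self._add(self._genes, chrom, start, end, gene_id)
        for s, e in exons:
            if s < start or e > end:
                raise ValueError(f"exon {s}-{e} outside gene {start}-{end}")
            self._add(self._exons, chrom, s, e, gene_id)
        for s, e in utrs:
            if s < start or e > end:
                raise ValueError(f"UTR {s}-{e} outside gene {start}-{end}")
            self._add(self._utrs, chrom, s, e, gene_id)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._genes)

    def region_of(self, chrom: str, pos: int) -> str:
        if chrom not in self._genes:
            return REGION_UNANNOTATED
        if chrom in self._exons and self._exons[chrom].overlaps(pos):
            return REGION_EXON
        if chrom in self._utrs and self._utrs[chrom].overlaps(pos):
            return REGION_UTR
        if self._genes[chrom].overlaps(pos):
            return REGION_INTRON
        return REGION_INTERGENIC

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        """Build from a GFF3 file (gene / exon / *_UTR features)."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        ann = cls()
        for gene in db.features_of_type("gene"):
            exons = [
                (f.start, f.end)
                for f in db.children(gene, featuretype="exon")
            ]
            utrs = [
                (f.start, f.end)
                for f in db.children(
                    gene, featuretype=("five_prime_UTR", "three_prime_UTR")
                )
            ]
            ann.add_gene(gene.seqid, gene.start, gene.end, exons, utrs, gene.id)
        return ann


def annotate_region(record: VariantRecord, annotation: GenomeAnnotation) -> str:
    """Label a variant exon/UTR/intron/intergenic (precedence exon > UTR > intron).

    A chromosome absent from the annotation yields ``unannotated`` rather
    than an error. The label is also written back onto the record.
    """
    label = annotation.region_of(record.chrom, record.pos)
    record.region = label
    return label


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {0: AA, 1: AB, 3: BB, 2: MISSING}  # cyvcf2 gt_types codes


def read_vcf(path: str | Path, split_multiallelic: bool = False) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    Multi-allelic sites are skipped with a warning by default; with
    ``split_multiallelic=True`` each ALT allele becomes its own biallelic
    record (calls carrying any other ALT allele are set missing).
    Source tags and priority are recovered from the optional ``SOURCES``
    and ``PRIORITY`` INFO fields.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc

    records: list[VariantRecord] = []
    for v in vcf:
        if v.format("GT") is None and not v.genotypes:
            raise VcfFormatError(f"no GT field at {v.CHROM}:{v.POS}")
        tags = frozenset(
            t for t in str(v.INFO.get("SOURCES") or "").split(",") if t
        )
        priority = int(v.INFO.get("PRIORITY") or 0)
        if len(v.ALT) != 1:
            if not split_multiallelic:
                logger.warning(
                    "skipping multi-allelic site %s:%s (%d ALT alleles)",
                    v.CHROM, v.POS, len(v.ALT),
                )
                continue
            genos = v.genotypes
            for k, alt in enumerate(v.ALT, start=1):
                calls = []
                for g in genos:
                    alleles = [a for a in g[:-1]]
                    if -1 in alleles:
                        calls.append(MISSING)
                    elif any(a not in (0, k) for a in alleles):
                        calls.append(MISSING)
                    else:
                        calls.append((AA, AB, BB)[sum(a == k for a in alleles)])
                records.append(
                    VariantRecord(
                        v.CHROM, v.POS, v.REF, alt, np.array(calls, dtype=object),
                        source_tags=tags, priority=priority,
                        marker_id=f"{v.ID or f'{v.CHROM}_{v.POS}'}_{k}",
                    )
                )
            continue
        calls = np.array([_GT_MAP[t] for t in v.gt_types], dtype=object)
        records.append(
            VariantRecord(
                v.CHROM, v.POS, v.REF, v.ALT[0], calls,
                source_tags=tags, priority=priority,
                marker_id=v.ID or f"{v.CHROM}_{v.POS}",
            )
        )
    return records


_CALL_TO_GT = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> Path:
    """Write records to a VCF 4.2 text file (round-trips through read_vcf)."""
    records = list(records)
    path = Path(path)
    if sample_ids is None:
        n = records[0].n_samples if records else 0
        sample_ids = [f"S{i + 1}" for i in range(n)]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SOURCES,Number=.,Type=String,Description="Provenance tags">',
        '##INFO=<ID=PRIORITY,Number=1,Type=Integer,Description="Design priority tier">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if r.n_samples != len(sample_ids):
            raise ValueError(
                f"{r.marker_id}: {r.n_samples} calls for {len(sample_ids)} samples"
            )
        info = []
        if r.source_tags:
            info.append("SOURCES=" + ",".join(sorted(r.source_tags)))
        info.append(f"PRIORITY={r.priority}")
        gts = "\t".join(_CALL_TO_GT[c] for c in r.calls)
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.marker_id}\t{r.ref_allele}\t{r.alt_allele}"
            f"\t.\tPASS\t{';'.join(info)}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA / genotype matrices
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an (indexed) FASTA into a chrom -> sequence dict via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


_DOSAGE = {AA: 0.0, AB: 1.0, BB: 2.0, MISSING: np.nan}


def genotype_matrix(records: Sequence[VariantRecord]) -> np.ndarray:
    """Stack calls into an (n_samples, n_markers) 0/1/2 dosage matrix (NaN missing)."""
    if not records:
        return np.empty((0, 0))
    G = np.empty((records[0].n_samples, len(records)))
    for j, r in enumerate(records):
        G[:, j] = [_DOSAGE[c] for c in r.calls]
    return G
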