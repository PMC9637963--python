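"""Seeded synthetic-data generators for a selfing, rice-like population.

Every input the pipeline consumes can be produced here: a random reference
genome with non-overlapping gene models (FASTA + GFF3), a variant cohort
with a controlled MAF spectrum, missingness and inbreeding-driven
heterozygote deficit (VCF), two-channel intensity clouds with controllable
cluster geometry and off-target contamination, and additive phenotypes at a
stated heritability. Each generator is a pure function of (config, seed):
reruns are bit-identical.

The defaults emulate an inbred rice panel: inbreeding coefficient F = 0.95
(strongly selfing, so heterozygotes are rare and the NoMinorHom /
MonoHighResolution QC categories are common), MAF drawn uniformly on
[0.05, 0.5], 2% missing calls, and well-separated genotype clusters in
(contrast, size) space. Markers are independent; linkage disequilibrium is
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import AA, AB, BB, MISSING, GenomeAnnotation, VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs for the synthetic rice-like study."""

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 50_000
    genes_per_chrom: int = 10
    gene_length: int = 1_200
    # cohort
    n_samples: int = 100
    n_variants: int = 500
    indel_fraction: float = 0.1
    maf_bounds: tuple = (0.05, 0.5)
    missing_rate: float = 0.02
    inbreeding: float = 0.95  # F
    # intensity clusters
    hom_contrast: float = 1.0
    contrast_sd: float = 0.15
    size_baseline: float = 1.0
    size_sd: float = 0.1
    het_size_offset: float = 0.2
    otv_fraction: float = 0.0
    otv_size_shift: float = -0.5
    # trait
    n_qtl: int = 100
    h2: float = 0.5

    def __post_init__(self):
        for name in ("missing_rate", "inbreeding", "h2", "indel_fraction",
                     "otv_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_bounds
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_bounds must satisfy 0 <= lo <= hi <= 0.5")
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("need a positive genome size")
        if self.gene_length < 900:
            raise ValueError("gene_length must be >= 900 for the fixed "
                             "UTR/exon/intron layout")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome(config: SimConfig) -> tuple[dict, GenomeAnnotation, list]:
    """Random genome plus non-overlapping gene models.

    Returns (sequences, annotation, gff_rows); ``gff_rows`` are GFF3 line
    tuples ready for :func:`write_gff3`. Raises if the requested genes do
    not fit on a chromosome.
    """
    rng = _rng(config, 1)
    span = config.gene_length
    if config.genes_per_chrom * (span + 100) > config.chrom_length:
        raise ValueError("gene density too high for chromosome length")
    sequences, ann, rows = {}, GenomeAnnotation(), []
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c:02d}"
        sequences[chrom] = "".join(
            rng.choice(_BASES, size=config.chrom_length)
        )
        # evenly spaced, jittered, guaranteed non-overlapping gene starts
        slot = config.chrom_length // config.genes_per_chrom
        for g in range(config.genes_per_chrom):
            jitter = int(rng.integers(0, max(slot - span, 1)))
            start = g * slot + jitter + 1
            end = start + span - 1
            gid = f"{chrom}g{g + 1:03d}"
            # fixed internal layout: 5'UTR, exon, intron, exon, 3'UTR
            u5 = (start, start + 99)
            e1 = (start + 100, start + 399)
            e2 = (start + 700, start + span - 101)
            u3 = (start + span - 100, end)
            exons, utrs = [e1, e2], [u5, u3]
            ann.add_gene(chrom, start, end, exons, utrs, gid)
            rows.append((chrom, "sim", "gene", start, end, gid, None))
            for i, (s, e) in enumerate(exons, 1):
                rows.append((chrom, "sim", "exon", s, e, f"{gid}.e{i}", gid))
            rows.append((chrom, "sim", "five_prime_UTR", *u5, f"{gid}.u5", gid))
            rows.append((chrom, "sim", "three_prime_UTR", *u3, f"{gid}.u3", gid))
    return sequences, ann, rows


def write_gff3(rows, path: str | Path) -> Path:
    path = Path(path)
    lines = ["##gff-version 3"]
    for chrom, source, ftype, start, end, fid, parent in rows:
        attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
        lines.append(
            f"{chrom}\t{source}\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_cohort(config: SimConfig, sequences: dict) -> list[VariantRecord]:
    """Variant cohort with inbreeding-controlled genotypes.

    Per variant the alternate-allele frequency p is uniform on
    ``maf_bounds`` and genotypes are drawn with heterozygote probability
    2 p (1 - p) (1 - F); F = 1 gives full selfing (no heterozygotes).
    Missing calls are masked independently at ``missing_rate``. Source tags
    alternate between japonica- and indica-like provenance.
    """
    rng = _rng(config, 2)
    chroms = list(sequences)
    records = []
    taken: set[tuple[str, int]] = set()
    while len(records) < config.n_variants:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(sequences[chrom]) + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref = sequences[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if rng.random() < config.indel_fraction:
            alt = ref + alt  # 1-bp insertion
        p = float(rng.uniform(*config.maf_bounds))
        F = config.inbreeding
        p_het = 2 * p * (1 - p) * (1 - F)
        p_bb = p**2 + p * (1 - p) * F
        u = rng.random(config.n_samples)
        calls = np.full(config.n_samples, AA, dtype=object)
        calls[u < p_bb + p_het] = AB
        calls[u < p_bb] = BB
        calls[rng.random(config.n_samples) < config.missing_rate] = MISSING
        tag = "japonica" if rng.random() < 0.8 else "indica"
        records.append(
            VariantRecord(chrom, pos, ref, alt, calls,
                          source_tags=frozenset({tag}))
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


_CALL_CONTRAST_SIGN = {AA: 1.0, AB: 0.0, BB: -1.0}


def simulate_intensities(
    records: list[VariantRecord], config: SimConfig
) -> pd.DataFrame:
    """Two-channel intensity table for every (marker, sample) pair.

    Genotype clusters sit at contrast +/-c (homozygotes) and 0 (het, with a
    ``het_size_offset`` lift in size); an ``otv_fraction`` of samples per
    marker is re-drawn from a low-size off-target cluster at het-like
    contrast. Channels are recovered from (contrast, size) by
    a = 2^(size + contrast/2), b = 2^(size - contrast/2), so the QC
    intensity transform inverts this exactly.
    """
    rng = _rng(config, 3)
    rows = []
    n = config.n_samples
    for r in records:
        contrast = np.empty(n)
        size = np.empty(n)
        for i, call in enumerate(r.calls):
            g = call if call != MISSING else [AA, AB, BB][int(rng.integers(3))]
            contrast[i] = rng.normal(
                _CALL_CONTRAST_SIGN[g] * config.hom_contrast, config.contrast_sd
            )
            lift = config.het_size_offset if g == AB else 0.0
            size[i] = rng.normal(config.size_baseline + lift, config.size_sd)
        if config.otv_fraction > 0:
            otv = rng.random(n) < config.otv_fraction
            k = int(otv.sum())
            contrast[otv] = rng.normal(0.0, config.contrast_sd, size=k)
            size[otv] = rng.normal(
                config.size_baseline + config.het_size_offset
                + config.otv_size_shift,
                config.size_sd, size=k,
            )
        a = 2.0 ** (size + contrast / 2.0)
        b = 2.0 ** (size - contrast / 2.0)
        for i in range(n):
            rows.append((r.marker_id, f"S{i + 1}", a[i], b[i]))
    return pd.DataFrame(
        rows, columns=["marker_id", "sample_id", "channel_a", "channel_b"]
    )


def simulate_phenotype(
    Z: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive trait with ``n_qtl`` causal markers at heritability ``h2``.

    QTL are drawn without replacement, effects are standard normal, the
    genetic value is g = Z_qtl u, and residual noise is scaled so that
    var(g)/var(y) equals ``h2`` (h2 = 1 gives y = g exactly; h2 = 0 gives
    pure noise). Returns (y, u_true, g) where ``u_true`` is dense over all
    markers (zero off the QTL).
    """
    rng = _rng(config, 4)
    Z = np.asarray(Z, float)
    n, m = Z.shape
    if config.n_qtl > m:
        raise ValueError(f"n_qtl={config.n_qtl} exceeds m={m} markers")
    qtl = rng.choice(m, size=config.n_qtl, replace=False)
    u = np.zeros(m)
    u[qtl] = rng.normal(0.0, 1.0, size=config.n_qtl)
    g = Z @ u
    var_g = float(np.var(g))
    if config.h2 == 0.0 or var_g == 0.0:
        y = rng.normal(0.0, 1.0, size=n)
    elif config.h2 == 1.0:
        y = g.copy()
    else:
        var_e = var_g * (1.0 - config.h2) / config.h2
        y = g + rng.normal(0.0, np.sqrt(var_e), size=n)
    return y, u, g


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write FASTA, GFF3, VCF, intensity and
    phenotype/truth CSVs into ``outdir``. Returns the path map."""
    from .io_formats import genotype_matrix, write_fasta, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, _, gff_rows = simulate_genome(config)
    records = simulate_cohort(config, sequences)
    intens = simulate_intensities(records, config)
    Z = np.nan_to_num(genotype_matrix(records) - 1.0)
    if config.n_qtl > config.n_variants:  # small studies: every marker a QTL
        config = replace(config, n_qtl=config.n_variants)
    y, u, g = simulate_phenotype(Z, config)
    paths = {
        "fasta": write_fasta(sequences, outdir / "genome.fa"),
        "gff3": write_gff3(gff_rows, outdir / "genes.gff3"),
        "vcf": write_vcf(
            records, outdir / "cohort.vcf",
            sample_ids=[f"S{i + 1}" for i in range(config.n_samples)],
            contig_lengths={c: len(s) for c, s in sequences.items()},
        ),
    }
    intens.to_csv(outdir / "intensities.csv", index=False)
    paths["intensities"] = outdir / "intensities.csv"
    pheno = pd.DataFrame(
        {"sample_id": [f"S{i + 1}" for i in range(config.n_samples)],
         "trait": y, "genetic_value": g}
    )
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    paths["phenotypes"] = outdir / "phenotypes.csv"
    pd.DataFrame(
        {"marker_id": [r.marker_id for r in records], "true_effect": u}
    ).to_csv(outdir / "true_effects.csv", index=False)
    paths["true_effects"] = outdir / "true_effects.csv"
    return paths
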