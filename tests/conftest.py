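"""Shared fixtures and small generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from axiomforge.io_formats import AA, AB, BB, MISSING, VariantRecord


def make_record(calls, chrom="chr01", pos=100, ref="A", alt="G", **kw):
    return VariantRecord(chrom, pos, ref, alt, np.array(calls, dtype=object), **kw)


def inbred_genotypes(n, m, rng, F=0.95, maf_bounds=(0.05, 0.5)):
    """0/1/2 dosage matrix for an inbred panel with per-marker uniform MAF."""
    p = rng.uniform(*maf_bounds, m)
    p_het = 2 * p * (1 - p) * (1 - F)
    p_bb = p**2 + p * (1 - p) * F
    u = rng.random((n, m))
    G = np.zeros((n, m))
    G[u < p_bb + p_het] = 1
    G[u < p_bb] = 2
    return G


def additive_trait(Z, n_qtl, h2, rng):
    """(y, qtl_idx, g): additive trait at stated heritability."""
    n, m = Z.shape
    qtl = rng.choice(m, n_qtl, replace=False)
    u = rng.normal(0, 1, n_qtl)
    g = Z[:, qtl] @ u
    if h2 >= 1.0:
        return g.copy(), qtl, g
    if h2 <= 0.0 or np.var(g) == 0:
        return rng.standard_normal(n), qtl, g
    e = rng.normal(0, np.sqrt(np.var(g) * (1 - h2) / h2), n)
    return g + e, qtl, g


@pytest.fixture(scope="session")
def sim_study():
    """One small synthetic study shared by read-only tests."""
    from axiomforge.simulate import SimConfig, simulate_cohort, simulate_genome

    cfg = SimConfig(seed=42, n_samples=60, n_variants=150)
    seqs, ann, gff_rows = simulate_genome(cfg)
    records = simulate_cohort(cfg, seqs)
    return {"config": cfg, "sequences": seqs, "annotation": ann,
            "gff_rows": gff_rows, "records": records}
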