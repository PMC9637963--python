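"""Intensity transform, cluster metrics, six-category classification."""

import math

import numpy as np
import pytest

from axiomforge import cluster_qc as cq
from axiomforge.cluster_qc import (
    CAT_CRBT, CAT_MONO, CAT_NO_MINOR_HOM, CAT_OTHER, CAT_OTV, CAT_POLY,
    ClusterFit, ClusterStats, QCThresholds, SNPQCMetrics,
)
from axiomforge.io_formats import AA, AB, BB, MISSING


def _fit(aa=None, ab=None, bb=None):
    """ClusterFit from (n, mean_contrast, sd_contrast, mean_size, sd_size)."""
    fit = ClusterFit()
    for g, t in ((AA, aa), (AB, ab), (BB, bb)):
        if t is not None:
            fit.clusters[g] = ClusterStats(*t)
    return fit


class TestTransform:
    @pytest.mark.parametrize("a, b, contrast, size", [
        (8.0, 8.0, 0.0, 3.0),
        (16.0, 4.0, 2.0, 3.0),
        (4.0, 4.0, 0.0, 2.0),
    ])
    def test_log_ratio_and_mean(self, a, b, contrast, size):
        c, s = cq.transform_intensities([a], [b])
        assert c[0] == pytest.approx(contrast)
        assert s[0] == pytest.approx(size)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cq.transform_intensities([1.0, 0.0], [1.0, 1.0])


class TestFitClusters:
    def test_hand_computed_summary(self):
        contrast = [1.0, 1.2, 0.0, -0.9, -1.1, 0.2]
        size = [2.0, 2.2, 2.5, 1.9, 2.1, 2.7]
        calls = [AA, AA, AB, BB, BB, AB]
        fit = cq.fit_clusters(contrast, size, calls)
        assert fit[AA].n == 2
        assert fit[AA].mean_contrast == pytest.approx(1.1)
        assert fit[AA].sd_contrast == pytest.approx(np.std([1.0, 1.2], ddof=1))
        assert fit[AB].mean_size == pytest.approx(2.6)
        assert fit[BB].mean_contrast == pytest.approx(-1.0)

    def test_absent_and_singleton_clusters(self):
        fit = cq.fit_clusters([1.0, 0.9], [2.0, 2.1], [AA, MISSING])
        assert fit.present(AA) and not fit.present(AB) and not fit.present(BB)
        assert fit[AA].sd_contrast == 0.0  # singleton

    def test_metrics_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=30)
        s = rng.normal(size=30)
        calls = np.array([AA, AB, BB] * 10, dtype=object)
        perm = rng.permutation(30)
        f1 = cq.fit_clusters(c, s, calls)
        f2 = cq.fit_clusters(c[perm], s[perm], calls[perm])
        for g in (AA, AB, BB):
            assert f1[g].mean_contrast == pytest.approx(f2[g].mean_contrast)
            assert f1[g].sd_size == pytest.approx(f2[g].sd_size)


class TestFLD:
    def test_hand_formula(self):
        fit = _fit(aa=(10, 1.0, 0.2, 2.0, 0.1), ab=(10, 0.0, 0.2, 2.0, 0.1),
                   bb=(10, -1.0, 0.2, 2.0, 0.1))
        assert cq.compute_fld(fit) == pytest.approx(5.0)

    def test_sign_flip_invariance(self):
        fit = _fit(aa=(8, 0.8, 0.15, 2, 0.1), ab=(4, 0.1, 0.2, 2, 0.1),
                   bb=(12, -1.2, 0.25, 2, 0.1))
        flipped = _fit(aa=(12, 1.2, 0.25, 2, 0.1), ab=(4, -0.1, 0.2, 2, 0.1),
                       bb=(8, -0.8, 0.15, 2, 0.1))
        assert cq.compute_fld(fit) == pytest.approx(cq.compute_fld(flipped))

    def test_undefined_without_het_cluster(self):
        assert math.isnan(cq.compute_fld(_fit(aa=(5, 1, 0.1, 2, 0.1))))

    def test_zero_pooled_sd_is_infinite(self):
        fit = _fit(aa=(5, 1.0, 0.0, 2, 0), ab=(5, 0.0, 0.0, 2, 0))
        assert cq.compute_fld(fit) == math.inf

    def test_nearest_hom_governs(self):
        fit = _fit(aa=(10, 0.5, 0.1, 2, 0.1), ab=(10, 0.0, 0.1, 2, 0.1),
                   bb=(10, -2.0, 0.1, 2, 0.1))
        assert cq.compute_fld(fit) == pytest.approx(0.5 / 0.1)


class TestHetSO:
    def test_chord_offset(self):
        fit = _fit(aa=(5, 1.0, 0.1, 1.0, 0.1), ab=(5, 0.0, 0.1, 1.25, 0.1),
                   bb=(5, -1.0, 0.1, 1.0, 0.1))
        assert cq.compute_hetso(fit) == pytest.approx(0.25)

    def test_on_chord_is_zero_and_below_negative(self):
        on = _fit(aa=(5, 1.0, 0.1, 1.0, 0.1), ab=(5, 0.5, 0.1, 1.5, 0.1),
                  bb=(5, -1.0, 0.1, 3.0, 0.1))
        # chord at contrast 0.5 between (1,1) and (-1,3): size 1.5
        assert cq.compute_hetso(on) == pytest.approx(0.0)
        below = _fit(aa=(5, 1.0, 0.1, 1.0, 0.1), ab=(5, 0.0, 0.1, 0.7, 0.1),
                     bb=(5, -1.0, 0.1, 1.0, 0.1))
        assert cq.compute_hetso(below) < 0

    def test_undefined_cases(self):
        assert math.isnan(cq.compute_hetso(_fit(aa=(5, 1, 0.1, 2, 0.1),
                                                ab=(5, 0, 0.1, 2, 0.1))))
        degenerate = _fit(aa=(5, 0.5, 0.1, 2, 0.1), ab=(5, 0, 0.1, 2, 0.1),
                          bb=(5, 0.5, 0.1, 2, 0.1))
        assert math.isnan(cq.compute_hetso(degenerate))


class TestHomRO:
    @pytest.mark.parametrize("aa, bb, expected", [
        ((5, 0.8, 0.1, 2, 0.1), (5, -0.5, 0.1, 2, 0.1), 0.5),
        (None, (5, -0.7, 0.1, 2, 0.1), 0.7),
        ((5, -0.2, 0.1, 2, 0.1), None, -0.2),  # wrong side of zero
    ])
    def test_min_rule_and_signs(self, aa, bb, expected):
        assert cq.compute_homro(_fit(aa=aa, bb=bb)) == pytest.approx(expected)

    def test_symmetric_homs(self):
        fit = _fit(aa=(5, 0.9, 0.1, 2, 0.1), bb=(5, -0.9, 0.1, 2, 0.1))
        assert cq.compute_homro(fit) == pytest.approx(0.9)

    def test_no_hom_is_undefined(self):
        assert math.isnan(cq.compute_homro(_fit(ab=(5, 0, 0.1, 2, 0.1))))


class TestCallGenotypes:
    def test_three_separated_blobs_recover_truth(self):
        rng = np.random.default_rng(6)
        truth = np.array([AA] * 40 + [AB] * 30 + [BB] * 40, dtype=object)
        centres = {AA: 1.0, AB: 0.0, BB: -1.0}
        contrast = np.array([rng.normal(centres[g], 0.08) for g in truth])
        calls, conf = cq.call_genotypes(contrast)
        called = calls != MISSING
        assert np.mean(called) > 0.97
        assert np.all(calls[called] == truth[called])

    def test_single_blob_single_genotype(self):
        rng = np.random.default_rng(7)
        calls, _ = cq.call_genotypes(rng.normal(0.9, 0.05, 60))
        assert set(calls) == {AA}

    def test_ambiguous_point_blanked(self):
        # two broad overlapping clusters; the exact midpoint has a flat
        # posterior and must fall below the confidence threshold
        rng = np.random.default_rng(8)
        contrast = np.concatenate([
            rng.normal(0.6, 0.3, 200), rng.normal(-0.6, 0.3, 200), [0.0]
        ])
        calls, conf = cq.call_genotypes(contrast)
        assert calls[-1] == MISSING
        assert conf[-1] < 0.95

    def test_degenerate_zero_variance(self):
        calls, conf = cq.call_genotypes(np.full(10, 0.7))
        assert set(calls) == {AA}
        assert np.all(conf == 1.0)


class TestDetectOTV:
    @staticmethod
    def _marker(otv_fraction, rng, n=200):
        truth = rng.choice([AA, AB, BB], size=n, p=[0.4, 0.3, 0.3])
        centres = {AA: 1.0, AB: 0.0, BB: -1.0}
        contrast = np.array([rng.normal(centres[g], 0.1) for g in truth])
        size = np.array([rng.normal(1.2 if g == AB else 1.0, 0.05)
                         for g in truth])
        k = int(otv_fraction * n)
        if k:
            idx = rng.choice(n, k, replace=False)
            contrast[idx] = rng.normal(0.0, 0.1, k)
            size[idx] = rng.normal(0.7, 0.05, k)  # 0.5 below the het cloud
        calls, _ = cq.call_genotypes(contrast)
        fit = cq.fit_clusters(contrast, size, calls)
        return fit, contrast, size, calls

    def test_injected_subcluster_flagged(self):
        fit, c, s, calls = self._marker(0.10, np.random.default_rng(1))
        assert cq.detect_otv(fit, c, s, calls)

    def test_clean_marker_not_flagged(self):
        fit, c, s, calls = self._marker(0.0, np.random.default_rng(2))
        assert not cq.detect_otv(fit, c, s, calls)

    def test_below_fraction_threshold_not_flagged(self):
        fit, c, s, calls = self._marker(0.02, np.random.default_rng(3))
        assert not cq.detect_otv(fit, c, s, calls)


def _oracle_classify(m: SNPQCMetrics, t: QCThresholds) -> str:
    """Independent re-statement of the decision tree, evaluated stepwise."""
    below = []
    for value, cut in ((m.fld, t.fld), (m.hetso, t.hetso), (m.homro, t.homro)):
        if not math.isnan(value):
            below.append(value < cut)
    if m.call_rate < t.call_rate:
        return CAT_CRBT
    if any(below):
        return CAT_OTHER
    if m.otv_flag:
        return CAT_OTV
    if m.n_clusters <= 1:
        return CAT_MONO
    if m.n_minor_hom == 0:
        return CAT_NO_MINOR_HOM
    if m.n_minor_allele_samples >= 2:
        return CAT_POLY
    return CAT_OTHER


def _random_metrics(rng) -> SNPQCMetrics:
    nan_or = lambda v: math.nan if rng.random() < 0.2 else v
    return SNPQCMetrics(
        call_rate=float(rng.uniform(80, 100)),
        fld=nan_or(float(rng.uniform(0, 10))),
        hetso=nan_or(float(rng.uniform(-1, 1))),
        homro=nan_or(float(rng.uniform(-1, 1))),
        n_clusters=int(rng.integers(1, 4)),
        n_minor_allele_samples=int(rng.integers(0, 10)),
        n_minor_hom=int(rng.integers(0, 4)),
        otv_flag=bool(rng.random() < 0.3),
    )


class TestClassifySNP:
    def test_poly_high_resolution(self):
        m = SNPQCMetrics(call_rate=99, fld=5, hetso=0.3, homro=0.6,
                         n_clusters=3, n_minor_allele_samples=7, n_minor_hom=5)
        assert cq.classify_snp(m) == CAT_POLY

    def test_call_rate_below_threshold(self):
        m = SNPQCMetrics(call_rate=96.5, fld=5, hetso=0.3, homro=0.6,
                         n_clusters=3, n_minor_allele_samples=7, n_minor_hom=5)
        assert cq.classify_snp(m) == CAT_CRBT

    def test_low_fld_is_other(self):
        m = SNPQCMetrics(call_rate=99, fld=2.0, hetso=0.3, homro=0.6,
                         n_clusters=3, n_minor_allele_samples=7, n_minor_hom=5)
        assert cq.classify_snp(m) == CAT_OTHER

    def test_two_clusters_without_minor_hom(self):
        m = SNPQCMetrics(call_rate=99, fld=5, hetso=math.nan, homro=0.6,
                         n_clusters=2, n_minor_allele_samples=6, n_minor_hom=0)
        assert cq.classify_snp(m) == CAT_NO_MINOR_HOM

    def test_single_cluster_is_mono(self):
        m = SNPQCMetrics(call_rate=99, fld=math.nan, hetso=math.nan,
                         homro=0.8, n_clusters=1, n_minor_allele_samples=0,
                         n_minor_hom=0)
        assert cq.classify_snp(m) == CAT_MONO

    def test_total_and_agrees_with_oracle_on_10000_random_vectors(self):
        rng = np.random.default_rng(13)
        thr = QCThresholds()
        for _ in range(10_000):
            m = _random_metrics(rng)
            got = cq.classify_snp(m, thr)
            assert got == _oracle_classify(m, thr)
            assert got in cq.CATEGORIES


class TestCohortProperties:
    def test_clean_separated_markers_mostly_poly(self):
        """Markers with >= 5 sd cluster separation and common minor alleles
        should essentially always reach PolyHighResolution."""
        from axiomforge.simulate import (SimConfig, simulate_cohort,
                                         simulate_genome, simulate_intensities)

        cfg = SimConfig(seed=21, n_samples=150, n_variants=120,
                        inbreeding=0.0, maf_bounds=(0.3, 0.5),
                        missing_rate=0.0, hom_contrast=1.0, contrast_sd=0.15)
        seqs, _, _ = simulate_genome(cfg)
        recs = simulate_cohort(cfg, seqs)
        df = simulate_intensities(recs, cfg)
        cats = []
        for marker, sub in df.groupby("marker_id"):
            c, s = cq.transform_intensities(sub["channel_a"].to_numpy(),
                                            sub["channel_b"].to_numpy())
            calls, _ = cq.call_genotypes(c)
            cats.append(cq.classify_snp(cq.compute_snp_metrics(c, s, calls)))
        assert np.mean(np.array(cats) == CAT_POLY) >= 0.99

    def test_degrading_separation_lowers_fld(self):
        rng = np.random.default_rng(30)
        flds = []
        for sd in (0.1, 0.2, 0.4):
            truth = np.array([AA] * 50 + [AB] * 50 + [BB] * 50, dtype=object)
            centres = {AA: 1.0, AB: 0.0, BB: -1.0}
            c = np.array([rng.normal(centres[g], sd) for g in truth])
            s = np.ones_like(c)
            flds.append(cq.compute_fld(cq.fit_clusters(c, s, truth)))
        assert flds[0] > flds[1] > flds[2]

    def test_category_counts_sum_to_cohort(self):
        cats = [CAT_POLY] * 5 + [CAT_OTV] * 2 + [CAT_OTHER] * 3
        table, pct = cq.conversion_summary(cats)
        assert table["count"].sum() == 10
        assert pct == pytest.approx(50.0)

    def test_all_one_category_is_100(self):
        table, pct = cq.conversion_summary([CAT_POLY] * 8)
        assert pct == pytest.approx(100.0)
        assert table.loc[CAT_POLY, "percent"] == pytest.approx(100.0)


class TestSampleQC:
    @pytest.mark.parametrize("dqc, cr, passed", [
        (0.83, 0.97, True),
        (0.82, 0.99, False),
        (0.95, 0.96, False),
        (0.9, 0.98, True),
    ])
    def test_pass_rule(self, dqc, cr, passed):
        (s,) = cq.sample_qc(["x"], [dqc], [cr])
        assert s.passed is passed
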