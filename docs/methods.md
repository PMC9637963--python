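# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `axiomforge`, in the spirit of the methods sections of
msprime or statsmodels.

## Variant model and filtering

A variant is a biallelic site with per-sample calls in
{AA, AB, BB, missing} (A = reference allele, B = alternate, unphased). The
alternate-allele frequency is (#AB + 2·#BB) / (2·#non-missing) and
MAF = min(f, 1−f); the missing rate is over all calls. Filtering removes a
site when MAF < 0.05 **or** missing rate > 0.1; both inequalities are
strict, so a site at exactly MAF 0.05 and missingness 0.1 is retained.
Multi-allelic VCF sites are skipped with a warning by default; opt-in
splitting emits one biallelic record per ALT allele, with calls carrying any
other ALT set missing. Genomic-region labels use 1-based closed intervals
with precedence exon > UTR > intron, so the three genic labels are disjoint
and labels partition any cohort; an unknown chromosome yields
`unannotated`, not an error.

## Probe candidates and the recommendation rule table

A probe candidate is the 71-mer reference flank centred on the target SNP
(35 bases each side), per strand; the reverse-strand candidate is the
reverse complement. A target within 35 bases of a contig end is
*not_possible* on that strand.

Strand status is decided by a fixed rule table:

- **not_recommended** if duplicate count > 0, or poly count > 0, or
  pconvert < 0.4, or wobble distance < 21, or wobble count ≥ 3, or any
  other polymorphism lies within 24 bases of the target (inclusive radius —
  the conservative probe-safety reading);
- otherwise **recommended** if pconvert > 0.6, no wobbles, poly count = 0;
- otherwise **neutral** (the closure gap between the two clause sets, which
  name the category but do not define it).

At marker level the better strand status wins; on a tie the strand with the
higher pconvert is tiled. Wobbles are IUPAC ambiguity codes in the flank;
wobble distance is measured in bases from the central target base.

**Convertibility surrogate.** The proprietary in-silico convertibility
score is replaced by a single documented function on the 71-mer:
`score = clip(1 − gc_pen − hp_pen − n_pen, 0, 1)` with
`gc_pen = 2·max(0, |GC − 0.5| − 0.2)` (no penalty inside GC 0.3–0.7),
`hp_pen = 0.1·max(0, longest homopolymer − 5)`, and an N penalty of 0.15
per N within the central 25 bases and 0.05 elsewhere. The N penalty slopes
dominate the largest possible GC-penalty relief from removing one base
(2/71 ≈ 0.028), so adding an N can never raise the score. A user-supplied
per-marker score table bypasses the surrogate entirely; the 0.4/0.6 rule
thresholds are configurable.

**Tiling.** Density tiling partitions each chromosome into fixed,
1-anchored, non-overlapping windows of 200 bp (configurable) and keeps at
most one recommended/neutral candidate per window, chosen by priority
(descending), then pconvert (descending), then leftmost position — a
deterministic, priority-respecting argmax that tests verify against
exhaustive per-window enumeration.

**GMO host-exclusion screen.** A probe intended to detect transgene
sequence must not cross-hybridize with the host genome. The screen indexes
all host k-mers (k = 25 default, both strands) and rejects a probe iff any
of its k-mers occurs exactly in the host; a probe sharing at most k−1
consecutive bases is retained. Exact k-mer matching replaces
alignment-based screening: it is deterministic, dependency-free and
implements the same reject/retain contract.

## Cluster QC

Per sample and marker the two allele channels a, b > 0 are transformed to
contrast = log₂(a/b) and size = (log₂a + log₂b)/2. Genotype calling (a
stand-in for the platform's proprietary caller) fits 1–3 component Gaussian
mixtures in contrast, selects the component count by BIC, labels components
AA/AB/BB by their contrast means (sign with a ±0.2 dead zone, rank-order
fallback), and blanks calls whose posterior falls below 0.95.

Cluster summaries use the sample standard deviation (ddof = 1; 0 for
singletons). The marker metrics, with their default thresholds:

- **CR** (call rate, ≥ 97%): percent non-missing calls.
- **FLD** (≥ 3.6): min over present hom clusters of
  |mean contrast(hom) − mean contrast(AB)| / pooled SD, the pooled SD being
  the square root of the n-weighted mean of all present clusters' contrast
  variances. Undefined without a het cluster; +∞ at zero pooled SD.
- **HetSO** (≥ −0.1): vertical offset of the het centre from the hom–hom
  chord in (contrast, size) space; negative means a weak het cluster below
  the chord. Undefined unless all three clusters are present.
- **HomRO** (≥ 0.3): signed contrast distance from zero of the hom cluster
  nearest zero (min(contrast(AA), −contrast(BB)) when both are present);
  negative flags a cluster on the wrong side of zero.

The platform does not publish closed-form definitions of these metrics; the
formulas above are fixed here and are threshold-compatible with the
conventional cut-offs.

**OTV heuristic.** An off-target variant shows an extra low-intensity
sub-cluster at het-like contrast. The flag fires when ≥ 5% of samples sit
within the het contrast band at a size ≥ 0.3 below the *expected het size*.
The reference is max(AB mean size, hom–hom chord at the band centre): in a
strongly selfing panel genuine hets are rare, so the contaminating
sub-cluster is often the only thing called AB and a naive AB-mean reference
would mask itself; the chord fallback keeps the detector meaningful there.
Both parameters are configurable.

**Classification.** Exactly one of six categories, in fixed order:
(1) CR below threshold → CallRateBelowThreshold; (2) any *defined*
resolution metric below threshold → Other (NaN metrics pass); (3) OTV flag
→ OTV; (4) single cluster → MonoHighResolution; (5) no minor homozygote →
NoMinorHom; (6) ≥ 2 minor-allele samples → PolyHighResolution; else Other.
Mono = one cluster and NoMinorHom = two clusters lacking the minor
homozygote follows standard SNPolisher semantics. "Converted" markers
default to {PolyHighResolution, NoMinorHom, MonoHighResolution}
(configurable). Samples pass QC iff DQC ≥ 0.83 and call rate ≥ 0.97; DQC is
consumed as a given per-sample number, never computed.

## Mixed-model GWAS

Kinship is the VanRaden genomic relationship matrix
K = WWᵀ / 2Σpⱼ(1−pⱼ), W the dosage matrix centred by twice the allele
frequency, with marker-mean imputation of missing dosages; an IBS matrix is
available by flag. Note that under strong inbreeding diag(K) ≈ 1 + F, so
σ²ᵤ/(σ²ᵤ+σ²ₑ) is a pseudo-heritability on the K scale; simulations that
target a variance ratio should normalize K to unit mean diagonal.

The null model y = Xβ + g + e, g ~ N(0, σ²ᵤK), e ~ N(0, σ²ₑI) is fitted by
REML profiled to one dimension: on the eigenbasis of SKS (S the fixed-effect
projection) the restricted likelihood is a scalar function of
δ = σ²ₑ/σ²ᵤ, evaluated in O(n) per point. The search is a 101-point grid on
log₁₀δ ∈ [−6, 8] refined by bounded Brent — deterministic for fixed inputs.
A materially non-PSD K is an error.

Marker tests use the P3D/EMMAX approximation: the null variance components
are reused for every marker, V^(−1/2) whitening via the eigendecomposition
of K turns GLS into OLS on rotated data, and markers are residualized on
the rotated covariates (Frisch–Waugh), giving a vectorized scan. p-values
are Wald t-tests with n − p − 1 degrees of freedom, which makes the scan
*exactly* OLS when K = I and σ²ᵤ = 0. Monomorphic or covariate-collinear
markers return effect 0, p = 1 with a warning. The default genome-wide
threshold is p < 3.16 × 10⁻⁷ (−log₁₀p = 6.5); a −log₁₀p = 7.0 cut-off is a
flag away, as conventions differ. Null simulations (n = 200, m = 2,000,
20 seeds) put the empirical type-I error at α = 0.05 inside the binomial
95% CI.

## Genomic selection

**rrBLUP.** y = μ + Zu + e with u ~ N(0, Iσ²ᵤ). Marker columns are centred
internally (leaving u unchanged); missing genotypes are imputed to the
marker mean; {0,1,2} and {−1,0,1} codings are both accepted.
λ = σ²ₑ/σ²ᵤ is estimated by REML through the equivalent kinship-form model
on the eigenbasis of ZcZcᵀ (a fixed-λ mode exists for oracle testing), then
μ = (1ᵀH⁻¹y)/(1ᵀH⁻¹1) and u = Zcᵀ H⁻¹(y − μ1) with H = ZcZcᵀ + λI. The
marker-effect form and the kinship (GBLUP) form agree to numerical
precision — an algebraic identity the tests assert at 10⁻⁸.

**Cross-validation.** Default fourfold (75% training); an 80/20 fivefold
preset is provided since both conventions circulate. Per seeded replicate
the samples are re-partitioned, each fold is predicted from a model trained
on the rest, and predictive ability r is the Pearson correlation of
observed phenotypes with the pooled held-out GEBVs; the default is 50
replicates. Under a pure-noise trait cross-validated r is slightly
*negative* (each sample is excluded from its own training-fold mean), so
"no skill" checks are one-sided.

**Accuracy ceiling without LD.** With m independent markers the expected
predictive ability is approximately
r ≈ sqrt(h² · nh²/(nh² + Mₑ)) with Mₑ = m effective segments. At n = 500
(fourfold CV → 375 training), m = 2,000, h² = 0.7 this gives r ≈ 0.30,
which the package reproduces (REML-estimated λ matches the best fixed λ on
a grid, and the value is invariant to QTL count). Published predictive
abilities above 0.5 on real rice panels arise because dense LD makes
~10⁵ markers act like a few hundred effective segments; the v1 generator
deliberately simulates linkage-free markers (see Limitations), so its
absolute r values sit at this ceiling and should be read as such.

**CNN.** A minimal 1D convolutional regressor in NumPy: convolution over
the marker axis (16 filters, kernel 20, stride 5) → min/mean/max pooling
(window 2) → dropout 0.2 → dense 64 → ReLU → batch normalization → linear
output; Adam (lr 10⁻², batch 8), MSE loss, early stopping on a 20%
validation split with patience 10 and best-weight restore. Inputs and
response are standardized internally; all randomness (init, batches,
dropout, split) flows from one seed, so training is bit-reproducible. The
defaults are modest deliberately: on linear traits the CNN tracks rrBLUP to
within ~0.1–0.15 in cross-validated r but does not beat it, and seed-to-seed
variation of a single small net is noticeable. A NaN loss raises
immediately with the epoch and learning rate.

## Synthetic data generator

The generator emulates the inputs of a rice array study, not rice biology:

- **Genome/genes**: uniform-random sequence; evenly-slotted, jittered,
  non-overlapping gene models with a fixed internal layout (5′UTR 100 bp,
  exon 300 bp, intron 300 bp, exon, 3′UTR 100 bp), requiring
  gene length ≥ 900 bp.
- **Cohort**: variant positions uniform without replacement; alternate
  allele frequency p ~ Uniform(0.05, 0.5); genotypes drawn independently
  per sample with heterozygote probability 2p(1−p)(1−F). The default
  F = 0.95 mimics a strongly selfing rice panel and makes the het-poor
  cluster geometry (NoMinorHom/Mono categories) common, as in real inbred
  material. Missing calls are masked independently (default 2%).
- **Intensities**: genotype clusters at contrast ±1 (homs) and 0 (het,
  with a +0.2 size lift), Gaussian with SDs 0.15/0.1 around a size baseline
  of 1.0 — a ≥ 5σ separation, i.e. a *clean* assay; an OTV fraction is
  re-drawn at het contrast with size shifted −0.5. Channels are recovered
  as a = 2^(size + contrast/2), b = 2^(size − contrast/2), so the QC
  transform inverts the construction exactly.
- **Traits**: QTL drawn without replacement, standard-normal effects,
  residual variance scaled so var(g)/var(y) equals the target h² exactly in
  expectation (h² = 1 gives y = g; h² = 0 gives pure noise).

Every generator is a pure function of (config, seed): reruns are
bit-identical, and generated FASTA/GFF3/VCF round-trip through the package
readers.

**What passing tests do and do not show.** Samples are unrelated
(no families or subpopulations), markers carry no LD, intensities have no
batch or plate effects, and traits are strictly additive. Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions — calibrated type-I error, unbiased variance components, correct
rule-table logic — not that real-data performance numbers (e.g. absolute GS
predictive ability) will be matched; those depend on LD and relatedness the
generator omits by design.

## Numerical choices and degenerate inputs

- Variance-ratio search bounded to δ ∈ [10⁻⁶, 10⁸]; eigenvalues clipped at
  zero; kinship PSD tolerance 10⁻⁶ relative.
- Zero-variance phenotype in rrBLUP → u = 0, μ = y with a warning; fold
  with fewer than 3 samples → error; marker mismatch on prediction names
  the missing markers.
- Gaussian mixture uses reg_covar 10⁻⁶ and 3 initializations with a fixed
  random state; zero-spread contrast input short-circuits to a single fully
  confident cluster.
- FLD with zero pooled SD is +∞ by convention; HetSO is undefined when the
  two hom contrasts coincide.
- Tiling windows are 1-anchored half-open in index arithmetic
  ((pos−1) div window), matching the 1-based closed coordinate convention.

## Known limitations

- No LD or pedigree structure in the generator (the main realism gap; see
  the accuracy-ceiling discussion above).
- The convertibility surrogate ranks probes sensibly but is not the
  platform's score; absolute thresholds applied to surrogate scores should
  not be compared with vendor score distributions.
- The genotype caller is a BIC-selected Gaussian mixture, not the
  platform's Bayesian caller with priors; it needs tens of samples per
  marker to be reliable.
- The CNN is a didactic reference implementation; it is CPU-bound NumPy
  and not intended for 10⁵-marker panels.
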