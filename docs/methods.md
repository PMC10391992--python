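# Methods

`meqtlkit` implements a two-stage methylation-QTL (meQTL) discovery
pipeline for multi-cohort array methylation studies, together with the
integration analyses that typically follow: twin-based heritability,
LD clumping and connectivity, annotation enrichment, and summary-based
Mendelian randomisation (SMR) against eQTL or GWAS summary statistics.
This note records the models, the defaults and why they were chosen, and
what the bundled synthetic-data generator does and does not emulate.

## Data preparation

**Genotype QC.** SNPs are dropped at folded MAF < 0.01 (strict), exact
Hardy–Weinberg p < 1e-6, or missingness > 3%; samples at missingness
> 5%. Samples are filtered first and SNP statistics recomputed — the
order matters for borderline SNPs and is fixed here because common
tooling is ambiguous about it. The HWE test is the exact conditional
test: given the allele counts, the probability of each admissible
heterozygote count is proportional to `2^h · n!/(h! n_AA! n_aa!)`, and
the p-value sums the probabilities not exceeding that of the observed
count.

**Methylation adjustment.** Beta-values (bounded in [0, 1]) are first
mapped to normal scores by a rank-based inverse normal transformation,
`y = Φ⁻¹((r − c)/(n − 2c + 1))` with the Blom offset c = 3/8 and average
ranks for ties. The offset choice is conventional, not consequential:
any c in [0, 1/2] gives the same ranks-to-quantiles monotone map up to
small tail differences. Residualization then removes fixed covariates
(sex, age, smoking, cell proportions) and technical factors (plate, chip
position). The default treats technical factors as categorical fixed
effects — deterministic, exactly reproducible, and conservative (it
removes all between-level variance). An optional random-intercept mode
estimates one-way variance components by method of moments and shrinks
level means by the BLUP factor `σ_b²/(σ_b² + σ_e²/n_g)`; it matters
mainly when levels are tiny (a level of size one is fully absorbed by
the fixed-effect mode but only partially by shrinkage). Family and
zygosity are deliberately *not* removed: the twin covariance is the
signal for the ACE model, and the family structure is what the
permutation scheme preserves.

## Two-stage association scan

Stage one fits, per cohort, a simple linear regression of residualized
methylation on alternative-allele dose for every SNP–CpG pair. Pairs
within 1 Mbp on the same chromosome are *cis* (inclusive boundary:
exactly 1,000,000 bp is cis), all others *trans*. Candidates are kept at
p ≤ 5e-3 (cis) and p ≤ 5e-6 (trans), two-sided t with n − 2 degrees of
freedom. Sporadic missing dosages are mean-imputed inside the scan only.
Scans stream CpG blocks; the output is provably independent of block
size (tested). p-values are floored at 1e-300 so noiseless fits do not
underflow to zero.

Stage two pools each candidate pair across the cohorts that retained it
with DerSimonian–Laird random-effects inverse-variance weighting:
fixed weights `w = 1/se²` give `Q = Σw(b − b_fixed)²` and
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`; random weights
`w* = 1/(se² + τ²)` produce the pooled estimate and its normal-reference
p-value. Random effects absorb between-cohort heterogeneity from
differing sample sizes and batches. Pairs must additionally be
candidates in ≥ 2 cohorts with the same direction of effect everywhere.

**Permutation FDR.** Sample labels of the methylation matrix are
shuffled per cohort with families moved as blocks (whole families are
reassigned among family-slots of equal size; singleton-only cohorts
reduce to a full shuffle), genotypes untouched. The *identical*
scan + meta + consistency pipeline runs on each of B = 20 permuted
datasets, so observed and null candidate p-values are exchangeable.
`FDR(t) = mean_b #{p_null ≤ t} / #{p_obs ≤ t}` is evaluated on the grid
of observed p-values, separately for cis and trans, and the selected
threshold is the largest t with FDR(t) ≤ 0.05. B is a flag; 20 keeps the
null-to-observed ratio stable because each permutation contributes an
entire genome-wide scan.

**Cell-specific scan.** The interaction scan fits
`meth ~ G + prop + G×prop` over cis pairs, on methylation adjusted
*without* the focal cell proportion, and retains interaction terms at
p ≤ 5e-3 (t with n − 4 df).

## Twin ACE heritability

Per CpG, MZ and DZ pair values are bivariate normal with common mean,
variance a² + c² + e², cov_MZ = a² + c² and cov_DZ = a²/2 + c².
The likelihood is maximised by L-BFGS-B on (a², c², e², μ) with variance
components bounded at zero (e² floored at 1e-6 to keep the pair
covariance positive definite), from two starts: the Falconer plug-in
(A = 2(r_MZ − r_DZ), C = r_MZ − A, clipped and renormalised) and equal
thirds. Values are standardized before fitting, so shares are invariant
to affine rescaling. Non-finite likelihood after both starts marks the
CpG as failed (shares missing) rather than forcing a value. Summaries
report the zero-inflation rate (share of CpGs with A < 0.01),
annotation-stratified means with 95% CIs, and a variability stratum at
raw beta-value sd > 0.025. The integration regression fits A on
has-cis/has-trans indicators by OLS and reports R², F and the four group
means (none / cis-only / trans-only / both).

## Clumping and connectivity

LD is the squared Pearson correlation of dosages over the pooled
samples of all cohorts. Clumping is greedy: SNPs sorted by
associated-CpG count (ties by best association p, then position); the
top unclumped SNP becomes representative and absorbs unclumped SNPs on
its chromosome within ±2 Mbp with r² > 0.1; repeat. The ± window
reading, and the count/p/position tie-break, are this package's fixed
interpretation of an otherwise underdetermined rule; regions partition
the SNP set by construction. Per CpG the effective meQTL count is the
number of distinct regions containing an associated SNP (most
significant SNP per region recorded); per region, the number of distinct
associated CpGs. Outliers ("highly regulated" CpGs, "key regulatory"
regions) are counts strictly above Q3 + 3·IQR with linear-interpolation
(type-7) quantiles — the flag is sensitive to the quantile convention,
which is why it is pinned here.

## Enrichment

Annotation tracks are BED (0-based half-open); points are 1-based, so
position p is inside [start, end) iff start ≤ p − 1 < end. The Fisher
test is two-tailed by the point-probability convention (sum of
hypergeometric probabilities ≤ that of the observed table); odds ratios
use Haldane–Anscombe +0.5 on all cells when any cell is zero, with the
Woolf logit CI in exact mode. Matched backgrounds resample the universe
within joint MAF × distance-to-nearest-CpG categories (MAF bin width
0.05; distance bins 0–1 kb, 1–10 kb, 10–100 kb, 100 kb–1 Mb, > 1 Mb) —
without replacement within a category, with replacement across
categories — B = 1000 times; the point estimate is the mean OR and the
CI the 2.5/97.5 percentiles of the resampled ORs. The MHC region
(chr6:28,477,797–33,448,354, GRCh37) ships as a named constant because
its extreme LD warrants routine sensitivity exclusion. TAD co-membership
counts a pair as shared only when both points fall in the *same*
interval; abutting TADs are kept distinct (merging only repairs true
overlaps), and TAD sizes of cis- vs trans-containing pairs are compared
by Welch's t-test.

## SMR and HEIDI

With exposure (meQTL) effect b_zx and outcome (eQTL/GWAS) effect b_zy
at the exposure's most significant SNP, the ratio estimate is
b_xy = b_zy/b_zx with delta-method variance
`se_zy²/b_zx² + b_zy²·se_zx²/b_zx⁴` and `T = b_xy²/var ~ χ²₁`.
Harmonisation aligns outcome alleles to the exposure coding (sign flip
on swap), drops strand-ambiguous A/T and C/G SNPs and allele or
frequency (> 0.2) mismatches. HEIDI tests homogeneity of the ratio
across up to twenty alternative SNPs (exposure p < 1.57e-3, 0.05 < r²
with the top SNP < 0.9 — the conventional defaults of the reference SMR
implementation, exposed as flags); deviations d_i = b_xy(i) − b_xy(top)
get a delta-method covariance with cov(b_i, b_j) ≈ r_ij·se_i·se_j per
trait, and T = Σ z_i² is referred to a Satterthwaite-scaled chi-square
from the eigenvalues of the d-correlation matrix. Fewer than three
eligible alternatives leaves p_HEIDI missing. A colocalisation is
reported when p_SMR passes the design's Bonferroni cutoff *and*
p_HEIDI > 0.05. Designs: cis (CpG–gene pairs), trans, targeted trans
(instrument SNPs within 5 Mbp of the CpG excluded, guarding long-range
LD), and GWAS (Bonferroni denominator = CpGs × phenotype classes).

Measured behaviour (recomputed by the test suite): under a
single-shared-causal-variant generator the HEIDI rejection rate at
α = 0.05 is ~0.05; under two causal variants in LD (r ≈ 0.5) it rejects
essentially always; the ratio estimate is unbiased to < 0.02 for
instruments with F > 30.

## The synthetic-data generator

The generator emulates a five-cohort blood-methylation study: unequal
cohorts with MZ/DZ twin pairs only in the first (a twin-registry
analogue; the rest are birth-cohort-like singleton sets), genotypes from
a latent-Gaussian AR(1) threshold model (haplotype allele j is carried
iff an AR(1) Gaussian with parameter `ld_rho` falls below Φ⁻¹ of the
allele frequency; blocks of `ld_block_size` SNPs are independent), MZ
twins sharing both haplotypes, DZ twins sharing each parental
transmission with probability 1/2. Methylation is built on a latent
scale — planted SNP effects + polygenic component (correlation 1 MZ,
0.5 DZ) scaled to A + family-shared C + independent E + cell/smoking/
age/batch covariate effects — and pushed through a logistic link with a
per-CpG baseline offset, so emitted beta-values live strictly in (0, 1)
and cross-twin latent correlations are exactly A + C (MZ) and A/2 + C
(DZ). Planted betas are defined pre-link; the link plus INT attenuates
them, so recovery tests are rank-based (detection, not effect-size
equality). Effects are either N(0, sd²) or calibrated to a fixed latent
variance explained (`effect_r2`) with random sign. Summary statistics
for SMR come from a separate region simulator: marginal effects are
r(j, causal)·b_causal under an AR(1) LD matrix, standard errors 1/√n,
noise drawn with the LD correlation — one shared causal SNP
(pleiotropy) or two causal SNPs in LD (linkage).

Not emulated: probe chemistry and detection p-values (QC consumes an
external mask list), genotype imputation quality, fine-scale recombination
(LD is blockwise AR(1), so long-range LD and MAF–LD coupling are absent),
realistic effect-size distributions (unknown for real meQTLs; defaults
are free parameters), and cell-type deconvolution (proportions are
generated, not estimated). Passing tests therefore demonstrate
correctness of the statistical machinery and calibration under the
stated model, not performance on array data with probe artefacts.

A single integer seed fans out to per-stage child streams via
`numpy.random.SeedSequence`, so every stage is independently
reproducible and two identical runs agree bit-for-bit.

## Problem sizes

The reference synthetic study is 5 cohorts × 150 samples, 300 SNPs ×
400 CpGs in LD blocks of 10 at ρ = 0.8, with 60 planted cis effects of
latent R² ≈ 0.15 — large enough that per-cohort scans, the 20-permutation
null, the consistency filter and LD tagging all operate as in a full
study, while a complete replicate (105 genome-wide scans plus
meta-analyses) runs in a few seconds. The realized cis false-discovery
proportion of the full pipeline, averaged over ten seeded replicates,
is reported by `scripts/acceptance.py` and stays well under the 0.05
target (LD tags of planted SNPs, r² > 0.1, count as true). ACE recovery
uses 1000+1000 pairs (asymptotic check, share error < 0.05) and 88+70
pairs (a realistic twin-cohort size, error < 0.15). HEIDI calibration
and power use 500 region replicates per scenario.

## Known limitations

- The per-CpG mixed model is approximated by fixed-effect
  residualization (default) or single-factor random intercepts; crossed
  random effects are not fitted.
- No conditional (multi-SNP) models: the number of independent signals
  per CpG is addressed only through LD clumping.
- HEIDI's delta-method covariance assumes exposure and outcome samples
  are independent and instruments are strong; weak-instrument regions
  should rely on the eligibility p filter.
- The permutation FDR needs at least one family-size class with two or
  more families to move twin cohorts; a degenerate pedigree falls back
  to a logged rotation.
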