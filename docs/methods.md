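# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design being modeled

A paired stimulus-response design: each donor's cells are assayed under a
vehicle condition and one or more stimulated conditions, with chromatin
accessibility (peak counts) and gene expression (gene counts) measured per
sample and a single genotype per donor. Sample sets differ slightly per
assay and condition (dropout), so analyses run on per-assay intersections.
Coordinates follow the standard conventions: intervals are 0-based
half-open (BED), variants 1-based (VCF); a variant at position p overlaps
[s, e) iff s < p ≤ e. The TSS is a single base, strand-aware (interval
start for +, end for −).

## Normalization

Counts are scaled by median-of-ratios size factors (upper-quartile
fallback when no feature is all-positive), transformed as
log2(count/sf + 0.5), and optionally GC-corrected: per sample, features
are binned into 20 GC quantile bins, the bin median of the deviation from
the feature's cross-sample mean forms an offset curve, linearly
interpolated at each feature's GC and subtracted. This shifted-log
transform is a deliberate stand-in for dispersion-based
variance-stabilizing transforms: the downstream models are linear on the
transformed scale and the contract (finite, roughly variance-stable
values) is what matters, not the specific curve. Latent structure is
removed by sample-space PCA (default 10 PCs, capped at n/4 with a warning
for small runs); PCs can alternatively be passed as fixed covariates.
Genotype summaries: exact Hardy–Weinberg test (conditional enumeration,
two-sided by probability mass, stable log-space recurrence), a genomic
relationship kinship matrix K = ZᵀZ/M from standardized dosages, and
ancestry coordinates from K's leading eigenvectors.

## Differential testing

The paired test operates on within-donor differences of normalized
values, so donor effects cancel exactly. Variance moderation fits a
scaled-inverse-χ² prior (d₀, s₀²) across features by method of moments
(from the mean and variance of the per-feature sample variances) and the
moderated t uses df + d₀ degrees of freedom. Effect-size shrinkage is
normal-prior: lfc·σ²_between/(σ²_between + se²) with σ²_between the
across-feature variance of the raw estimates, which guarantees
|shrunk| ≤ |raw|. Features with zero variance and zero mean difference get
p = 1, not NaN. The responsive gate (BH FDR < 0.1 and |LFC| > 0.5) applies
to the shrunken estimate by default, with a flag to use the raw one; BH is
computed within each contrast separately.

## cis-QTL mapping

Filters are computed on the condition's sample subset: MAF ≥ 1%, HWE
exact p ≥ 10⁻⁶, at least two minor-allele carriers, and an
imputation-quality filter (INFO R² ≥ 0.3) honored only when the key exists
— simulated genotypes carry none. Genes additionally require ≥ 10
normalized counts in ≥ 1% of samples. Windows are inclusive at both
boundaries (peak edge ± 25,000 bp; gene body ± 1 Mb).

The scan is OLS of the PC-residualized phenotype on mean-imputed dosage;
when covariates are supplied both sides are projected off them and the
residual degrees of freedom adjusted. Within one condition each donor
contributes one sample, so the donor intercept is exchangeable noise and
OLS is calibrated (verified by KS uniformity on permuted phenotypes).

Local correction, accessibility path: variants ordered by position are
chunked into windows of ≤ 200; each window's correlation matrix
contributes the smallest k eigenvalues summing to 99% of the trace;
p_local = min(1, p_min · m_eff). Constant variants count as one test each.
Expression path: the phenotype is permuted (default 1,000 times,
vectorized in blocks), the empirical p is (1 + #{min-p ≤ obs})/(1 + B),
and a Beta(a, b) fitted to the permutation minimum p-values by method of
moments supplies the reported CDF value — the two paths agree at Spearman
ρ > 0.95 on matched data. Globally, BH over p_local at FDR 0.1 defines the
cutoff p* (largest passing p_local), back-transformed per feature to a
nominal threshold (p*/m_eff, or the inverse Beta CDF), floored at the
feature's own minimum p so a significant feature always flags at least
one variant. Secondary signals: iterative LD pruning at r² < 0.2 with ties
broken by (p ascending, |beta| descending, position ascending), or
conditional re-scans adding each index dosage as a covariate until no
variant passes the feature's nominal threshold. Undefined r² (constant
dosage) is treated as 1 and the offending variant dropped.

## Response QTLs

The interaction model has a per-donor random intercept. For fixed
λ = σ²_donor/σ²_resid the covariance is σ²(I + λJ) blockwise per donor, and
(I + λJ_n)^(−1/2) = I + ((1+nλ)^(−1/2) − 1)·J_n/n, so whitening is two
vector operations per donor; β̂ and the profiled ML log-likelihood are then
closed-form, and λ is optimized by bounded search on log λ ∈ [−10, 10]
(ML, not REML, because the LRT compares fixed-effect structures). Negative
LRT values are clipped to zero. The χ²₁ reference is analytically liberal
in finite samples (level ≈ 0.0545 at n = 140 with four fixed parameters),
so the statistic is divided by the standard Bartlett-type factor
1 + (p+1)/n by default; a flag disables it, and the oracle comparison
against an independent mixed-model implementation uses the uncorrected
statistic. A no-random-effect mode reproduces the plain OLS LRT for
engines that ignore pairing; the default keeps the random intercept for
both assays because paired samples are correlated. Unpaired donors are
retained — the random intercept absorbs the imbalance. Per-condition
effects are reported as β_vehicle and β_vehicle + β_interaction.

Sharing across conditions is the per-feature set of conditions with ≥ 1
significant QTL, summarized by the stimulated-only increment:
(features significant under some stimulus but not vehicle) / (vehicle
features) × 100%.

## Priming classification

Candidate pairs are caPeaks within 1 Mb of an eGene TSS. The LD link
requires one significant SNP from each assay with r² ≥ 0.8; "significant"
means any variant below the feature's back-calculated nominal threshold
(index SNPs only, by flag). Labels: primed (caPeak significant in both
conditions, eGene stimulated-only), stimulus_specific (both
stimulated-only), shared (both in both), otherwise unlinked. Each
peak–gene pair is classified independently and receives exactly one label.

## Enrichment

The motif model is a per-motif logistic regression of binding-site
presence on peak class, peak width and conserved-base fraction (the two
covariates standardized), fitted by Newton/IRLS; complete separation or
non-convergence falls back to a Firth-penalized score
(U* = Xᵀ(y − p + h(½ − p)) with h the hat diagonal) and is flagged.
Motif scanning of sequence is out of scope: the motif table is an input
that the generator produces directly. Top-peak selection ranks
gate-passing peaks by |shrunken LFC| per direction (default 2,000) to
balance class sizes. Interval-overlap enrichment counts query peaks
touching ≥ 1 annotation interval (any-bp, half-open arithmetic; split
annotations are merged first, making the statistic invariant to
splitting), against the background overlap proportion, with a one-sided
exact binomial p; differences between two enrichments use the two-sided
Fisher exact test. The positional comparison of response vs non-response
eQTLs uses absolute variant-to-TSS distances and a two-sided Wilcoxon
rank-sum test (a design choice — distribution comparison is all that is
required), omitted below 3 per group.

## Colocalization

Candidates: GWAS SNPs at p < 5×10⁻⁸ within 1 Mb (inclusive) of a QTL
index, kept when index–index r² > 0.6 or any genome-wide SNP at the locus
has r² > 0.6 with the QTL index. Route 1, approximate conditional
analysis: with D = diag(2f(1−f)n) and B the LD-scaled cross-product from a
reference panel, the conditional effect of target t given set C is
b_t − B_tC B_CC⁻¹ b_C with variance σ²/(B_tt − B_tC B_CC⁻¹ B_tC), σ²
estimated as the median of D_jj·se_j². Variants whose sumstats frequency
differs from the reference by > 0.2 are excluded; targets with r² > 0.9 to
a conditioning SNP are masked. The route passes when every genome-wide
SNP's conditional p exceeds 10⁻⁴ (configurable) after conditioning on the
QTL index. Route 2, single-causal-variant colocalization: per study,
Wakefield ABFs (prior sd 0.15 on the standardized scale, configurable)
are normalized to causal posteriors over SNPs at p < 0.05 in both studies,
and CLPP_j is the per-SNP product; the route passes when max CLPP > 1% and
that SNP has r² > 0.8 to a genome-wide-significant SNP. The verdict is the
disjunction. A salvage pass re-runs the CLPP route in conditions where a
feature that colocalized elsewhere missed the QTL FDR gate but had best
nominal p < 10⁻⁶, flagging results as salvage. The single-causal
posterior replaces multi-causal enumeration deliberately: it is
closed-form at desk scale and preserves the verdict thresholds exactly.

## The synthetic-data generator

Defaults encode the emulated study: 80 donors × 3 conditions with 5%
per-condition/assay sample dropout, ~3,000 biallelic variants at 800 bp
spacing in 20-variant LD blocks, 300 peaks (width 200–2,000 bp, GC
0.3–0.7), 150 genes, NB counts with size 10, donor intercept sd 0.3
(natural log), log-normal library sizes (sd 0.3) and per-sample GC slopes
(sd 0.3). All randomness flows from one master seed; each stage draws from
an independent child stream keyed by (stage, seed), so stages re-run in
isolation and datasets are byte-reproducible.

Genotypes: one target frequency per LD block (uniform on the MAF range);
within a block each variant copies the previous variant's allele per
haplotype with probability 0.9, else draws fresh — this preserves every
variant's marginal frequency exactly (HWE holds by construction) while
correlation decays as 0.9^distance. Counts:
count ~ NB(exp(logL_s + slope_s(GC_j − mean) + a_j + u_d + ln2·LFC_jc +
β_jc x_d), size), with a hard error if the log-mean exceeds 30. Scenario
wiring pairs one peak with one gene (TSS within 1 Mb, causal variant
inside peak ± 25 kb) and sets per-condition allelic effects: shared
(both assays, all conditions), primed (peak always, gene stimulated-only),
stimulus_specific (both stimulated-only), response_magnitude (effect
enlarged under stimulus). Gene effects are mediation_gamma times the
peak's per-condition effect at the same causal variant, applied to the
genotype contribution of the mean — a deterministic mediation that makes
eQTLs peak-mediated at the effect level without propagating the peak's
sampling noise. Unwired "marginal" QTLs and condition LFCs are planted on
separate features.

Effect sizes can be specified directly (natural-log β) or as a variance
fraction: with `qtl_var_frac` set, β is calibrated per feature so the
genetic term explains that fraction of the predicted within-condition
log-count variance, donor_sd² + 1/size + 1/mean (delta method). Because
size-factor normalization absorbs the donor intercept (it shifts all
features of a sample equally), realized fractions on the scanned
phenotype run somewhat above nominal; the calibration is fixed and
documented rather than tuned.

The GWAS cohort (default 20,000 individuals) is drawn from the same LD
process; loci alternately reuse a QTL causal variant ("shared") or a
low-LD (r² < 0.1) neighbor ("distinct"), trait = Σ effects + N(0,1), and
marginal regressions give the summary statistics. A locus-level variant of
this (`simulate_coloc_locus`) drives the colocalization benchmarks with
explicitly well-powered settings (QTL h² = 0.25 at n = 80, GWAS h² = 0.005
per locus), at which both discrimination rates are saturated.

What the generator does **not** emulate: allele-specific reads, read-level
artifacts (mappability, duplicates), multi-ancestry structure (a
two-population mode exists only implicitly via the config and is off),
polygenic GWAS background, dispersion heterogeneity across features, and
sequence-level motif/conservation content (motif presence is drawn from
the planted logistic model directly). Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery on data
satisfying the model's assumptions, not robustness to real-data artifacts.

## Known limitations

The hierarchical correction buys FDR control at a real power cost: a
feature is discovered only if its best nominal p survives both the
within-feature penalty (m_eff ≈ 36 for a ±25 kb window at 800 bp spacing;
effectively several hundred for ±1 Mb expression windows) and the global
BH cutoff. At n ≈ 80 this puts the detection boundary near 15–20%
variance explained for accessibility and higher for expression. Benchmark
sensitivities at 8% variance (~0.1) and unconditional priming recalls at
15% variance (~0.05–0.2) reflect this boundary honestly; the priming
classifier itself is exact on constructed cases and conditionally on
detected QTL patterns. Mislabeling of shared pairs as primed is driven by
vehicle-condition eQTL misses and is therefore also a power statement.
Other numerical choices: p-values are floored at the smallest positive
float rather than 0; BH families are kept separate per contrast, assay and
condition pair; the exact HWE p-value distribution is discrete and
conservative by construction, so its calibration is verified at the
rejection tails rather than by a uniformity statistic.

## Benchmark problem sizes

The reproduction script uses 1,000 interaction tests (70 donors), 8
replicates of the 400-peak FDR benchmark (n = 76), 40 features × 5,000
permutations for the concordance check, 200 effect-recovery QTLs (n = 80),
150 priming pairs (n = 80, 300 permutations), 30 motif replicates plus
3 × 200 null motifs, 60 + 60 colocalization loci and one 2,000-feature
differential run — about a minute of compute, chosen as the smallest sizes
at which the measured rates are stable to a few percent.
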