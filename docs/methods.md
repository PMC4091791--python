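# Methods

## Model and procedure

The pipeline treats gene expression as a quantitative trait measured on
probes and genotype as a per-sample additive dosage: the expected
alternate-allele count in [0, 2] for SNPs, or a (possibly continuous)
copy-number dose for CNVs. Both variant classes flow through identical
rank-based statistics; nothing downstream distinguishes them except the
CNV-specific trans filters. Coordinates are 1-based and windows closed on
both ends; all distances are |variant position − TSS|.

### Association and p-values

Association is Spearman rank correlation with average ranks for ties
(ties are ubiquitous in hard-called dosages), so ρ is the Pearson
correlation of mid-ranks. The two-sided p-value uses the t approximation
t = ρ·√((n−2)/(1−ρ²)) with n−2 degrees of freedom. −log10 p is computed
in log space; beyond the range where `scipy`'s `t.logsf` underflows
(|t| ≳ 40) a small-x series of the regularized incomplete beta takes
over, keeping the statistic exact to ~13 digits arbitrarily deep in the
tail. |ρ| = 1 is reported as the smallest positive normal float rather
than zero. At n = 7 the approximation agrees with the exhaustive
permutation distribution to within ~9% (mid-p convention) except for
|ρ| > 0.8, where all permutation p-values are below 0.01 anyway.

### Scan geometry

* cis: variants on the probe's chromosome with |pos − TSS| ≤ 1 Mb
  (a 2 Mb window). Probes whose sequence contains a common SNP are
  excluded (hybridization artifacts masquerade as cis signal).
* trans: variants on another chromosome or with |pos − TSS| > 5 Mb.
  Multi-mapping probes are excluded. The 1–5 Mb band on the same
  chromosome is deliberately tested by neither scan: it is too far to be
  confidently regulatory-proximal and too near to rule out LD with the
  proximal region.

### Permutation FDR

Cis significance is gene-based: each permutation round draws one shared
sample-label permutation (preserving inter-probe correlation), re-runs
the scan, and records each probe's minimum p. At rank r the per-probe
threshold is its r-th smallest null minimum; expected false discoveries
are G·r/(n_perm + 1) over G tested probes (the +1 avoids a degenerate
zero threshold at r = 0), and the selected rank is the largest with
estimated FDR ≤ target. Trans significance pools per-probe genome-wide
minima across probes and permutations into a single reference
distribution — justified because every probe faces approximately the
same number of tests and the rank statistic is outlier-robust — and
sweeps its values as genome-wide thresholds the same way. For the
trans-of-cis stage (trans effects of the variants already called as
cis-eQTLs) every eligible probe is permuted rather than a subsample.

CNV trans associations are discarded when (a) the probe sits on the
CNV's own chromosome, (b) the probe's chromosome harbors a SNP with
dosage r² > 0.1 with the CNV (the CNV may be mismapped or tagging that
locus), or (c) the CNV's dosage differs by sex (two-sided rank-sum test,
Bonferroni level 0.05/n_CNVs by default), since a sex-imbalanced CNV
correlates spuriously with every sex-differential probe.

### Conditional regression and heritability

For each discovered gene, expression is standard-normalized
(rank-based inverse normal, Φ⁻¹((rank − 0.5)/n), average ranks for
ties), regressed jointly on all accepted dosages, and the residuals
re-scanned over the cis window; the best variant is accepted while its p
stays below the gene's primary permutation threshold, reused verbatim
(no re-permutation of residuals). The primary variant is accepted
unconditionally — the scan is only run for genes that already passed FDR
control. Joint (rather than sequential) residualization avoids
order-dependent drift; candidates with r² > 0.999 against the accepted
set are skipped with a warning. Heritability explained is
min(r²/h², 1), with h² an externally supplied per-probe estimate (the
synthetic truth provides it in tests); r² > h² is possible because the
two quantities come from different estimators, hence the cap.

### π1 sharing and replication

Storey's π1 = 1 − π0 estimates the alternative fraction in a p-value
collection: π0(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05…0.95, smoothed by a
natural cubic smoothing spline with effective df = 3 (the penalty is
bisected on the fixed grid to hit that df, matching the reference
estimator's heavily smoothed fit) and evaluated at λ = 0.95, clamped to
[0, 1]. An interpolating spline would reduce to the raw π0(0.95) value,
whose sampling noise (sd ≈ 0.035 at m = 10⁴) defeats the purpose of the
grid. Even so, single-draw noise is material; accuracy experiments
therefore average over replicate draws. Replication of an association
list in a second cohort counts pairs with p < α and concordant ρ sign;
sharing-versus-sample-size curves subsample the replication cohort with
5%/95% quantile bands across draws. A variant's trans load is the π1 of
its p-values against all eligible trans probes.

### Matched-variant enrichment

Overlap between a target variant set and significant eQTLs is judged
against matched nulls: each permutation draws, per target, a uniform
pool variant with MAF within ±1% and distance-to-closest-gene within
±2 kb (without replacement within a set, independently across
permutations); the empirical p is (1 + #{null ≥ observed})/(n_perm + 1).
Overlap means the variant itself is significant; LD-aware co-localization
is out of scope.

### Causal triplets

Three DAGs anchored at the genotype (which expression cannot cause) are
scored: SCT G→C→T, STC G→T→C, INDEP C←G→T. Each network's ln L is the
sum of Gaussian node terms — the root ln N(G) (identical across models,
kept so likelihoods share a variable set) plus linear-Gaussian child
terms with ML variance RSS/n — and AIC = 2k − 2 ln L with k = 5 for all
models, so AIC ranking equals likelihood ranking; a call requires the
best model to be ≥10× more likely than the runner-up
(exp(ΔAIC/2) ≤ 0.1). Genotype is modeled as a continuous Gaussian node;
since the term cancels across models, a multinomial root would change no
ranking.

The CIT tests, per mediation direction (mediator M, outcome O): p1, G
associated with O; p2, G associated with M given O; p3, M associated
with O given G; p4, an equivalence component supporting G ⊥ O | M. p4
refers the observed conditional F of G (in O ~ G + M) to a noncentral F
whose noncentrality is method-of-moments-estimated from B replicates in
which M is permuted within rounded-dosage strata of G — preserving the
G–O and G–M marginals while severing mediation — so small p4 means the
conditional association is significantly weaker than a direct effect of
the observed marginal strength would produce. The omnibus p is the max
of the four components; calling uses a Bonferroni level
α/n_triplets: SCT if only the C-direction is significant, STC if only
the T-direction, INDEP if neither, no call if both. The consensus is the
shared verdict of BN and CIT, else none.

"Variance of the trans association explained by the cis gene" is
1 − (β_G|C/β_G)², clamped to [0, 1], where β_G is the coefficient of G
in T ~ G and β_G|C in T ~ G + C. The coefficient-attenuation form is
used deliberately: residualizing T on C *unconditionally* strips part of
the G signal even when C and T are independent given G (for
equal-strength pleiotropy it would report 1/3 instead of ~0), whereas
the conditional coefficient is untouched exactly when C carries no
information about T beyond G.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* several hundred unrelated samples (defaults: 400 for calibration
  scenarios, 800 for power scenarios, matching the regime of
  cohort-scale expression studies);
* biallelic SNPs in Hardy–Weinberg proportions with MAF uniform in
  (0.05, 0.5), grouped in LD blocks via a shared latent haplotype pair
  (pairwise r² = target within a block, no decay — sufficient to
  exercise LD filters and conditional regression);
* CNVs as integer copy numbers 2 + Binomial(2, f), optionally with a
  different duplication frequency per sex;
* expression as a sum of scaled standardized dosages (variance-explained
  targets), an unlinked polygenic score topping variance up to h², and
  Gaussian noise; mediated (SCT), reverse-causal (STC) and pleiotropic
  (INDEP) triplets built from those pieces; designated probes get a mean
  shift by sex. Genes are spaced 12 Mb apart so cis windows are disjoint
  and unambiguous.

Gaussian noise is a deliberate choice: downstream inference is
rank-based or runs on standard-normalized values, so the marginal family
is immaterial, while Gaussianity makes the variance budget exact in
expectation. Everything is a pure function of (config, seed).

What the generator does **not** emulate — and what passing tests
therefore cannot certify on real data: population structure and
relatedness, imputation uncertainty, LD decay within blocks and any LD
between blocks, probe-level hybridization artifacts beyond the two QC
flags, batch effects, and non-Gaussian expression error families.

Scenario presets (`make_scenario`): `null` (500 noise genes, 2000 SNPs,
n = 400), `cis_only` (100 genes at r² = 0.1 plus 50 noise genes,
n = 800), `multi_cis` (50 genes with two independent r² = 0.1 variants),
`mediation` (12 triplets per model at genetic/mediated variance 0.2),
`sex_cnv_confound` (5 sex-imbalanced and 5 balanced CNVs plus 30
sex-differential probes). Effect sizes sit in the range reported for
array-based cis-eQTLs (a strong cis signal explains 10–20% of expression
variance; trans and mediated effects are weaker).

## Numerical choices and edge cases

* Quantile normalization ties receive the mean of the reference
  quantiles they span; replicate averaging can create rank-crossing
  ties, after which "identical sorted values" holds only up to those
  averaged entries.
* The PCA outlier rule (exclude |PC_k − mean| > s·sd for k ≤ 2) defaults
  to s = 1, which under approximate Gaussianity excludes a large sample
  fraction; the implementation warns at s ≤ 1 and exposes the
  multiplier.
* `standard_normalize` rejects constant vectors; Spearman tests reject
  constant inputs and n < 4.
* FDR selection returns rank 0 / threshold 0 and an empty discovery set
  when no rank or threshold meets the target; the trans threshold is
  always an element of the pooled null.
* Degenerate BN fits (residual variance ≤ 1e−12 of the child's variance,
  e.g. T an exact copy of C) raise instead of returning ±∞ likelihoods.
* Bisection tie-breaks: scans take the first minimum; conditional
  regression takes the largest |ρ| not collinear with the accepted set.

## Problem sizes in tests

The test suite runs its experiments at deliberately modest sizes chosen
to keep each statistical check well-powered but quick: FDR calibration
on 20 null cohorts of 500 probes × 2000 variants at n = 400 with 200
permutations; causal recovery on 30 planted triplets at n = 800 with
B = 500 CIT permutations; conditional recovery over 100 seeded cohorts;
π1 accuracy as the mean over 10 draws of m = 10⁴ (single-draw noise in
even the reference estimator exceeds the accuracy bands). The full suite
completes in about a minute on one core.

## Known limitations

* The per-gene permutation threshold is reused for conditional rounds
  rather than re-derived on residuals; with many accepted variants this
  is slightly anti-conservative.
* The pooled trans null assumes comparable test counts per probe; very
  uneven variant coverage would bias the genome-wide threshold.
* CNV "MAF" (pooled non-modal rounded copy-class frequency) is a
  convention; other definitions shift which CNVs pass a MAF filter.
* The CIT p4 reference is a permutation construction; its calibration is
  established empirically (null and specificity experiments) rather than
  by a closed-form distribution.
* No covariate adjustment, interaction models, phased haplotypes, or
  LD-aware co-localization.
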