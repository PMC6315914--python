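# Methods

This note documents the models and estimators implemented in
`ghostalleles`, the defaults and why they were chosen, the numerical
choices that affect results, and what the synthetic-data experiments do
and do not demonstrate.

## Data model

Genotypes are diploid ALT-allele dosages in {0, 1, 2} over biallelic SNP
sites, with a missing state for no-calls; half-calls (`./0`) and `./.`
are both treated as missing, and phase separators are ignored
(`0|1` → dosage 1). "Allele" in all sharing analyses means a specific
allele (REF or ALT) at a site, never a dosage. Samples are partitioned by
a population map into named reference groups and *focal* individuals;
focal individuals are analysed one at a time and are never pooled into a
reference group, so they can never veto an allele's privateness.
Coordinates are 1-based (VCF convention) internally; GFF3 (1-based
closed) and BED (0-based half-open) gene-model intervals are converted at
the reader boundary.

## Site filters

1. **Missingness**: a site is kept when its missing-call fraction is
   ≤ `max_missing` (default 0.10, inclusive at the boundary, so exactly
   10% missing passes).
2. **MAF**: minor allele frequency over all non-missing gene copies of
   all analysed samples (reference and focal jointly, mirroring a
   cohort-level plink run) must be ≥ `min_maf` (default 0.01);
   monomorphic sites drop out here. The two rules always apply in this
   order, and the chain is idempotent.
3. **One SNP per RAD locus**: the positionally first SNP per locus tag is
   kept; untagged sites pass through.
4. **LD pruning**: squared composite (dosage) correlation with
   pairwise-complete observations; zero-variance pairs count as r² = 0.
   Rather than literal step-offset sliding windows — which cannot
   guarantee any bound for pairs that straddle every window placement —
   pruning operates on *retained-site distance*: while any pair of
   retained sites on a chromosome separated by fewer than `window`
   (default 50) retained sites has r² > `r2_max` (default 0.5), one
   member of the worst pair is removed, iterated to a fixed point. The
   removed member is the site with more missing calls, ties broken by
   removing the later coordinate. This is deterministic and makes the
   output bound (`verify_ld`) hold by construction; it is close to, but
   not identical with, plink's `--indep-pairwise` (`step` is accepted in
   the interface for compatibility with the familiar 50/5/0.5 triple but
   is not needed by the fixed-point formulation).

## Diversity and differentiation

Per locus, H_O is the heterozygote fraction among non-missing genotypes
and H_E = 2p̂(1−p̂) with no small-sample correction (documented choice:
the plain form is what the estimand 2·E[p(1−p)] under drift predicts, and
comparisons here are within-panel). Group values are means over loci with
at least one called genotype.

Pairwise F_ST is the Weir–Cockerham (1984) two-population estimator:
per-locus variance components a (among populations), b (among
individuals within populations), c (within individuals) computed from
genotyped sample sizes, allele frequencies and observed heterozygote
fractions, combined over loci as Σa / Σ(a+b+c) (ratio of averages).
Loci monomorphic across the pair, or with fewer than two genotyped
individuals in either group, contribute zero components. Small negative
multi-locus estimates are possible and expected for an unbiased
estimator near zero differentiation.

Group comparisons use the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction) on per-locus statistic vectors — the
operation is generic in which statistic is supplied; the pipeline feeds
per-locus H_E — with Benjamini–Hochberg adjustment across pairs and
significance at FDR < 0.05.

## Rarefaction (ADZE-style estimators)

For group k with N_kj copies of allele j among N_k called copies at a
locus, the probability that j appears in a uniform subsample of g copies
is 1 − C(N_k−N_kj, g)/C(N_k, g) (C(a,b) = 0 when a < b). Allelic
richness A_R sums this over alleles; private allelic richness PA_R
weights each term by the probability the allele is simultaneously absent
from g-subsamples of every other analysed group. Reported values are
means over retained loci.

Missing-data tolerance semantics: g must satisfy
g ≤ floor((1 − tolerance)·2n_k) for every analysed group, and a locus
enters the average only if every analysed group has ≥ g called copies
there. This reproduces the practical behaviour of the standard
rarefaction tool's tolerance parameter and is flagged as an
interpretation. Defaults: g = 18 at tolerance 0.10 for panel diversity
(the largest g feasible for 10-sample groups at that tolerance). For
shared richness the default tolerance is 0.15, at which g = 18 is
infeasible for 10-sample groups (floor(0.85·20) = 17), so the sharing
stage defaults g to the largest value feasible for every group rather
than a fixed 18.

Binomial coefficients are computed in log space (`gammaln`) to avoid
overflow; the test oracle recomputes everything by exhaustive subsample
enumeration in exact rational arithmetic for panels of ≤ 12 copies, and
the two agree to 10⁻¹² relative error. At g = N the estimator equals the
observed distinct-allele count exactly. A_R is non-decreasing in g;
PA_R is **not** monotone in general (for alleles present in several
groups the absence factors fall as g grows), which the enumeration
oracle confirms.

## Private-allele sharing

An allele is private to reference group k iff its count is ≥ 1 in k and
0 in every other reference group (non-missing copies only; singletons
count). Per focal individual, analyses survey only the loci at which the
focal is fully genotyped and recompute the private sets over the
surveyed loci — missing focal data therefore shrinks the denominator
rather than masquerading as absence of sharing. S_PA counts surveyed
private alleles the focal carries (dosage implies ≥ 1 copy), with
zygosity from the focal genotype and S_PA% = 100·S_PA/N_PA rounded to
two decimals.

Shared private allelic richness S_PAr conditions the PA_R machinery on
focal carriage: per retained locus (focal genotyped, all groups ≥ g
copies), Σ_a P(a in g-subsample of k) · Π_{k′≠k} P(a absent from
k′-subsample) · 1[a carried by the focal], averaged over retained loci;
the focal is a fixed, unsubsampled unit of two gene copies. The exact
population combinations behind the original tool's "shared" mode are not
recoverable from its documentation; this focal-conditioned construction
is our interpretation and is tested against the same enumeration oracle.

Frequency-binned sharing proportions (propS) use left-open/right-closed
bins (0, 0.1], …, (0.9, 1.0] on the allele's frequency in its owning
group (full sample, no rarefaction). The denominator is per-bin (shared
in bin / private in bin); a per-bin denominator is what makes propS ≈ 1
attainable in sparse high-frequency bins. The published description is
ambiguous between per-bin and global denominators, so a
`global_denominator` flag switches to shared-in-bin / all-private. Bins
with zero private alleles are undefined (NaN), never 0.

Focal-unique alleles are those with count 0 in every reference group and
≥ 1 copy in ≥ 1 focal; the report gives per-focal carriage, homozygous
fraction, and the intersection across focals. Identity-by-state between
two samples is the mean over jointly genotyped loci of 1 − |d₁ − d₂|/2.

## Ancestry

The supervised estimator assumes each of the focal's two gene copies at
locus l descends from reference A with probability q (else B) and then
carries the ALT allele with that reference's frequency, all copies
independent — the same generative model as the synthetic admixture
generator, with no linkage. The dosage likelihood is Binomial(2, m_l),
m_l = q·p_A,l + (1−q)·p_B,l, maximised by EM on per-copy ancestry
responsibilities from the deterministic start q = 0.5; convergence at
|Δq| < 10⁻⁶ or 500 iterations, and the log-likelihood is checked to be
non-decreasing every iteration. Reference frequencies are clamped to
[ε, 1−ε] with ε = 0.001 (a fixed floor rather than a 1/(2n+1)-style one,
for simplicity) so alleles unobserved in one reference — the ghost-allele
case itself — cannot produce infinite log-likelihoods. If the references
are indistinguishable at every usable locus the likelihood is flat and
q̂ = 0.5 is returned with an explicit non-identifiability flag. This
deterministic ML estimator stands in for Bayesian assignment trained on
two reference groups; it is not an MCMC clone, and unsupervised
clustering (ADMIXTURE/STRUCTURE-style K > 2 inference) is out of scope.

PCA mean-imputes missing dosages per site, centres at 2p̂, optionally
scales by sqrt(2p̂(1−p̂)), and takes the SVD; component signs are fixed
by forcing each component's largest-magnitude loading positive, making
scores reproducible.

## Synthetic data: what it emulates, and what it does not

Reference groups drift independently from a shared ancestral frequency
p under the Balding–Nichols model: group frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F), so the drift parameter F maps onto
expected pairwise F_ST ((F₁+F₂)/2 for two groups), and genotypes are
Binomial(2, group frequency). Focal individuals draw each gene copy from
source A with probability q. Missing calls are uniform at random.

The default panel emulates a 62-individual, 4-group canid study:
29 'coyote' (F = 0.010), 10 'gray_wolf' (F = 0.115), 10 'eastern_wolf'
(F = 0.075), 11 'red_wolf' (F = 0.070) — a least-squares-flavoured
placement putting all pairwise F_ST in the observed 0.04–0.14 band with
the coyote group most diverse — plus two focal individuals at q = 0.6
red_wolf × coyote, 7,000 loci and 10% missing calls. Its ancestral
frequency law is the U-shaped Beta(0.5, 0.5): a rare-allele-rich
spectrum is required for reference groups to own private alleles at all
(under a uniform (0.05, 0.95) law the barely drifted coyote group
essentially never loses an allele, leaving the wolf groups with no
private alleles and the sharing analysis degenerate). `SimConfig`
retains Uniform(0.05, 0.95) as its field-level default, which keeps the
1% MAF filter essentially non-binding in small unit fixtures.

Deliberate simplifications: no linkage or ancestry-tract structure (all
statistics here are single-site; gene-copy-level admixture is exactly
the ancestry model's assumption), no ascertainment model for how a real
RAD SNP panel is discovered, no genotyping-error model, and missingness
independent of genotype. Consequently, passing recovery tests shows the
estimators are correct *under their own model assumptions*; it does not
show robustness to linked loci, batch-structured missingness, allele
dropout, or reference misassignment in real data. Empirical quantities
computed from real panels (published diversity tables, F_ST values,
assignment proportions, IBS values) are data-dependent and are not
reproduction targets; the published per-focal private-allele count table
is used only to exercise the percentage rule.

## Experiment sizes

The recovery experiments run at: admixture — 4 true q values, 5,000
loci, two references of 30 at F = 0.1, 20 seeds (mean q̂ within ±0.05 of
truth; EM within 10⁻³ of a 10⁻⁴-step grid-search oracle); F_ST —
F ∈ {0.05, 0.10, 0.15}, two groups of 50, 5,000 loci, 10 seeds (mean
within 20% relative error); ghost-allele planting — a strongly drifted
remnant group (F = 0.30, a bottlenecked relict) among two F = 0.10
groups, 3,000 loci, focals at q ∈ {0, 0.3, 0.6}, 10 seeds (mean S_PA
with the remnant strictly increasing in q, with q = 0 background under
20% of the q = 0.6 signal). These sizes give comfortable Monte-Carlo
margins for the stated tolerances while keeping the full suite fast.

## Known limitations

- The LD pruner is a documented variant of, not a byte-compatible clone
  of, plink's `--indep-pairwise`.
- Rarefaction tolerance semantics and the S_PAr construction are
  interpretations of the reference tool's behaviour (flagged above).
- The supervised ancestry model ignores LD, so its likelihood is a
  composite likelihood on real data; standard errors are not reported.
- propS bins use full-sample owner frequencies; rarefaction is not
  applied inside the binning.
- VCF output is minimal v4.2 with GT only.
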