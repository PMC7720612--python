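# Methods

This note documents the statistical models implemented in `herdstat`, the
choices made where the methods literature leaves room, and what the
synthetic-data validation does and does not demonstrate.

## Genotype containers and quality control

Genotypes are alternate-allele counts {0, 1, 2} with a dedicated missing
sentinel (−1); phased panels store two haplotype rows per animal, and the
haplotype rows always sum to the genotype row. Coordinates are 1-based (VCF
convention); physical distance is |pos_a − pos_b| bp.

QC retains autosomal SNPs only (labels that parse as positive integers) and
applies call-rate thresholds of 0.90 to SNPs and then to animals, with the
animal rate computed on the surviving SNPs. No MAF or HWE filter is applied
at this stage: rare alleles are informative for breed differentiation, and
HWE is not expected to hold in admixed or small populations. The SNP→animal
cycle is repeated to a fixed point, because removing missing-heavy animals
can push a surviving SNP's call rate back below threshold; one pass alone is
not idempotent, and idempotence is the property a QC filter should have.
The cumulative removal counts are reported per category.

Multi-source merging intersects panels on (chromosome, position) and
harmonises alleles to the first panel: identical ref/alt kept, swapped
ref/alt recoded g → 2 − g, anything else dropped and logged. Strand-ambiguous
(A/T, C/G) mismatches are *not* rescued by frequency matching — silent
flipping risks corrupting downstream F-statistics and admixture, so dropping
is the safe default. For PLINK text input, which carries unordered allele
letters, ref is defined as the lexicographically smaller observed allele;
the merge harmonisation makes this convention immaterial.

## GRM and PCA

VanRaden's first method: M ∈ {−1,0,1}, P = 2(p − 0.5), Z = M − P,
GRM = ZZ′/d with d = 2Σp(1−p). Frequencies are always computed from the
analysed panel itself, so GRM rows sum to ~0 by construction (this is
asserted in tests to 1e−8·n). Missing genotypes get centred value 0 —
equivalent to mean imputation — so they contribute to no relationship.
The eigen-solver runs on the explicitly symmetrised matrix; tiny negative
eigenvalues from floating point are clipped to zero when variance fractions
are formed but reported raw. Scores are eigenvector × √eigenvalue.

Relatedness pruning (threshold 0.2 by default) removes, repeatedly, the
animal with the most above-threshold relationships; ties go to the larger
mean off-diagonal relationship, then the lexicographically smaller ID.
Max-degree-first retains the most animals in star-shaped families. Pruning
can be disabled (`relatedness_threshold=None`): in a small closed population
every animal exceeds 0.2 with many others simply because realized kinship in
a population of effective size ~100 is pervasive, and the rule — intended to
drop close relatives from large breed samples — would empty the panel.

## Supervised admixture

Model: g_ij ~ Binomial(2, h_ij), h_ij = Σ_k q_ik f_kj. K equals the number
of reference populations; reference animals have fixed one-hot Q rows.
Fitting is EM block relaxation: a Q-step (the classic EM multiplicative
update per non-reference animal, followed by simplex renormalisation) and an
F-step (expected alt/total allele counts attributed to each ancestral
population over *all* animals, matching supervised semantics in which
admixed animals inform F). Each block step is an EM step on the full
likelihood with the other block fixed, so the log-likelihood trace is
non-decreasing — asserted on every fit. Quasi-Newton acceleration is
deliberately not used: the optimum is the same and plain EM is easier to
verify. Convergence: |Δ log L| < 1e−4 (or 2,000 iterations, reported via a
`converged` flag, never an exception). F is clamped to [1e−6, 1−1e−6];
missing genotype cells contribute to neither step. Q starts uniform at 1/K,
F at the reference-panel frequencies.

A frozen-F mode keeps F at the reference-only frequencies. Each animal's Q
problem is then a concave maximisation over the simplex, which lets a
0.001-step grid search act as an independent oracle for K=2 — the EM answer
agrees to < 0.002 in the validation suite.

Reference pooling (`pool_reference`) samples a fixed number of animals per
source breed (default 8) without replacement into one pooled ancestral
population, the standard device when several reference breeds are nearly
indistinguishable in PCA; undersized breeds contribute all animals with a
warning.

## F-statistics

Pairwise F_ST uses the Weir–Cockerham (1984) genotype-level estimator for
r = 2 populations with observed heterozygote frequencies h̄, combined across
loci as a ratio of sums θ̂ = Σa / Σ(a+b+c) — the estimator's standard
multi-locus form, which is not the average of per-locus ratios. Per-locus
sample sizes count the non-missing genotypes in each population. Loci
monomorphic across the pair are skipped; a pair with no informative locus is
flagged undefined rather than zero. Negative θ̂ (sampling noise around zero
differentiation, or heterozygote excess) is reported as computed.

F_IS is Nei's 1 − Ho/He aggregated as a ratio of sums with He = 2p(1−p) and
no small-sample correction; whether a correction should be applied is left
to the caller, and the uncorrected form is the one implemented.

Clustering of the θ̂ matrix uses complete linkage; negative entries are
clamped to zero *only* inside the clustering (a dissimilarity cannot be
negative), labels are pre-sorted so equal-distance ties resolve by
lexicographic pair order, and a newick export is provided for the dendrogram.

## LD and effective population size

r² between two loci is computed from phased haplotype frequencies:
D = f(AB) − f(A)f(B), r² = D²/(f(A)f(a)f(B)f(b)) — algebraically the squared
Pearson correlation of the two 0/1 haplotype columns, which is how the
full-panel scan computes it (blockwise matrix products per chromosome); the
two routes agree to 1e−12 in tests. Pairs are strictly within chromosomes,
at most 50 Mb apart, after a MAF ≥ 0.05 filter on haplotype frequencies.

Decay tables use half-open bins [k·w, (k+1)·w) (a pair at exactly 10 kb
falls in the second 10 kb bin); empty bins are reported with n = 0.

Ne estimation maps distance to recombination rate at the constant
1 Morgan = 100 Mbp and inverts Sved's drift-recombination relationship
Ne = (1/4c)(1/r² − 1) on the binned mean r², dated t = 1/(2c) generations
ago. Sample size inflates r² by about 1/(2N) for N diploids; the Weir–Hill
adjustment subtracts it from the bin mean before inversion (the adjustment
is linear, so adjusting the mean equals averaging adjusted pairs). Bin
layout: 80 half-open 25 kb bins over (0, 2 Mb], representative c at the bin
midpoint (so the first bin is dated t = 4,000); beyond 2 Mb, one bin per
generation t = 25…1 at target c_t = 1/(2t), with edges at midpoints between
consecutive c_t, clipped to (2 Mb, 50 Mb]. The midpoint conventions are
documented choices; they make the t labels reproducible. Bins whose
adjusted mean r² is non-positive are reported with Ne_adj omitted and a
reason, never floored — flooring would fabricate a finite Ne. Estimation
refuses populations with fewer than 20 diploids after relatedness pruning.

## Synthetic data

The Balding–Nichols generator draws, per SNP, an ancestral frequency
p ~ Uniform(0.05, 0.95) — an ascertained-array-like spectrum with no
monomorphic markers; the true ascertainment of commercial arrays is not
modelled — and population-k frequencies Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)
(mean p, variance F_k·p(1−p); F=0 gives p exactly, F=1 the Bernoulli
fixation limit). Admixed individuals get Dirichlet ancestry; each of an
individual's two alleles is an independent Bernoulli(h_ij) draw, so the
generator is the exact generative counterpart of the admixture likelihood
and, within populations, sites are in HWE and linkage equilibrium. Default
panel shape: ~40k SNPs on 29 autosomes of 100 Mb, K=3 populations at
F = 0.05/0.10/0.20 (African taurine / European taurine / indicine-scale
differentiation), 20 reference animals per population, 50 admixed, 7.5%
missingness. One global seed feeds fixed per-purpose substreams, so
changing the SNP count does not perturb animal-level draws.

The Wright–Fisher simulator is a discrete non-overlapping-generation
population of `ne` diploids; each offspring haplotype picks a random parent
and recombines its two haplotypes with Poisson(map length) crossovers placed
uniformly on the map (compiled inner loop; all randomness drawn from the
numpy generator outside the kernel, so seeding semantics are plain numpy).
Founders start in linkage equilibrium with frequencies Uniform(0.1, 0.9).
There is no mutation or selection, so heterozygosity decays as
(1 − 1/(2Ne))^t — verified against the closed form — and long histories fix
most loci: after 1,000 generations at Ne = 100 only ~1% of loci remain
polymorphic. For LD work this sparsity is the binding constraint, so a
multi-chromosome genome is emulated by concatenating independent replicate
runs as unlinked chromosomes under one sample: unlinked chromosomes drift
independently given the pedigree, so expected within-chromosome LD is
unchanged while SNP pairs per distance bin accumulate linearly.

## Validation design and problem sizes

All validation experiments run on synthetic panels at desk scale:

* ancestry recovery — K=3, F = 0.05/0.10/0.20, 5,000 SNPs, 20 reference
  animals per population, 50 admixed with flat Dirichlet ancestry; mean
  |q̂ − q| < 0.03;
* F_ST calibration — two populations at F = 0.1, 10,000 SNPs, 50 animals
  each, 10 replicates; mean θ̂ within [0.08, 0.12];
* Ne recovery — Ne = 100, 1,000 generations, 2,000 loci per 1-Morgan
  chromosome, 50 sampled diploids, 200 replicate chromosomes pooled.
  Recovery is assessed on bins with t ∈ [10, 100] and at least 30 pairs:
  with ~30 pairs the relative standard error of a bin's mean r² is roughly
  25% (the coefficient of variation of r² near drift-recombination
  equilibrium exceeds 1), which is the noise level at which a factor-of-two
  Ne check is meaningful; sparser bins are reported but not graded. The
  adjusted estimate must also dominate the raw one wherever both exist.

Because the admixture generator has no LD and the Wright–Fisher panels have
no population structure, passing these tests shows estimator correctness
under each model's own assumptions — not robustness to array ascertainment,
phasing error (synthetic panels are emitted perfectly phased; statistical
phasing of real data is out of scope), genotyping error, or admixture-LD.
Sved's formula is itself an approximation, with c-dependent bias visible in
the validation (short-range bins recover slightly under, long-range bins
slightly over the true value); the factor-of-two tolerance absorbs this,
which is consistent with how LD-based Ne estimates are interpreted in
practice.

## Numerical details

* frequency clamp ε = 1e−6 in admixture; EM tolerance 1e−4 on |Δ log L|,
  iteration cap 2,000;
* GRM symmetrised as (G + Gᵀ)/2 before eigen-decomposition; symmetry asserted
  to 1e−10;
* r² clipped to [0, 1] against floating-point overshoot; pair distances are
  strictly positive;
* undefined quantities (all-missing frequencies, monomorphic-pair θ̂, zero-He
  F_IS) are NaN-flagged, never silently zero;
* all tables are TSV with headers; every pipeline threshold is echoed into
  the run manifest together with the seed and input digests.
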