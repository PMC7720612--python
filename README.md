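# herdstat

Population-structure and linkage-disequilibrium analysis for livestock SNP
panels: genotype QC and multi-source panel merging, VanRaden genomic
relationships and PCA, supervised maximum-likelihood admixture, Weir–Cockerham
F<sub>ST</sub> / Nei F<sub>IS</sub>, haplotype r² LD decay, and LD-based
historical effective population size — all validated end-to-end against
synthetic genotype panels with known ground truth.

## What it computes

**Genomic relationships.** Genotypes are allele counts g ∈ {0, 1, 2}, coded
−1/0/1 into **M** and centred by **P** = 2(p<sub>i</sub> − 0.5):

    GRM = ZZ′ / d,   Z = M − P,   d = 2 Σᵢ pᵢ(1 − pᵢ)

with missing genotypes imputed to the SNP mean (centred entry 0). PCA is the
eigen-decomposition of the GRM; animals with a relationship > 0.2 to any other
animal can be greedily pruned before Ne estimation.

**Supervised admixture.** The binomial likelihood
g<sub>ij</sub> ~ Binomial(2, h<sub>ij</sub>), h<sub>ij</sub> = Σ<sub>k</sub>
q<sub>ik</sub> f<sub>kj</sub>, with reference animals held at one-hot ancestry,
fitted by EM block relaxation (Q-step, then F-step over all animals); the
log-likelihood is non-decreasing by construction. A frozen-F mode (reference
frequencies only) makes each animal's problem convex and exactly checkable
against grid search.

**Differentiation.** Pairwise Weir–Cockerham θ̂ from the genotype-level
variance components (a, b, c), combined across loci as Σa / Σ(a+b+c);
F<sub>IS</sub> = 1 − ΣHo / ΣHe with He = 2p(1−p). The θ̂ matrix is ordered by
complete-linkage hierarchical clustering.

**LD and historical Ne.** From phased haplotypes, D = f(AB) − f(A)f(B) and
r² = D² / (f(A)f(a)f(B)f(b)) for all within-chromosome pairs up to 50 Mb with
MAF ≥ 5%. Binned mean r² (10 kb bins to 1 Mb for decay; 80×25 kb bins to 2 Mb
plus generation-indexed bins for 25…1 generations beyond, for Ne) feeds Sved's
formula with the Weir–Hill sample-size adjustment:

    Ne = (1 / 4c) (1 / r²_adj − 1),   r²_adj = r² − 1/(2N),   t = 1/(2c)

with c in Morgans at the constant 1 Morgan = 100 Mbp, for populations with
N ≥ 20 after relatedness pruning.

**Synthetic data.** A Balding–Nichols admixture generator (K differentiated
populations, Dirichlet ancestry, optional missingness) and a discrete
Wright–Fisher forward simulator with Poisson recombination provide panels
whose true Q, F<sub>ST</sub> and Ne are known.

## Worked example

```python
import numpy as np
from herdstat import (SimConfig, simulate_panel, qc_filter, compute_grm,
                      pca_grm, ReferenceSpec, fit_supervised_admixture,
                      pairwise_fst)

cfg = SimConfig(n_snps=5000, n_chromosomes=5, n_pops=3,
                fst_per_pop=(0.05, 0.10, 0.20), dirichlet_alpha=(1, 1, 1),
                n_ref_per_pop=20, n_admixed=50, missing_rate=0.05, seed=42)
gm, panel, q_true, freqs = simulate_panel(cfg)

gm, report = qc_filter(gm)
print(report.n_snps_out, "SNPs,", report.n_animals_out, "animals after QC")

pca = pca_grm(compute_grm(gm), 5)
print("PC1-5 explain", round(100 * pca.variance_fractions[:5].sum(), 1), "%")

ref = ReferenceSpec({f"pop{k+1}": [f"ref{k+1}_{i}" for i in range(20)]
                     for k in range(3)})
model = fit_supervised_admixture(gm, ref)
err = np.abs(model.Q[~model.supervised_mask]
             - q_true[~model.supervised_mask]).mean()
print("mean |q_hat - q_true| =", round(err, 4))

theta, _ = pairwise_fst(gm, "pop1", "pop3")
print("theta(pop1, pop3) =", round(theta, 4))
```

prints

```
4952 SNPs, 110 animals after QC
PC1-5 explain 14.9 %
mean |q_hat - q_true| = 0.022
theta(pop1, pop3) = 0.1236
```

The 5% injected missingness costs 48 SNPs to the 90% call-rate filter. The
ancestry error is the mean absolute gap between estimated and simulated
ancestry proportions over the 50 admixed animals; θ̂ between two populations
simulated at differentiation 0.05 and 0.20 from a shared ancestor lands
between those values, as expected for a pair estimate. The first five PCs
explain a modest share of variance here because 110 exchangeable animals in
three moderately diverged populations leave most genomic relationship
variance off the population axes — with strongly diverged real breeds the
leading PCs dominate.

A CLI mirrors the stages (`herdstat simulate | qc | grm | pca | admix | fst |
ld | ne | run`); `herdstat run config.yaml` executes the whole pipeline and
writes TSV tables plus a manifest with seeds, digests and per-stage counts.

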