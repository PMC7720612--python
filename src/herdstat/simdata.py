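"""Synthetic genotype panels with known ground truth.

Two generative models are provided:

* a Balding–Nichols admixture model — K ancestral populations whose per-SNP
  allele frequencies are Beta-distributed around a shared ancestral
  frequency with differentiation parameter F_k, plus admixed individuals
  whose ancestry vectors are Dirichlet draws; haplotype alleles are
  independent Bernoulli draws from the individual's ancestry-weighted
  frequency, so the panel matches the binomial admixture likelihood exactly
  (no within-chromosome LD);

* a discrete Wright–Fisher forward simulator with recombination — a closed
  population of ``ne`` diploids reproduces for ``n_generations`` with
  Poisson crossovers on a genetic map, producing phased haplotypes whose LD
  decay reflects the (known) effective population size.  Physical positions
  are assigned at the constant rate 1 Morgan = 100 Mbp so base-pair
  distances feed the Ne binning directly.

Ancestral frequencies are drawn Uniform(0.05, 0.95), mimicking an
ascertained SNP array without monomorphic markers.  A single global integer
seed determines every draw; submodules derive independent streams from
fixed offsets so that, e.g., changing the SNP count does not perturb
animal-level ancestry draws.
"""

from __future__ import annotations

import dataclasses
import json

import numba
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, HaplotypePanel, write_plink, write_vcf

# fixed sub-stream offsets (spawn keys off the global seed)
_STREAM_FREQS = 1
_STREAM_Q = 2
_STREAM_ALLELES = 3
_STREAM_WF = 4
_STREAM_MISSING = 5
_MORGAN_BP = 100_000_000  # 1 Morgan = 100 Mbp


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class SimConfig:
    """Configuration of the Balding–Nichols admixed-panel generator.

    Defaults emulate a medium-density bovine array panel: ~40k SNPs spread
    over 29 autosomes of 100 Mb, three ancestral populations with moderate
    differentiation, flat Dirichlet ancestry for the admixed animals, and
    7.5% random missingness (the midpoint of the 5-10% range typical of
    array data before call-rate QC).
    """

    n_snps: int = 40_000
    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    n_pops: int = 3
    fst_per_pop: tuple[float, ...] = (0.05, 0.10, 0.20)
    dirichlet_alpha: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_ref_per_pop: int = 20
    n_admixed: int = 50
    missing_rate: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fst_per_pop) != self.n_pops:
            raise ValueError("fst_per_pop must have one entry per population")
        if len(self.dirichlet_alpha) != self.n_pops:
            raise ValueError("dirichlet_alpha must have one entry per population")
        for f in self.fst_per_pop:
            if not (f == 0.0 or 0.0 < f <= 1.0):
                raise ValueError(f"differentiation parameter {f} outside [0, 1]")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("n_snps", "n_chromosomes", "chrom_length_bp",
                     "n_pops", "n_ref_per_pop"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_admixed < 0:
            raise ValueError("n_admixed must be >= 0")


@dataclass
class WFConfig:
    """Configuration of the Wright–Fisher forward simulator."""

    ne: int = 100
    n_generations: int = 1000
    n_loci: int = 2000
    map_length_morgans: float = 1.0
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.sample_size > self.ne:
            raise ValueError("sample_size cannot exceed ne")
        if self.sample_size < 1 or self.n_loci < 1 or self.n_generations < 0:
            raise ValueError("invalid WFConfig counts")
        if self.map_length_morgans < 0:
            raise ValueError("map_length_morgans must be >= 0")


def _snp_map(n_snps: int, n_chromosomes: int, chrom_length_bp: int) -> pd.DataFrame:
    """Evenly spaced SNP positions over equal-length autosomes."""
    per = np.full(n_chromosomes, n_snps // n_chromosomes)
    per[: n_snps % n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(n_chromosomes):
        k = per[c]
        if k == 0:
            continue
        pos = np.linspace(1, chrom_length_bp, k, dtype=np.int64)
        if k > 1 and (np.diff(pos) <= 0).any():
            raise ValueError("chromosome too short for requested SNP density")
        chroms.extend([str(c + 1)] * k)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    df = pd.DataFrame({
        "chrom": chroms, "pos": pos_all,
        "ref": ["A"] * n_snps, "alt": ["C"] * n_snps,
    })
    # chromosome labels are strings, so order blocks lexicographically
    # ("1", "10", "2", ...); SNPs are exchangeable under the panel models
    order = np.lexsort((df["pos"], df["chrom"]))
    return df.iloc[order].reset_index(drop=True)


def simulate_ancestral_frequencies(cfg: SimConfig) -> np.ndarray:
    """Draw K x n_snps population allele frequencies (Balding–Nichols).

    For each SNP an ancestral frequency p ~ Uniform(0.05, 0.95); population
    k's frequency is Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), whose mean is p
    and variance F_k p(1-p).  F_k = 0 degenerates to p itself; F_k = 1 is
    the fixation limit, a Bernoulli(p) choice between 0 and 1.
    """
    rng = _rng(cfg.seed, _STREAM_FREQS)
    p = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    freqs = np.empty((cfg.n_pops, cfg.n_snps))
    for k, f in enumerate(cfg.fst_per_pop):
        if f == 0.0:
            freqs[k] = p
        elif f == 1.0:
            freqs[k] = (rng.random(cfg.n_snps) < p).astype(float)
        else:
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            freqs[k] = rng.beta(a, b)
    return freqs


def draw_q_matrix(cfg: SimConfig) -> np.ndarray:
    """Ground-truth ancestry: one-hot rows for references, Dirichlet for admixed."""
    rng = _rng(cfg.seed, _STREAM_Q)
    K = cfg.n_pops
    ref_q = np.repeat(np.eye(K), cfg.n_ref_per_pop, axis=0)
    adm_q = (
        rng.dirichlet(np.asarray(cfg.dirichlet_alpha), size=cfg.n_admixed)
        if cfg.n_admixed
        else np.empty((0, K))
    )
    return np.vstack([ref_q, adm_q])


def simulate_admixed_panel(
    freqs: np.ndarray,
    q_matrix: np.ndarray,
    cfg: SimConfig,
):
    """Draw a phased admixed panel from population frequencies and Q.

    Each of an individual's two alleles at SNP j is 1 with probability
    h_ij = sum_k q_ik f_kj, drawn independently; the genotype is the allele
    sum.  Returns (GenotypeMatrix, HaplotypePanel, Q).
    """
    freqs = np.asarray(freqs, dtype=float)
    q_matrix = np.asarray(q_matrix, dtype=float)
    if q_matrix.ndim != 2 or q_matrix.shape[1] != freqs.shape[0]:
        raise ValueError("q_matrix columns must match number of populations")
    if (q_matrix < 0).any() or np.abs(q_matrix.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("each q row must lie on the simplex")

    rng = _rng(cfg.seed, _STREAM_ALLELES)
    h = q_matrix @ freqs  # (n, n_snps)
    n = h.shape[0]
    hap_a = (rng.random(h.shape) < h).astype(np.int8)
    hap_b = (rng.random(h.shape) < h).astype(np.int8)
    hap_calls = np.empty((2 * n, h.shape[1]), dtype=np.int8)
    hap_calls[0::2] = hap_a
    hap_calls[1::2] = hap_b

    K = cfg.n_pops
    labels, ids = [], []
    for i in range(n):
        row = q_matrix[i]
        if i < cfg.n_ref_per_pop * K and np.isclose(row.max(), 1.0):
            k = int(row.argmax())
            labels.append(f"pop{k + 1}")
            ids.append(f"ref{k + 1}_{i % cfg.n_ref_per_pop}")
        else:
            labels.append("admixed")
            ids.append(f"adm{i}")
    samples = pd.DataFrame({"id": ids, "population": labels})
    snps = _snp_map(h.shape[1], cfg.n_chromosomes, cfg.chrom_length_bp)
    panel = HaplotypePanel(samples, snps, hap_calls)
    return panel.to_genotypes(), panel, q_matrix.copy()


def simulate_panel(cfg: SimConfig):
    """Convenience wrapper: frequencies + ground-truth Q + panel in one call."""
    freqs = simulate_ancestral_frequencies(cfg)
    q = draw_q_matrix(cfg)
    gm, panel, q = simulate_admixed_panel(freqs, q, cfg)
    if cfg.missing_rate > 0:
        gm = inject_missingness(gm, cfg.missing_rate, cfg.seed)
    return gm, panel, q, freqs


def inject_missingness(
    gm: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each genotype missing independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing rate must be in [0, 1]")
    if rate == 0.0:
        return GenotypeMatrix(gm.samples, gm.snps, gm.calls.copy())
    rng = _rng(seed, _STREAM_MISSING)
    mask = rng.random(gm.calls.shape) < rate
    calls = gm.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(gm.samples, gm.snps, calls)


# ---------------------------------------------------------------------------
# Wright–Fisher forward simulation
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _recombine_generation(pop, new, parents, starts, cuts, offsets,
                          locus_pos_m):
    """One generation of gamete formation (compiled inner loop).

    All randomness is drawn by the caller; this kernel only walks each
    gamete's crossover list (sorted in place) along the locus map, toggling
    the parental phase at each crossover.
    """
    n_gam = parents.shape[0]
    n_loci = locus_pos_m.shape[0]
    for g in range(n_gam):
        lo, hi = offsets[g], offsets[g + 1]
        # insertion sort of this gamete's few crossover positions
        for i in range(lo + 1, hi):
            v = cuts[i]
            j = i - 1
            while j >= lo and cuts[j] > v:
                cuts[j + 1] = cuts[j]
                j -= 1
            cuts[j + 1] = v
        phase = starts[g]
        ci = lo
        base = 2 * parents[g]
        for l in range(n_loci):
            while ci < hi and cuts[ci] < locus_pos_m[l]:
                phase ^= 1
                ci += 1
            new[g, l] = pop[base + phase, l]

def simulate_wright_fisher(cfg: WFConfig) -> HaplotypePanel:
    """Forward-simulate a closed diploid population with recombination.

    Discrete non-overlapping generations of ``ne`` diploids.  Each offspring
    haplotype picks a uniform random parent and recombines that parent's two
    haplotypes with Poisson(map_length_morgans) crossovers placed uniformly
    on the genetic map.  Founder haplotypes start in linkage equilibrium
    with per-locus frequencies Uniform(0.1, 0.9); no mutation, so LD at
    sampling reflects drift and recombination only.  Loci are evenly spaced
    on one chromosome; physical positions use 1 Morgan = 100 Mbp.
    """
    rng = _rng(cfg.seed, _STREAM_WF)
    L = cfg.n_loci
    locus_pos_m = (
        np.linspace(0.0, cfg.map_length_morgans, L)
        if L > 1
        else np.array([0.0])
    )
    p0 = rng.uniform(0.1, 0.9, size=L)
    pop = (rng.random((2 * cfg.ne, L)) < p0).astype(np.int8)

    n_gam = 2 * cfg.ne
    new = np.empty_like(pop)
    for _ in range(cfg.n_generations):
        parents = rng.integers(0, cfg.ne, size=n_gam)
        n_x = rng.poisson(cfg.map_length_morgans, size=n_gam)
        starts = rng.integers(0, 2, size=n_gam).astype(np.int64)
        cuts = rng.uniform(0.0, cfg.map_length_morgans, size=int(n_x.sum()))
        offsets = np.concatenate(([0], np.cumsum(n_x)))
        _recombine_generation(pop, new, parents, starts, cuts, offsets,
                              locus_pos_m)
        pop, new = new, pop

    picked = rng.choice(cfg.ne, size=cfg.sample_size, replace=False)
    hap_idx = np.ravel(np.column_stack((2 * picked, 2 * picked + 1)))
    haps = pop[hap_idx]
    pos_bp = np.maximum(1, np.round(locus_pos_m * _MORGAN_BP).astype(np.int64))
    # strictly increasing positions (ties only arise on near-zero maps)
    for j in range(1, L):
        if pos_bp[j] <= pos_bp[j - 1]:
            pos_bp[j] = pos_bp[j - 1] + 1
    snps = pd.DataFrame({
        "chrom": ["1"] * L, "pos": pos_bp,
        "ref": ["A"] * L, "alt": ["C"] * L,
    })
    samples = pd.DataFrame({
        "id": [f"wf{i}" for i in range(cfg.sample_size)],
        "population": ["wf"] * cfg.sample_size,
    })
    return HaplotypePanel(samples, snps, haps)


def simulate_wright_fisher_genome(
    cfg: WFConfig, n_chromosomes: int
) -> HaplotypePanel:
    """Multi-chromosome Wright–Fisher panel from independent replicate runs.

    Unlinked chromosomes drift independently given the pedigree, so a
    genome of ``n_chromosomes`` chromosomes is emulated by concatenating
    independent single-chromosome runs (sub-seeded from ``cfg.seed``) under
    one set of sample IDs.  Expected LD within each chromosome is identical
    to a shared-pedigree genome; pooling chromosomes simply accumulates SNP
    pairs per distance bin, which matters in long mutation-free histories
    where drift fixes most loci.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    panels = []
    for c in range(n_chromosomes):
        sub = dataclasses.replace(cfg, seed=cfg.seed * 10_000 + c)
        panels.append(simulate_wright_fisher(sub))
    snps = pd.concat([
        p.snps.assign(chrom=str(c + 1)) for c, p in enumerate(panels)
    ], ignore_index=True)
    calls = np.concatenate([p.calls for p in panels], axis=1)
    order = np.lexsort((snps["pos"], snps["chrom"]))
    return HaplotypePanel(panels[0].samples, snps.iloc[order], calls[:, order])


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(outdir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Emit VCF (phased), PLINK text, and ground-truth files for a panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, panel, q, _ = simulate_panel(cfg)
    paths = {
        "vcf": outdir / "panel.vcf",
        "ped": outdir / "panel.ped",
        "truth_q": outdir / "truth_q.tsv",
    }
    write_vcf(paths["vcf"], panel.to_genotypes(), panel)
    write_plink(outdir / "panel", gm)
    truth = pd.DataFrame(q, columns=[f"q_{k + 1}" for k in range(cfg.n_pops)])
    truth.insert(0, "animal", gm.samples["id"])
    truth.to_csv(paths["truth_q"], sep="\t", index=False)
    return paths


def write_wf_fixture(outdir: str | Path, cfg: WFConfig) -> dict[str, Path]:
    """Emit a phased VCF plus a truth JSON (ne, generations) for a WF run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_wright_fisher(cfg)
    paths = {"vcf": outdir / "wf.vcf", "truth": outdir / "truth_wf.json"}
    write_vcf(paths["vcf"], panel.to_genotypes(), panel)
    paths["truth"].write_text(json.dumps({
        "ne": cfg.ne, "n_generations": cfg.n_generations,
        "map_length_morgans": cfg.map_length_morgans,
        "sample_size": cfg.sample_size, "seed": cfg.seed,
    }, indent=2))
    return paths
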