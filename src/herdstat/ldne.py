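"""Haplotype r², LD decay, and LD-based historical effective population size.

r² between two loci is computed from phased haplotype frequencies:
D = f(AB) - f(A)f(B) and r² = D² / (f(A) f(a) f(B) f(b)), which equals the
squared Pearson correlation of the two 0/1 haplotype columns.  Pairs are
formed within chromosomes only, up to 50 Mb apart, after a MAF >= 5%
filter.

Historical Ne comes from Sved's drift-recombination relationship
Ne = (1/4c)(1/r² - 1), where c is the map distance in Morgans at the
constant rate 1 Morgan = 100 Mbp, evaluated on binned mean r² and dated to
t = 1/(2c) generations ago.  Finite sample size inflates r² by roughly
1/(2N) for N sampled diploids; the Weir–Hill adjustment
r²_adj = r² - 1/(2N) removes this before inverting Sved's formula.  Ne is
estimated only for populations with N >= 20 after pruning animals with a
genomic relationship above 0.2, since close relatives bias recent Ne
upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HaplotypePanel
from .grmpca import GRM, compute_grm, prune_related

MORGAN_BP = 100_000_000  # 1 Morgan = 100 Mbp
MAX_DIST_BP = 50_000_000
SHORT_BIN_BP = 25_000
SHORT_RANGE_BP = 2_000_000
N_SHORT_BINS = 80
MIN_SAMPLE_SIZE = 20


@dataclass
class NeBin:
    bp_lo: float
    bp_hi: float
    c: float                 # Morgans, representative distance
    t: float                 # generations ago, 1/(2c)
    n_pairs: int
    mean_r2: float
    mean_r2_adj: float
    ne: float | None
    ne_adj: float | None
    note: str = ""


@dataclass
class NeTrajectory:
    population: str
    sample_size: int         # diploids remaining after relatedness pruning
    bins: list[NeBin]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "t": b.t, "c": b.c, "bp_lo": b.bp_lo, "bp_hi": b.bp_hi,
            "n_pairs": b.n_pairs, "mean_r2": b.mean_r2,
            "mean_r2_adj": b.mean_r2_adj, "Ne": b.ne, "Ne_adj": b.ne_adj,
            "note": b.note,
        } for b in self.bins])


def pair_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r² between two phased 0/1 haplotype columns from haplotype frequencies.

    Both loci must be polymorphic among the haplotypes; otherwise r² is
    undefined and ValueError is raised (the MAF filter removes such loci
    upstream).
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("haplotype columns must be equal-length, length >= 2")
    n = len(a)
    fA = a.sum() / n
    fB = b.sum() / n
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        raise ValueError("monomorphic locus: r² undefined")
    fAB = float(np.sum((a == 1) & (b == 1))) / n
    d = fAB - fA * fB
    return d * d / (fA * (1.0 - fA) * fB * (1.0 - fB))


def ld_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    max_dist: int = MAX_DIST_BP,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to ``max_dist`` apart, with r².

    Loci failing the MAF filter are excluded from every pair.  Returns a
    DataFrame with columns (i, j, chrom, dist_bp, r2), each pair once; r²
    is computed blockwise as the squared correlation of haplotype columns,
    algebraically identical to the haplotype-frequency formula.
    """
    freqs = panel.calls.mean(axis=0)
    maf_ok = np.minimum(freqs, 1.0 - freqs) >= maf_min
    out = []
    for chrom in panel.snps["chrom"].unique():
        on_chrom = (panel.snps["chrom"] == chrom).to_numpy() & maf_ok
        idx = np.flatnonzero(on_chrom)
        if idx.size < 2:
            continue
        pos = panel.snps["pos"].to_numpy()[idx]
        x = panel.calls[:, idx].astype(float)
        x -= x.mean(axis=0)
        norm = np.sqrt((x**2).sum(axis=0))
        x /= norm
        corr = x.T @ x
        iu, ju = np.triu_indices(idx.size, k=1)
        dist = pos[ju] - pos[iu]
        keep = (dist > 0) & (dist <= max_dist)
        out.append(pd.DataFrame({
            "i": idx[iu[keep]], "j": idx[ju[keep]],
            "chrom": chrom, "dist_bp": dist[keep],
            "r2": np.clip(corr[iu[keep], ju[keep]] ** 2, 0.0, 1.0),
        }))
    if not out:
        return pd.DataFrame(columns=["i", "j", "chrom", "dist_bp", "r2"])
    return pd.concat(out, ignore_index=True)


def ld_decay_table(
    pairs: pd.DataFrame,
    n_diploids: int | None = None,
    bin_width: int = 10_000,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Mean r² per half-open distance bin [k*w, (k+1)*w) up to ``max_dist``.

    Empty bins are reported with n = 0.  When ``n_diploids`` is given the
    sample-size-adjusted mean r²_adj = mean r² - 1/(2N) is included.
    """
    if pairs.empty:
        raise ValueError("no LD pairs to bin")
    n_bins = max_dist // bin_width
    edges = np.arange(n_bins + 1) * bin_width
    which = np.floor_divide(pairs["dist_bp"].to_numpy(), bin_width)
    rows = []
    for k in range(n_bins):
        sel = pairs["r2"].to_numpy()[which == k]
        mean = float(sel.mean()) if sel.size else float("nan")
        row = {
            "bin_lo": int(edges[k]), "bin_hi": int(edges[k + 1]),
            "n_pairs": int(sel.size), "mean_r2": mean,
        }
        if n_diploids is not None:
            row["mean_r2_adj"] = (
                adjust_r2(mean, n_diploids) if sel.size else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def adjust_r2(r2: float, n_diploids: int) -> float:
    """Weir–Hill finite-sample adjustment r²_adj = r² - 1/(2N); may be <= 0."""
    if n_diploids < 1:
        raise ValueError("sample size must be >= 1")
    return r2 - 1.0 / (2.0 * n_diploids)


def sved_ne(mean_r2: float, c: float) -> tuple[float, float]:
    """Sved's formula: Ne = (1/4c)(1/r² - 1), dated t = 1/(2c) generations ago.

    ``c`` is in Morgans.  Raises ValueError for non-positive r² (such bins
    are dropped upstream rather than floored, since flooring would
    fabricate a finite Ne).
    """
    if c <= 0.0:
        raise ValueError("map distance c must be positive")
    if not 0.0 < mean_r2 <= 1.0:
        raise ValueError("non-positive adjusted r²")
    ne = (1.0 / (4.0 * c)) * (1.0 / mean_r2 - 1.0)
    t = 1.0 / (2.0 * c)
    return ne, t


def _trajectory_bins() -> list[tuple[float, float, float]]:
    """(bp_lo, bp_hi, c) for the short- and long-range trajectory bins.

    Short range: 80 half-open 25 kb bins over (0, 2 Mb], representative c
    at the bin midpoint.  Long range: one bin per generation t = 25..1 with
    target c_t = 1/(2t); edges at midpoints between consecutive c_t mapped
    to bp, clipped to (2 Mb, 50 Mb].
    """
    bins = []
    for k in range(N_SHORT_BINS):
        lo = k * SHORT_BIN_BP
        hi = lo + SHORT_BIN_BP
        mid = (lo + hi) / 2.0
        bins.append((float(lo), float(hi), mid / MORGAN_BP))
    ts = list(range(25, 0, -1))
    cs = [1.0 / (2.0 * t) for t in ts]          # increasing with recency
    edges = [SHORT_RANGE_BP / MORGAN_BP]
    for c_prev, c_next in zip(cs, cs[1:]):
        edges.append((c_prev + c_next) / 2.0)
    edges.append(MAX_DIST_BP / MORGAN_BP)
    for (lo_c, hi_c), c in zip(zip(edges, edges[1:]), cs):
        bins.append((lo_c * MORGAN_BP, hi_c * MORGAN_BP, c))
    return bins


def ne_trajectory(
    panel: HaplotypePanel,
    population: str,
    grm: GRM | None = None,
    maf_min: float = 0.05,
    relatedness_threshold: float | None = 0.2,
) -> NeTrajectory:
    """Historical Ne per distance bin for one population.

    Animals with a genomic relationship above ``relatedness_threshold`` to
    any other animal are pruned first (GRM computed from the population's
    own genotypes when not supplied); at least 20 diploids must remain.
    ``relatedness_threshold=None`` disables pruning — appropriate for small
    closed populations where background realized relatedness is pervasive
    and the rule, meant to drop close relatives from large breed samples,
    would empty the panel.  Bins whose adjusted mean r² is non-positive are
    retained in the output with Ne_adj omitted and a reason note.
    """
    mask = panel.population_mask(population)
    if not mask.any():
        raise KeyError(f"no animals in population {population!r}")
    sub = panel.subset_animals(mask)
    if relatedness_threshold is not None:
        if grm is None:
            grm = compute_grm(sub.to_genotypes())
        keep_ids = prune_related(grm, relatedness_threshold)
        keep_ids = [i for i in keep_ids if i in set(sub.samples["id"])]
        idx = pd.Index(sub.samples["id"]).get_indexer(keep_ids)
        sub = sub.subset_animals(np.sort(idx))
    n = sub.n_animals
    if n < MIN_SAMPLE_SIZE:
        raise ValueError(
            f"population {population!r} has {n} animals after relatedness "
            f"pruning; Ne is estimated only for sample sizes >= {MIN_SAMPLE_SIZE}"
        )
    pairs = ld_scan(sub, maf_min=maf_min, max_dist=MAX_DIST_BP)
    dist = pairs["dist_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    bins = []
    for lo, hi, c in _trajectory_bins():
        sel = r2[(dist >= lo) & (dist < hi)] if hi < MAX_DIST_BP else \
            r2[(dist >= lo) & (dist <= hi)]
        t = 1.0 / (2.0 * c)
        if sel.size == 0:
            bins.append(NeBin(lo, hi, c, t, 0, float("nan"), float("nan"),
                              None, None, "empty bin"))
            continue
        mean = float(sel.mean())
        mean_adj = adjust_r2(mean, n)
        ne = sved_ne(mean, c)[0] if mean > 0 else None
        if mean_adj > 0:
            ne_adj = sved_ne(mean_adj, c)[0]
            note = ""
        else:
            ne_adj = None
            note = "non-positive adjusted r²"
        bins.append(NeBin(lo, hi, c, t, int(sel.size), mean, mean_adj,
                          ne, ne_adj, note))
    return NeTrajectory(population, n, bins)
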