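"""Weir–Cockerham FST, Nei FIS, and complete-linkage ordering of the matrix.

Pairwise FST uses the Weir–Cockerham (1984) genotype-level variance-
components estimator for r = 2 populations, with observed heterozygote
frequencies, combined across loci as a ratio of sums
theta = sum_l a_l / sum_l (a_l + b_l + c_l) — the estimator's standard
multi-locus form, not an average of per-locus ratios.  Negative estimates
are legitimate (sampling noise around zero differentiation) and are
reported as computed; they are clamped to zero only inside clustering,
where a dissimilarity is required.

FIS is the plain Nei definition 1 - Ho/He aggregated as a ratio of sums
over loci, with He = 2p(1-p) and no small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genio import MISSING, GenotypeMatrix


@dataclass
class FstMatrix:
    """Pairwise theta-hat off-diagonal, FIS on the diagonal (not 0 by fiat)."""

    labels: list[str]
    matrix: np.ndarray       # symmetric; diag = FIS
    n_snps_used: np.ndarray  # per-pair informative locus counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _pop_counts(gm: GenotypeMatrix, pop: str):
    mask = gm.population_mask(pop)
    if mask.sum() < 2:
        raise ValueError(f"population {pop!r} needs >= 2 animals")
    calls = gm.calls[mask]
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)            # called animals per locus
    alt = np.where(obs, calls, 0).sum(axis=0)
    het = np.where(obs, calls == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Per-locus Weir–Cockerham variance components (a, b, c) for r = 2.

    a: among populations; b: among individuals within populations;
    c: within individuals.  Inputs are per-locus sample sizes, alternate
    allele frequencies and observed heterozygote fractions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str):
    """Multi-locus Weir–Cockerham theta-hat between two populations.

    Returns (theta, components DataFrame).  Loci monomorphic across the
    pair, or with fewer than 2 called animals in either population, are
    skipped; theta is ``nan`` when no informative locus remains.
    """
    n1, p1, h1 = _pop_counts(gm, pop_a)
    n2, p2, h2 = _pop_counts(gm, pop_b)
    valid = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(valid, (n1 * p1 + n2 * p2) / (n1 + n2), np.nan)
        hbar = np.where(valid, (n1 * h1 + n2 * h2) / (n1 + n2), np.nan)
    poly = valid & ~(((pbar == 0.0) | (pbar == 1.0)) & (hbar == 0.0))
    idx = np.flatnonzero(poly)
    if idx.size == 0:
        return float("nan"), pd.DataFrame(columns=["locus", "a", "b", "c"])
    a, b, c = wc_components(
        n1[idx], p1[idx], h1[idx], n2[idx], p2[idx], h2[idx]
    )
    comp = pd.DataFrame({"locus": idx, "a": a, "b": b, "c": c})
    denom = float((a + b + c).sum())
    theta = float(a.sum()) / denom if denom != 0.0 else float("nan")
    return theta, comp


def fis(gm: GenotypeMatrix, pop: str) -> float:
    """Nei inbreeding coefficient 1 - sum(Ho) / sum(He) over loci.

    He = 2p(1-p) from the population's own frequencies; monomorphic loci
    contribute zero to both sums.  ``nan`` when sum(He) = 0.
    """
    n, p, h = _pop_counts(gm, pop)
    valid = (n >= 1) & ~np.isnan(p)
    he = np.where(valid, 2.0 * p * (1.0 - p), 0.0)
    ho = np.where(valid, h, 0.0)
    ho = np.where(he > 0.0, ho, 0.0)  # monomorphic loci drop from both sums
    she = float(he.sum())
    if she == 0.0:
        return float("nan")
    return 1.0 - float(ho.sum()) / she


def fst_fis_matrix(gm: GenotypeMatrix, populations: list[str] | None = None) -> FstMatrix:
    """All pairwise theta-hats with per-population FIS on the diagonal."""
    pops = populations or gm.populations()
    k = len(pops)
    m = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for i, a in enumerate(pops):
        m[i, i] = fis(gm, a)
        for j in range(i + 1, k):
            theta, comp = pairwise_fst(gm, a, pops[j])
            m[i, j] = m[j, i] = theta
            counts[i, j] = counts[j, i] = len(comp)
    return FstMatrix(pops, m, counts)


def cluster_fst(fst: FstMatrix):
    """Complete-linkage hierarchical clustering of the FST matrix.

    Negative theta-hats are clamped to 0 for clustering only.  Returns
    (scipy linkage matrix, leaf-order labels) for heatmap rendering.
    Labels are pre-sorted so equal-distance ties resolve by lexicographic
    pair order.
    """
    off = fst.matrix.copy()
    np.fill_diagonal(off, 0.0)
    if np.isnan(off).any():
        raise ValueError(
            "FST matrix has undefined entries; impute or exclude those "
            "populations before clustering"
        )
    order = np.argsort(np.asarray(fst.labels, dtype=object))
    labels = [fst.labels[i] for i in order]
    dist = np.clip(off[np.ix_(order, order)], 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    leaves = hierarchy.leaves_list(z)
    return z, [labels[i] for i in leaves]


def dendrogram_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch heights."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    body = walk(tree, tree.dist)
    return body + ";"
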