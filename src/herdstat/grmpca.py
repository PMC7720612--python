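"""Genomic relationship matrix (VanRaden method 1), PCA, relatedness pruning.

The GRM is ZZ'/d: genotypes coded -1/0/1 into **M**, centred by
P = 2(p_i - 0.5) with p_i the alternate-allele frequency computed from the
analysed panel itself, and scaled by d = 2 * sum p_i (1 - p_i).  Missing
genotypes are replaced by the SNP's mean coded value 2p_i - 1, i.e. their
centred entry is exactly 0, so they contribute nothing to any relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .genio import MISSING, GenotypeMatrix, allele_frequencies


@dataclass
class GRM:
    ids: list[str]
    matrix: np.ndarray
    d: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n != len(self.ids):
            raise ValueError("GRM must be square and match the ID list")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-10:
            raise ValueError("GRM must be symmetric to 1e-10")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, raw (may contain tiny negatives)
    scores: np.ndarray             # (n_animals, n_components)
    variance_fractions: np.ndarray # over all n components, sums to 1
    ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "id", self.ids)
        return df


def compute_grm(gm: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from a genotype panel.

    Raises ValueError when every SNP is monomorphic (d = 0).
    """
    if gm.n_animals < 2:
        raise ValueError("GRM needs at least two animals")
    p = allele_frequencies(gm)
    p = np.where(np.isnan(p), 0.0, p)
    d = 2.0 * float(np.sum(p * (1.0 - p)))
    if d == 0.0:
        raise ValueError("all SNPs monomorphic: GRM scaling constant d = 0")
    # Z = (g - 1) - 2(p - 0.5) = g - 2p; missing -> 0 (mean imputation)
    g = gm.calls.astype(float)
    z = g - 2.0 * p[np.newaxis, :]
    z[gm.calls == MISSING] = 0.0
    grm = (z @ z.T) / d
    grm = (grm + grm.T) / 2.0  # absorb floating-point asymmetry
    return GRM(list(gm.samples["id"]), grm, d)


def pca_grm(grm: GRM, n_components: int | None = None) -> PCAResult:
    """Eigen-decomposition PCA of a GRM.

    Scores are eigenvector * sqrt(eigenvalue); the variance fraction of
    component i is lambda_i / sum_j max(lambda_j, 0) — numerically negative
    eigenvalues are clipped to zero in the denominator but reported raw.
    """
    n = grm.n
    if n_components is None:
        n_components = n
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds {n} animals")
    evals, evecs = scipy.linalg.eigh((grm.matrix + grm.matrix.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    clipped = np.clip(evals, 0.0, None)
    total = clipped.sum()
    fractions = clipped / total if total > 0 else np.zeros_like(clipped)
    scores = evecs[:, :n_components] * np.sqrt(clipped[:n_components])
    return PCAResult(evals, scores, fractions, list(grm.ids))


def prune_related(grm: GRM, threshold: float = 0.2) -> list[str]:
    """Greedy removal of animals until no relationship exceeds ``threshold``.

    Repeatedly removes the animal with the most off-diagonal relationships
    above the threshold (ties: larger mean off-diagonal relationship, then
    lexicographically smaller ID), which retains the most animals for a
    star-shaped relatedness pattern.  Returns surviving IDs in input order.
    """
    m = grm.matrix.copy()
    np.fill_diagonal(m, 0.0)
    alive = np.ones(grm.n, dtype=bool)
    ids = np.asarray(grm.ids, dtype=object)
    while True:
        sub = m[np.ix_(alive, alive)]
        over = sub > threshold
        if not over.any():
            break
        degree = over.sum(axis=1)
        cand = np.flatnonzero(degree == degree.max())
        if len(cand) > 1:
            means = sub[cand].mean(axis=1)
            cand = cand[np.isclose(means, means.max())]
            if len(cand) > 1:
                sub_ids = ids[alive][cand]
                cand = cand[[int(np.argmin(sub_ids))]]
        victim_global = np.flatnonzero(alive)[cand[0]]
        alive[victim_global] = False
    return [i for i, a in zip(grm.ids, alive) if a]
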