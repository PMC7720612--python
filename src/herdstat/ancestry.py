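"""Supervised maximum-likelihood admixture estimation.

The model is the standard binomial admixture likelihood: individual i's
genotype at SNP j is Binomial(2, h_ij) with h_ij = sum_k q_ik f_kj, where
q_i is the individual's ancestry vector over K ancestral populations and
f_kj are the ancestral alternate-allele frequencies.  In supervised mode
reference animals carry fixed one-hot ancestry rows and only the remaining
animals' Q rows are estimated.

Fitting uses EM block relaxation: a Q-step (EM update of each non-reference
animal's ancestry with F fixed) followed by an F-step (expected allele
counts attributed to each ancestral population over all animals, reference
included).  Each block step is an EM step on the full likelihood with the
other block fixed, so the log-likelihood never decreases across iterations.
A frozen-F mode keeps F at the reference-panel allele frequencies, making
each animal's Q problem convex and exactly checkable against grid search.

Missing genotypes contribute nothing to either step.  Frequencies are
clamped to [1e-6, 1 - 1e-6] so the likelihood stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, allele_frequencies

_EPS = 1e-6  # frequency boundary clamp


@dataclass
class ReferenceSpec:
    """Mapping ancestral-population label -> reference animal IDs (disjoint)."""

    populations: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, ids in self.populations.items():
            if not ids:
                raise ValueError(f"reference population {label!r} is empty")
            dup = seen.intersection(ids)
            if dup:
                raise ValueError(f"reference sets overlap on {sorted(dup)[:5]}")
            seen.update(ids)

    @property
    def labels(self) -> list[str]:
        return list(self.populations)

    @property
    def k(self) -> int:
        return len(self.populations)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        have = set(gm.samples["id"])
        for label, ids in self.populations.items():
            missing = set(ids) - have
            if missing:
                raise KeyError(
                    f"reference population {label!r} lists unknown animals "
                    f"{sorted(missing)[:5]}"
                )


@dataclass
class AncestryModel:
    labels: list[str]                  # K ancestral-population labels
    animal_ids: list[str]
    Q: np.ndarray                      # (n_animals, K), rows on the simplex
    F: np.ndarray                      # (K, n_snps) in [eps, 1-eps]
    supervised_mask: np.ndarray        # animals with fixed one-hot rows
    loglik_trace: list[float]
    converged: bool

    @property
    def k(self) -> int:
        return len(self.labels)

    def q_frame(self, populations: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=self.labels)
        df.insert(0, "animal", self.animal_ids)
        if populations is not None:
            df.insert(1, "population", populations)
        return df


def pool_reference(
    gm: GenotypeMatrix,
    breeds: list[str],
    per_breed: int = 8,
    seed: int = 0,
    pooled_label: str = "pooled",
) -> ReferenceSpec:
    """Sample ``per_breed`` animals per breed (without replacement) into one
    pooled reference population; breeds that cluster tightly in PCA can thus
    enter the model as a single ancestral population.  Breeds with fewer
    animals contribute all of them, with a warning.  Combine with other
    reference populations by merging the returned mapping.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for breed in breeds:
        ids = gm.samples.loc[gm.samples["population"] == breed, "id"].tolist()
        if not ids:
            raise KeyError(f"unknown breed label {breed!r}")
        if len(ids) <= per_breed:
            if len(ids) < per_breed:
                warnings.warn(
                    f"breed {breed!r} has only {len(ids)} animals "
                    f"(< {per_breed}); taking all of them"
                )
            chosen.extend(ids)
        else:
            chosen.extend(sorted(rng.choice(ids, size=per_breed, replace=False)))
    return ReferenceSpec({pooled_label: chosen})


def log_likelihood(
    gm: GenotypeMatrix, Q: np.ndarray, F: np.ndarray
) -> float:
    """Binomial admixture log-likelihood (binomial coefficient omitted).

    sum_ij [ g_ij ln h_ij + (2 - g_ij) ln(1 - h_ij) ], missing cells skipped.
    """
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if Q.shape[0] != gm.n_animals or F.shape[1] != gm.n_snps \
            or Q.shape[1] != F.shape[0]:
        raise ValueError("Q/F shapes do not conform to the panel")
    if np.abs(Q.sum(axis=1) - 1.0).max() > 1e-6 or (Q < -1e-12).any():
        raise ValueError("Q rows must lie on the simplex")
    h = Q @ F
    g = gm.calls.astype(float)
    obs = gm.calls != MISSING
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(obs, g * np.log(h) + (2.0 - g) * np.log1p(-h), 0.0)
    return float(ll.sum())


def reference_frequencies(
    gm: GenotypeMatrix, ref: ReferenceSpec
) -> np.ndarray:
    """Per-ancestral-population allele frequencies from reference animals only."""
    F = np.empty((ref.k, gm.n_snps))
    for k, (label, ids) in enumerate(ref.populations.items()):
        sub = gm.subset_animals(ids)
        p = allele_frequencies(sub)
        F[k] = np.where(np.isnan(p), 0.5, p)
    return np.clip(F, _EPS, 1.0 - _EPS)


def fit_supervised_admixture(
    gm: GenotypeMatrix,
    ref: ReferenceSpec,
    freeze_f: bool = False,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AncestryModel:
    """Fit ancestry proportions with fixed-label reference populations.

    K is the number of reference populations.  Non-reference animals start
    from uniform ancestry 1/K; F starts at (and, with ``freeze_f``, stays
    at) the reference-panel frequencies.  Iterates Q- and F-steps until the
    log-likelihood improves by less than ``tol`` or ``max_iter`` is reached;
    non-convergence is reported via ``converged=False``, not an exception.
    """
    ref.validate_against(gm)
    K = ref.k
    n = gm.n_animals
    ref_row = np.full(n, -1, dtype=int)
    id_pos = {a: i for i, a in enumerate(gm.samples["id"])}
    for k, ids in enumerate(ref.populations.values()):
        for a in ids:
            ref_row[id_pos[a]] = k
    is_ref = ref_row >= 0
    if is_ref.all():
        raise ValueError("no non-reference animals to estimate")

    G = gm.calls.astype(float)
    obs = gm.calls != MISSING
    G[~obs] = 0.0           # masked cells contribute 0 via the obs mask
    G2 = np.where(obs, 2.0 - gm.calls, 0.0)
    J = obs.sum(axis=1).astype(float)  # non-missing SNPs per animal
    if (J == 0).any():
        raise ValueError("animal with no called genotypes")

    F = reference_frequencies(gm, ref)
    Q = np.full((n, K), 1.0 / K)
    Q[is_ref] = np.eye(K)[ref_row[is_ref]]

    trace = [log_likelihood(gm, Q, F)]
    converged = False
    for _ in range(max_iter):
        # Q-step: EM update for non-reference animals, F fixed
        H = Q @ F
        A = (G / H) @ F.T                  # sum_j g f_k / h
        B = (G2 / (1.0 - H)) @ (1.0 - F).T # sum_j (2-g)(1-f_k)/(1-h)
        Qnew = Q * (A + B) / (2.0 * J)[:, None]
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        Qnew[is_ref] = Q[is_ref]
        Q = Qnew
        # F-step: expected allele counts attributed to each population
        if not freeze_f:
            H = Q @ F
            alt = F * (Q.T @ (G / H))                    # (K, n_snps)
            refc = (1.0 - F) * (Q.T @ (G2 / (1.0 - H)))
            with np.errstate(invalid="ignore"):
                F = np.where(alt + refc > 0, alt / (alt + refc), F)
            F = np.clip(F, _EPS, 1.0 - _EPS)
        ll = log_likelihood(gm, Q, F)
        trace.append(ll)
        if abs(ll - trace[-2]) < tol:
            converged = True
            break

    return AncestryModel(
        labels=ref.labels,
        animal_ids=list(gm.samples["id"]),
        Q=Q,
        F=F,
        supervised_mask=is_ref,
        loglik_trace=trace,
        converged=converged,
    )


def fit_q_grid(
    g: np.ndarray, F: np.ndarray, step: float = 0.001
) -> np.ndarray:
    """Brute-force grid maximiser of one animal's ancestry for K=2.

    Independent check for the EM fit on convex frozen-F problems.
    ``g`` is the animal's genotype vector (MISSING allowed); F is (2, n_snps).
    """
    if F.shape[0] != 2:
        raise ValueError("grid search implemented for K=2 only")
    obs = g != MISSING
    gv = g[obs].astype(float)
    f = F[:, obs]
    qs = np.arange(0.0, 1.0 + step / 2, step)
    best_q, best_ll = 0.0, -np.inf
    for q1 in qs:
        h = q1 * f[0] + (1.0 - q1) * f[1]
        h = np.clip(h, _EPS, 1.0 - _EPS)
        ll = float(np.sum(gv * np.log(h) + (2.0 - gv) * np.log1p(-h)))
        if ll > best_ll:
            best_q, best_ll = q1, ll
    return np.array([best_q, 1.0 - best_q])
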