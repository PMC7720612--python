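"""Genotype containers, standard-format I/O, quality control and panel merging.

Genotypes are stored as alternate-allele counts in an ``int8`` matrix of
shape (n_animals, n_snps), with :data:`MISSING` (-1) as the missing sentinel
(never 0, so a missing call can never be confused with a homozygous
reference call).  SNP records are kept sorted by (chromosome, position) and
coordinates are 1-based inclusive, following VCF convention; physical
distances are ``|pos_a - pos_b|`` base pairs.

Supported formats: VCF 4.2 (GT field; the phased ``|`` vs unphased ``/``
separator is honoured — a phased haplotype panel is produced only when every
call in the file is phased) and the PLINK text dialect (.ped/.map, alleles
as letters, ``0 0`` missing).  For PLINK input, which carries unordered
allele letters, the reference allele of each SNP is defined as the
lexicographically smaller of the two observed alleles.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype / haplotype call
MISSING: int = -1


class FormatError(ValueError):
    """Raised when an input file violates the named standard."""


class EmptyPanelError(ValueError):
    """Raised when a filter or merge removes every SNP or every animal."""


def _check_snp_table(snps: pd.DataFrame) -> None:
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(snps.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    key = list(zip(snps["chrom"], snps["pos"]))
    if sorted(key) != key:
        raise FormatError("SNPs must be sorted by (chromosome, position)")
    if len(set(key)) != len(key):
        dup = pd.Series(key)[pd.Series(key).duplicated()].iloc[0]
        raise FormatError(f"duplicate SNP position {dup[0]}:{dup[1]}")


@dataclass
class GenotypeMatrix:
    """Diploid SNP panel: animals x SNPs alternate-allele counts.

    Attributes
    ----------
    samples : DataFrame with columns ``id`` (unique) and ``population``.
    snps : DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``,
        sorted by (chrom, pos) with no duplicate positions.
    calls : int8 array (n_animals, n_snps) in {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.samples["id"].duplicated().any():
            raise ValueError("animal IDs must be unique")
        _check_snp_table(self.snps)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValueError("genotype calls must be in {0,1,2} or MISSING")

    @property
    def n_animals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def animal_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.samples["id"])
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown animal IDs: {missing[:5]}")
        return idx

    def population_mask(self, population: str) -> np.ndarray:
        return (self.samples["population"] == population).to_numpy()

    def subset_animals(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.animal_index(mask_or_ids)
        return GenotypeMatrix(
            self.samples.iloc[idx], self.snps, self.calls[idx]
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            self.samples, self.snps.iloc[idx], self.calls[:, idx]
        )

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))


@dataclass
class HaplotypePanel:
    """Phased panel: 2 haplotypes per animal, rows ``2i`` and ``2i+1``.

    ``calls`` is an int8 array (2*n_animals, n_snps) of {0,1} alternate-allele
    indicators.  Summing an animal's two haplotype rows reproduces its
    genotype row.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        _check_snp_table(self.snps)
        if self.calls.shape != (2 * len(self.samples), len(self.snps)):
            raise ValueError("haplotype calls must be 2*n_animals x n_snps")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("haplotype calls must be 0/1")

    @property
    def n_animals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def to_genotypes(self) -> GenotypeMatrix:
        g = self.calls[0::2] + self.calls[1::2]
        return GenotypeMatrix(self.samples, self.snps, g)

    def subset_animals(self, mask: np.ndarray) -> "HaplotypePanel":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        hap_idx = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        return HaplotypePanel(
            self.samples.iloc[idx], self.snps, self.calls[hap_idx]
        )

    def population_mask(self, population: str) -> np.ndarray:
        return (self.samples["population"] == population).to_numpy()


@dataclass
class QCConfig:
    """Quality-control thresholds.

    Call-rate thresholds of 0.90 for both SNPs and animals; only autosomes
    retained; no MAF or HWE filter for structure analyses (low-MAF SNPs are
    informative for breed differentiation and HWE is not expected to hold in
    admixed or small populations).  ``maf_min_for_ld`` applies only inside
    the LD analyses.
    """

    snp_call_rate_min: float = 0.90
    animal_call_rate_min: float = 0.90
    autosomes_only: bool = True
    maf_min_for_ld: float = 0.05

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "animal_call_rate_min", "maf_min_for_ld"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_snps_in: int
    n_animals_in: int
    n_snps_nonautosomal: int
    n_snps_low_call_rate: int
    n_animals_low_call_rate: int
    n_snps_out: int
    n_animals_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(self)]
        ).T.reset_index().set_axis(["step", "count"], axis=1)


def is_autosome(chrom: str) -> bool:
    """An autosome label is a plain positive integer (optionally 'chr'-prefixed)."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.isdigit() and int(c) > 0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    populations: dict[str, str] | None = None,
):
    """Read a genotype panel.

    Parameters
    ----------
    path : VCF file, or PLINK .ped path (the .map is found by extension swap).
    format : ``"vcf"`` or ``"plink_text"``.
    populations : optional mapping animal ID -> population label. For PLINK
        input the family ID column is used when no mapping is given; for VCF,
        unmapped animals get population ``"unknown"``.

    Returns
    -------
    (GenotypeMatrix, HaplotypePanel | None) — the haplotype panel is present
    only when every GT call in a VCF is phased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, populations)
    if format == "plink_text":
        return _read_plink(path, populations)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path, populations: dict[str, str] | None):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    ids = list(vcf.samples)
    rows = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    last_key: tuple[str, int] | None = None
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key in seen:
            raise FormatError(f"duplicate position {var.CHROM}:{var.POS}")
        if last_key is not None and key[0] == last_key[0] and key[1] < last_key[1]:
            raise FormatError(f"unsorted VCF at {var.CHROM}:{var.POS}")
        seen.add(key)
        last_key = key
        alt = var.ALT[0] if var.ALT else "."
        rows.append((var.CHROM, var.POS, var.REF, alt))
        gts = var.genotypes  # [[a0, a1, phased], ...]
        g = np.empty(len(ids), dtype=np.int8)
        h = np.empty((len(ids), 2), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise FormatError(
                    f"non-diploid call at {var.CHROM}:{var.POS}, sample {ids[i]}"
                )
            a0, a1, phased = gt[0], gt[1], gt[2]
            if a0 < 0 or a1 < 0:
                g[i] = MISSING
                h[i] = 0
                all_phased = False
            else:
                g[i] = a0 + a1
                h[i, 0], h[i, 1] = a0, a1
                if not phased:
                    all_phased = False
        geno_cols.append(g)
        hap_cols.append(h)
    if not rows:
        raise FormatError(f"no variant records in {path}")
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    order = np.lexsort((snps["pos"], snps["chrom"]))
    snps = snps.iloc[order]
    calls = np.stack(geno_cols, axis=1)[:, order]
    pops = [
        (populations or {}).get(i, "unknown") for i in ids
    ]
    samples = pd.DataFrame({"id": ids, "population": pops})
    gm = GenotypeMatrix(samples, snps, calls)
    panel = None
    if all_phased:
        haps = np.stack(hap_cols, axis=0)[order]  # (n_snps, n, 2)
        hap_calls = haps.transpose(1, 2, 0).reshape(2 * len(ids), -1)
        panel = HaplotypePanel(samples, snps, hap_calls)
    return gm, panel


def _read_plink(path: Path, populations: dict[str, str] | None):
    ped_path = path if path.suffix == ".ped" else path.with_suffix(".ped")
    map_path = ped_path.with_suffix(".map")
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    n_snps = len(map_df)
    ids, pops, geno_rows = [], [], []
    allele_sets: list[set[str]] = [set() for _ in range(n_snps)]
    raw_pairs = []
    with open(ped_path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snps:
                raise FormatError(
                    f"PED line for {tok[1] if len(tok) > 1 else '?'} has "
                    f"{len(tok) - 6} allele fields, expected {2 * n_snps}"
                )
            fid, iid = tok[0], tok[1]
            ids.append(iid)
            pops.append((populations or {}).get(iid, fid))
            pair = np.array(tok[6:], dtype=object).reshape(n_snps, 2)
            raw_pairs.append(pair)
            for j in range(n_snps):
                allele_sets[j].update(a for a in pair[j] if a != "0")
    refs, alts = [], []
    for j, s in enumerate(allele_sets):
        if len(s) > 2:
            raise FormatError(
                f"SNP {map_df['snp_id'][j]} has >2 alleles: {sorted(s)}"
            )
        al = sorted(s)
        refs.append(al[0] if al else "N")
        alts.append(al[1] if len(al) == 2 else ".")
    calls = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    for i, pair in enumerate(raw_pairs):
        for j in range(n_snps):
            a, b = pair[j]
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == alts[j]) + (b == alts[j])
    snps = pd.DataFrame({
        "chrom": map_df["chrom"].astype(str), "pos": map_df["pos"],
        "ref": refs, "alt": alts,
    })
    order = np.lexsort((snps["pos"], snps["chrom"]))
    snps = snps.iloc[order]
    calls = calls[:, order]
    samples = pd.DataFrame({"id": ids, "population": pops})
    return GenotypeMatrix(samples, snps, calls), None


def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    panel: HaplotypePanel | None = None,
) -> None:
    """Write a minimal VCF 4.2; phased GT when a haplotype panel is given."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"]) + "\n"
        )
        for j, snp in enumerate(gm.snps.itertuples(index=False)):
            fields = [
                str(snp.chrom), str(snp.pos), f"snp{j}", snp.ref, snp.alt,
                ".", "PASS", ".", "GT",
            ]
            if panel is not None:
                a = panel.calls[0::2, j]
                b = panel.calls[1::2, j]
                gts = [f"{x}|{y}" for x, y in zip(a, b)]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(g)] for g in gm.calls[:, j]]
            fh.write("\t".join(fields + gts) + "\n")


def write_plink(path_prefix: str | Path, gm: GenotypeMatrix) -> None:
    """Write PLINK text .ped/.map (alleles as letters, '0 0' missing)."""
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, snp in enumerate(gm.snps.itertuples(index=False)):
            fh.write(f"{snp.chrom}\tsnp{j}\t0\t{snp.pos}\n")
    refs = gm.snps["ref"].to_numpy()
    alts = gm.snps["alt"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(gm.samples.itertuples(index=False)):
            row = [s.population, s.id, "0", "0", "0", "-9"]
            for j, g in enumerate(gm.calls[i]):
                if g == MISSING:
                    row += ["0", "0"]
                elif g == 0:
                    row += [refs[j], refs[j]]
                elif g == 1:
                    row += [refs[j], alts[j]]
                else:
                    row += [alts[j], alts[j]]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, cfg: QCConfig | None = None):
    """Apply the standard panel QC and return (filtered panel, report).

    Order: non-autosomal SNPs dropped first, then SNPs with call rate below
    ``snp_call_rate_min``, then animals with call rate (computed on the
    surviving SNPs) below ``animal_call_rate_min``.  No MAF or HWE filtering.
    """
    cfg = cfg or QCConfig()
    n_snps_in, n_animals_in = gm.n_snps, gm.n_animals

    if cfg.autosomes_only:
        auto = gm.snps["chrom"].map(is_autosome).to_numpy()
    else:
        auto = np.ones(gm.n_snps, dtype=bool)
    n_nonauto = int((~auto).sum())
    gm4 = gm.subset_snps(auto) if n_nonauto else gm
    if gm4.n_snps == 0:
        raise EmptyPanelError("no autosomal SNPs remain")

    # SNP-then-animal call-rate cycle, repeated to a fixed point: removing
    # missing-heavy animals can push surviving-SNP call rates back under the
    # threshold, so one pass alone would not be idempotent
    n_low_snp = n_low_animal = 0
    while True:
        observed = gm4.calls != MISSING
        keep_snp = observed.mean(axis=0) >= cfg.snp_call_rate_min
        dropped_snps = int((~keep_snp).sum())
        n_low_snp += dropped_snps
        if dropped_snps:
            gm4 = gm4.subset_snps(keep_snp)
        if gm4.n_snps == 0:
            raise EmptyPanelError("all SNPs removed by call-rate filter")
        animal_cr = (gm4.calls != MISSING).mean(axis=1)
        keep_animal = animal_cr >= cfg.animal_call_rate_min
        dropped_animals = int((~keep_animal).sum())
        n_low_animal += dropped_animals
        if dropped_animals:
            gm4 = gm4.subset_animals(keep_animal)
        if gm4.n_animals == 0:
            raise EmptyPanelError("all animals removed by call-rate filter")
        if dropped_snps == 0 and dropped_animals == 0:
            break

    report = QCReport(
        n_snps_in=n_snps_in,
        n_animals_in=n_animals_in,
        n_snps_nonautosomal=n_nonauto,
        n_snps_low_call_rate=n_low_snp,
        n_animals_low_call_rate=n_low_animal,
        n_snps_out=gm4.n_snps,
        n_animals_out=gm4.n_animals,
    )
    return gm4, report


# ---------------------------------------------------------------------------
# multi-panel merge
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def merge_intersect(panels: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge panels from different sources, keeping only shared SNPs.

    SNPs are matched on (chromosome, position).  Alleles are harmonised to
    the first panel: identical ref/alt kept as-is; swapped ref/alt recoded
    ``g -> 2 - g``; anything else (including strand-ambiguous mismatches,
    which cannot be resolved safely without frequency heuristics) dropped
    and logged.  Animal IDs must be disjoint across panels.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    all_ids = pd.concat([p.samples["id"] for p in panels])
    if all_ids.duplicated().any():
        raise ValueError("animal IDs must be disjoint across panels")

    def keys(p: GenotypeMatrix):
        return pd.MultiIndex.from_arrays([p.snps["chrom"], p.snps["pos"]])

    shared = keys(panels[0])
    for p in panels[1:]:
        shared = shared.intersection(keys(p))
    if len(shared) == 0:
        raise EmptyPanelError("no SNPs shared across all panels")

    base = panels[0]
    base_idx = keys(base).get_indexer(shared)
    ref0 = base.snps["ref"].to_numpy()[base_idx]
    alt0 = base.snps["alt"].to_numpy()[base_idx]

    keep = np.ones(len(shared), dtype=bool)
    blocks = [base.calls[:, base_idx]]
    for p in panels[1:]:
        idx = keys(p).get_indexer(shared)
        ref, alt = p.snps["ref"].to_numpy()[idx], p.snps["alt"].to_numpy()[idx]
        calls = p.calls[:, idx].copy()
        same = (ref == ref0) & (alt == alt0)
        swapped = (ref == alt0) & (alt == ref0)
        flip = swapped & ~same
        if flip.any():
            col = calls[:, flip]
            miss = col == MISSING
            col = 2 - col
            col[miss] = MISSING
            calls[:, flip] = col
        bad = ~(same | swapped)
        if bad.any():
            for k in np.flatnonzero(bad)[:20]:
                logger.warning(
                    "dropping SNP %s:%s — irreconcilable alleles %s/%s vs %s/%s",
                    shared[k][0], shared[k][1], ref0[k], alt0[k], ref[k], alt[k],
                )
            keep &= ~bad
        blocks.append(calls)
    if not keep.any():
        raise EmptyPanelError("no SNPs with reconcilable alleles remain")

    snps = pd.DataFrame({
        "chrom": [k[0] for k in shared], "pos": [k[1] for k in shared],
        "ref": ref0, "alt": alt0,
    }).iloc[np.flatnonzero(keep)]
    calls = np.concatenate([b[:, keep] for b in blocks], axis=0)
    samples = pd.concat([p.samples for p in panels], ignore_index=True)
    order = np.lexsort((snps["pos"], snps["chrom"]))
    return GenotypeMatrix(samples, snps.iloc[order], calls[:, order])


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    gm: GenotypeMatrix, group: str | None = None
) -> np.ndarray:
    """Per-SNP alternate-allele frequency p_i = alt count / (2 x non-missing).

    With ``group`` given, only animals of that population contribute.  SNPs
    with no called animal in the group get ``nan`` (frequency undefined).
    """
    if group is not None:
        mask = gm.population_mask(group)
        if not mask.any():
            raise KeyError(f"no animals in population {group!r}")
        calls = gm.calls[mask]
    else:
        calls = gm.calls
    observed = calls != MISSING
    n_called = observed.sum(axis=0)
    alt = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return p


def minor_allele_frequencies(gm_or_freq) -> np.ndarray:
    p = (
        allele_frequencies(gm_or_freq)
        if isinstance(gm_or_freq, GenotypeMatrix)
        else np.asarray(gm_or_freq, dtype=float)
    )
    return np.minimum(p, 1.0 - p)
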