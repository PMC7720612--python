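"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order mirroring a standard panel workflow:
QC -> GRM/PCA -> supervised admixture -> FST/FIS -> LD/Ne.  The GRM is
computed before the LD stage so that relatedness pruning for Ne uses the
same relationship definition as the PCA.  Every stage's outputs are pure
functions of (inputs, config, seed); a manifest records the seed, input
digests, thresholds and per-stage counts so runs are reproducible and
auditable.  A stage failure aborts the run with the stage name and cause,
leaving prior outputs plus a ``.partial`` marker in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import ReferenceSpec, fit_supervised_admixture
from .fstats import cluster_fst, dendrogram_newick, fst_fis_matrix
from .genio import QCConfig, qc_filter, read_genotypes
from .grmpca import compute_grm, pca_grm, prune_related
from .ldne import MIN_SAMPLE_SIZE, ld_decay_table, ld_scan, ne_trajectory

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every threshold is echoed into the manifest."""

    input_path: str
    input_format: str = "vcf"
    population_map: str | None = None      # TSV: animal <tab> population
    output_dir: str = "results"
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    run_grm_pca: bool = True
    n_components: int = 5
    admixture_references: dict[str, list[str]] | None = None
    run_fst: bool = True
    run_ld_ne: bool = True
    ld_populations: list[str] | None = None
    relatedness_threshold: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QCConfig(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)


def _load_population_map(path: str | None) -> dict[str, str] | None:
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t", header=None, names=["animal", "population"])
    return dict(zip(df["animal"], df["population"]))


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    partial.touch()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "input": str(config.input_path),
        "input_digest": _digest(config.input_path),
        "thresholds": {
            "snp_call_rate_min": config.qc.snp_call_rate_min,
            "animal_call_rate_min": config.qc.animal_call_rate_min,
            "autosomes_only": config.qc.autosomes_only,
            "maf_min_for_ld": config.qc.maf_min_for_ld,
            "relatedness_threshold": config.relatedness_threshold,
        },
        "stages": {},
    }
    stage = "load"
    try:
        pops = _load_population_map(config.population_map)
        gm, panel = read_genotypes(config.input_path, config.input_format, pops)
        manifest["stages"]["load"] = {
            "n_animals": gm.n_animals, "n_snps": gm.n_snps,
            "phased": panel is not None,
        }

        stage = "qc"
        gm, report = qc_filter(gm, config.qc)
        if panel is not None:
            # keep the phased panel aligned with the QC'd genotypes
            snp_keep = pd.MultiIndex.from_frame(panel.snps[["chrom", "pos"]]) \
                .get_indexer(pd.MultiIndex.from_frame(gm.snps[["chrom", "pos"]]))
            panel = type(panel)(panel.samples, panel.snps.iloc[snp_keep],
                                panel.calls[:, snp_keep])
            panel = panel.subset_animals(
                panel.samples["id"].isin(gm.samples["id"]).to_numpy()
            )
        report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "n_animals": gm.n_animals, "n_snps": gm.n_snps,
            "snps_nonautosomal": report.n_snps_nonautosomal,
            "snps_low_call_rate": report.n_snps_low_call_rate,
            "animals_low_call_rate": report.n_animals_low_call_rate,
        }

        grm = None
        if config.run_grm_pca:
            stage = "grm_pca"
            grm = compute_grm(gm)
            grm_df = grm.to_frame()
            grm_df.to_csv(outdir / "grm.tsv", sep="\t")
            pca = pca_grm(grm, min(config.n_components, grm.n))
            scores = pca.scores_frame()
            scores.insert(1, "population", list(gm.samples["population"]))
            scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
            pd.DataFrame({
                "eigenvalue": pca.eigenvalues,
                "variance_fraction": pca.variance_fractions,
            }).to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index=False)
            manifest["stages"]["grm_pca"] = {
                "d": grm.d,
                "variance_fractions_reported": [
                    round(float(v), 6)
                    for v in pca.variance_fractions[: config.n_components]
                ],
            }

        if config.admixture_references:
            stage = "admixture"
            ref = ReferenceSpec(config.admixture_references)
            model = fit_supervised_admixture(gm, ref)
            qdf = model.q_frame(list(gm.samples["population"]))
            qdf.to_csv(outdir / "admixture_q.tsv", sep="\t", index=False)
            manifest["stages"]["admixture"] = {
                "k": model.k,
                "iterations": len(model.loglik_trace) - 1,
                "converged": model.converged,
                "final_loglik": model.loglik_trace[-1],
            }

        if config.run_fst:
            stage = "fst"
            fst = fst_fis_matrix(gm)
            fst.to_frame().to_csv(outdir / "fst_fis_matrix.tsv", sep="\t")
            if len(fst.labels) >= 2 and not np.isnan(fst.matrix).any():
                z, leaf_order = cluster_fst(fst)
                (outdir / "fst_dendrogram.nwk").write_text(
                    dendrogram_newick(z, sorted(fst.labels)) + "\n"
                )
                manifest["stages"]["fst"] = {
                    "n_populations": len(fst.labels), "leaf_order": leaf_order,
                }
            else:
                manifest["stages"]["fst"] = {"n_populations": len(fst.labels)}

        if config.run_ld_ne:
            stage = "ld_ne"
            if panel is None:
                raise ValueError("LD/Ne stage requires phased input")
            ld_info: dict = {}
            targets = config.ld_populations or [
                p for p in gm.populations()
                if (gm.samples["population"] == p).sum() >= MIN_SAMPLE_SIZE
            ]
            for pop in targets:
                sub = panel.subset_animals(panel.population_mask(pop))
                n = sub.n_animals
                pairs = ld_scan(sub, maf_min=config.qc.maf_min_for_ld)
                if pairs.empty:
                    ld_info[pop] = {"n_pairs": 0}
                    continue
                decay = ld_decay_table(pairs, n_diploids=n)
                decay.to_csv(outdir / f"ld_decay_{pop}.tsv", sep="\t",
                             index=False)
                traj = ne_trajectory(
                    panel, pop,
                    maf_min=config.qc.maf_min_for_ld,
                    relatedness_threshold=config.relatedness_threshold,
                )
                traj.to_frame().to_csv(outdir / f"ne_trajectory_{pop}.tsv",
                                       sep="\t", index=False)
                ld_info[pop] = {
                    "n_pairs": int(len(pairs)),
                    "sample_size_after_pruning": traj.sample_size,
                    "n_bins": len(traj.bins),
                }
            manifest["stages"]["ld_ne"] = ld_info
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    partial.unlink(missing_ok=True)
    return manifest
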