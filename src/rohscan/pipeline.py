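"""End-to-end orchestration: ingest/simulate -> QC -> ROH -> F_ROH -> islands -> GWAS.

Stages run in the fixed order QC (both profiles), ROH calling, genomic
inbreeding, island detection, association scans.  Every stage writes its
table under the output directory and a manifest records inputs, parameters
and the seed so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (
    compute_kinship,
    compute_pcs,
    genotype_trait_summary,
    glm_scan,
    mlm_scan,
)
from .datatypes import PhenotypeTable
from .genio import read_phenotypes, read_plink_bed, read_plink_text
from .inbreeding import (
    BOS_TAURUS_AUTOSOME_BP,
    froh_per_animal,
    froh_population_summary,
)
from .islands import detect_islands, island_report, islands_to_bed, snp_in_roh_frequency
from .qc import QCConfig, build_dataset
from .rohcall import ROHParams, call_roh_all, segments_to_bed, segments_to_dataframe, summarize_roh
from .simdata import QTLSpec, SimConfig, simulate_dataset, simulate_phenotype

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full-run configuration; every filtering parameter is surfaced."""

    bfile: str | None = None            # PLINK prefix (binary; falls back to text)
    pheno: str | None = None            # phenotype TSV
    simulate: SimConfig | None = None   # generate data instead of reading
    sim_qtl: QTLSpec | None = None      # phenotype model for simulated data
    qc_gwas: QCConfig = field(default_factory=lambda: QCConfig(profile="gwas"))
    qc_roh: QCConfig = field(default_factory=lambda: QCConfig(profile="roh"))
    roh: ROHParams = field(default_factory=ROHParams)
    island_threshold_pct: float = 30.0
    island_min_markers: int = 1
    autosome_length_bp: int = BOS_TAURUS_AUTOSOME_BP
    traits: list = field(default_factory=list)
    model: str = "mlm"                  # "glm" or "mlm"
    n_pcs: int = 3
    alpha: float = 0.01
    out_dir: str = "rohscan_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            if "sweep_regions" in sim:
                sim["sweep_regions"] = tuple(tuple(r) for r in sim["sweep_regions"])
            kwargs["simulate"] = SimConfig(**sim)
        if "sim_qtl" in kwargs and kwargs["sim_qtl"] is not None:
            kwargs["sim_qtl"] = QTLSpec(**kwargs["sim_qtl"])
        for key, klass in (("qc_gwas", QCConfig), ("qc_roh", QCConfig),
                           ("roh", ROHParams)):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


@dataclass
class RunReport:
    qc_reports: dict
    roh_summary: object
    froh_table: pd.DataFrame
    froh_stats: pd.DataFrame
    islands: pd.DataFrame
    assoc: dict                      # trait -> AssocResult
    variance_components: dict        # trait -> VarianceComponents | None
    significant_hits: pd.DataFrame
    manifest: dict


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        g, m, truth, pool = simulate_dataset(cfg.simulate)
        pheno = None
        if cfg.sim_qtl is not None:
            y, realized = simulate_phenotype(g, cfg.sim_qtl, seed=cfg.seed + 17)
            pheno = PhenotypeTable(
                pd.DataFrame({"sim_trait": y}, index=pd.Index(g.samples, name="sample_id"))
            )
            log.info("simulated phenotype: %s", realized)
        return g, m, pheno, truth
    if cfg.bfile is None:
        raise ValueError("PipelineConfig needs either bfile or simulate")
    prefix = Path(cfg.bfile)
    if prefix.with_suffix(".bed").exists():
        g, m = read_plink_bed(prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
                              prefix.with_suffix(".fam"))
    else:
        g, m = read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    pheno = read_phenotypes(cfg.pheno, genotype_samples=g.samples) if cfg.pheno else None
    return g, m, pheno, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g_raw, m_raw, pheno, truth = _load_inputs(cfg)

    # --- QC, both profiles -------------------------------------------------
    g_gwas, m_gwas, rep_gwas = build_dataset(g_raw, m_raw, cfg.qc_gwas)
    g_roh, m_roh, rep_roh = build_dataset(g_raw, m_raw, cfg.qc_roh)
    qc_reports = {"gwas": rep_gwas, "roh": rep_roh}
    for name, rep in qc_reports.items():
        (out / f"qc_{name}.json").write_text(json.dumps(rep.to_dict(), indent=2))

    # --- ROH / inbreeding / islands ---------------------------------------
    segments = call_roh_all(g_roh, m_roh, cfg.roh)
    seg_df = segments_to_dataframe(segments)
    seg_df.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    segments_to_bed(segments, out / "roh_segments.bed")
    summary = summarize_roh(segments, g_roh.samples)
    summary.per_animal.to_csv(out / "roh_per_animal.tsv", sep="\t")
    summary.class_stats.to_csv(out / "roh_class_stats.tsv", sep="\t", index=False)

    froh_table = froh_per_animal(segments, g_roh.samples, cfg.autosome_length_bp)
    froh_table.to_csv(out / "froh.tsv", sep="\t", index_label="sample_id")
    froh_stats = froh_population_summary(froh_table)
    froh_stats.to_csv(out / "froh_stats.tsv", sep="\t")

    track = snp_in_roh_frequency(segments, m_roh, g_roh.n_samples)
    track.to_csv(out / "snp_in_roh.tsv", sep="\t", index=False)
    isl = detect_islands(track, cfg.island_threshold_pct, cfg.island_min_markers)
    isl_df = island_report(isl)
    isl_df.to_csv(out / "islands.tsv", sep="\t", index=False)
    islands_to_bed(isl, out / "islands.bed")

    # --- GWAS ---------------------------------------------------------------
    assoc_results: dict = {}
    vcs: dict = {}
    hit_rows = []
    traits = cfg.traits or (pheno.trait_names if pheno is not None else [])
    if pheno is None or not traits:
        log.info("no phenotypes: GWAS stage skipped")
    else:
        pcs = compute_pcs(g_gwas, cfg.n_pcs)
        K = compute_kinship(g_gwas)
        for trait in traits:
            y = pheno.aligned_to(g_gwas.samples)[trait].to_numpy(dtype=float)
            if cfg.model == "glm":
                res = glm_scan(g_gwas, y, covariates=pcs, m=m_gwas, alpha=cfg.alpha)
                vc = None
            else:
                res, vc = mlm_scan(g_gwas, y, K, covariates=pcs, m=m_gwas,
                                   alpha=cfg.alpha)
            assoc_results[trait] = res
            vcs[trait] = vc
            res.table.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            for mid in res.significant_markers:
                j = int(np.flatnonzero(m_gwas.marker_id == mid)[0])
                strat = genotype_trait_summary(
                    g_gwas.dosage[:, j], (m_gwas.allele_a[j], m_gwas.allele_b[j]), y
                )
                row = res.table[res.table["marker_id"] == mid].iloc[0]
                hit_rows.append(
                    {"trait": trait, "marker_id": mid, "chrom": row["chrom"],
                     "pos_bp": row["pos_bp"], "model": res.model,
                     "p": row["p"], "beta": row["beta"],
                     "genotype_means": strat["mean"].round(4).to_dict(),
                     "genotype_n": strat["n"].to_dict()}
                )
    hits = pd.DataFrame(hit_rows)
    hits.to_csv(out / "significant_hits.tsv", sep="\t", index=False)

    manifest = {
        "rohscan_version": __version__,
        "seed": cfg.seed,
        "config": _config_to_jsonable(cfg),
        "stages": ["qc_gwas", "qc_roh", "roh", "froh", "islands"]
        + (["gwas"] if assoc_results else []),
        "n_samples_raw": g_raw.n_samples,
        "n_markers_raw": g_raw.n_markers,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunReport(
        qc_reports=qc_reports,
        roh_summary=summary,
        froh_table=froh_table,
        froh_stats=froh_stats,
        islands=isl_df,
        assoc=assoc_results,
        variance_components=vcs,
        significant_hits=hits,
        manifest=manifest,
    )


def _config_to_jsonable(cfg: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return conv(cfg)
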