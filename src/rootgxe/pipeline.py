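"""End-to-end pipeline: simulate/load -> indices -> G×E -> correlations ->
introgression scan -> hot spots -> QTL enrichment.

Every stage writes its outputs under ``out_dir`` and contributes record
counts to a JSON run manifest, so a fixed seed reproduces the whole run
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlate import count_significant, pairwise_correlations
from .enrich import enrich_region
from .gxe import (ammi_decompose, cluster_dendrogram, gge_decompose,
                  impute_missing, ss_partition_percent)
from .phenotype import STRESS_INDEX_DEFS, ls_means, stress_indices
from .scan import (block_association, detect_hotspots, filter_significant,
                   merge_regions)
from .simulate import SimulationConfig, gen_blocks, gen_phenotype, gen_qtl_annotations
from . import io as rio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the published procedure
    (P < 0.001 scan cutoff, >= 5 aligned traits for a hot spot, 20 cm deep-root
    cutoff, window population of 3680 for externally supplied annotations)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    phenotypes_path: str | None = None   # observations TSV; overrides simulation
    blocks_path: str | None = None
    annotations_path: str | None = None
    alpha_scan: float = 0.001
    alpha_corr: float = 0.05
    min_traits: int = 5
    deep_root_cutoff_cm: float = 20.0
    population_total: int | None = None  # default: window universe size
    qtl_window_counts: tuple = (28, 42, 56, 2, 60, 22, 97, 13, 120)
    imputation_rank: int = 2
    out_dir: str = "rootgxe_out"
    seed: int | None = None              # overrides simulation.seed
    log_level: str = "INFO"

    def __post_init__(self):
        for name, val in (("alpha_scan", self.alpha_scan),
                          ("alpha_corr", self.alpha_corr)):
            if not 0 < val <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.deep_root_cutoff_cm <= 0:
            raise ValueError("deep_root_cutoff_cm must be positive")
        if self.min_traits < 1:
            raise ValueError("min_traits must be >= 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_pipeline_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        if "causal_windows" in sim:
            sim["causal_windows"] = [tuple(c) for c in sim["causal_windows"]]
        raw["simulation"] = SimulationConfig(**sim)
    if "qtl_window_counts" in raw:
        raw["qtl_window_counts"] = tuple(raw["qtl_window_counts"])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "rootgxe",
        "version": __version__,
        "lib_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "inputs": {},
        "stages": {},
    }
    sim = config.simulation
    if config.seed is not None:
        sim = dataclasses.replace(sim, seed=config.seed)
    manifest["seed"] = sim.seed

    # ---- stage: load or simulate ------------------------------------------
    try:
        if config.phenotypes_path:
            obs = rio.read_observations_tsv(config.phenotypes_path)
            manifest["inputs"]["phenotypes"] = _sha256(config.phenotypes_path)
            truth = None
        else:
            obs, truth = gen_phenotype(sim)
            rio.write_observations_tsv(obs, out / "observations.tsv")
        if config.blocks_path:
            blocks = rio.read_blocks_tsv(config.blocks_path)
            manifest["inputs"]["blocks"] = _sha256(config.blocks_path)
        else:
            blocks = gen_blocks(sim)
            rio.write_blocks_tsv(blocks, out / "blocks.tsv")
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    manifest["stages"]["load"] = {
        "n_observations": int(len(obs)),
        "n_windows": int(len(blocks.windows)),
    }
    if truth is not None:
        manifest["stages"]["load"]["realized_variance_fractions"] = {
            k: round(v, 6) for k, v in truth.realized_variance_fractions.items()
        }

    # ---- stage: LS means and stress indices -------------------------------
    trait = str(obs["trait"].iloc[0])
    try:
        matrix = ls_means(obs, trait)
        rio.write_phenotype_tsv(matrix, out / f"lsmeans_{trait}.tsv")
    except ValueError as exc:
        raise PipelineError("lsmeans", str(exc)) from exc
    manifest["stages"]["lsmeans"] = {
        "trait": trait,
        "n_genotypes": int(matrix.shape[0]),
        "n_environments": int(matrix.shape[1]),
    }

    indices_rows = 0
    if trait in STRESS_INDEX_DEFS:
        frames = []
        for ctrl in [c for c in matrix.columns if c.endswith("C")]:
            strs = ctrl[:-1] + "S"
            if strs not in matrix.columns:
                continue
            tab = stress_indices({trait: matrix[ctrl]}, {trait: matrix[strs]})
            tab.insert(0, "site", ctrl[:-1])
            frames.append(tab.reset_index())
        if frames:
            idx = pd.concat(frames, ignore_index=True)
            idx.to_csv(out / "stress_indices.tsv", sep="\t", index=False,
                       na_rep="NA", lineterminator="\n")
            indices_rows = len(idx)
    manifest["stages"]["indices"] = {"n_rows": indices_rows}

    # ---- stage: G×E decomposition -----------------------------------------
    try:
        filled = impute_missing(matrix.dropna(how="all"),
                                rank=config.imputation_rank)
        ammi = ammi_decompose(filled)
        gge = gge_decompose(filled)
    except ValueError as exc:
        raise PipelineError("gxe", str(exc)) from exc
    parts = ss_partition_percent(ammi)
    pd.DataFrame([parts]).to_csv(out / "ss_partition.tsv", sep="\t",
                                 index=False, lineterminator="\n")
    ammi.biplot_coordinates().to_csv(out / "biplot_ammi.tsv", sep="\t",
                                     index=False, lineterminator="\n")
    gge.biplot_coordinates().to_csv(out / "biplot_gge.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    rio.write_newick(cluster_dendrogram(filled, "genotypes"),
                     out / "dendrogram_genotypes.nwk")
    rio.write_newick(cluster_dendrogram(filled, "environments"),
                     out / "dendrogram_environments.nwk")
    manifest["stages"]["gxe"] = {k: round(v, 4) for k, v in parts.items()}

    # ---- stage: correlations ----------------------------------------------
    cm = pairwise_correlations(matrix)
    rio.write_correlation_tsvs(cm, out / "corr_r.tsv", out / "corr_p.tsv")
    counts = count_significant(cm, alpha=config.alpha_corr, sign_split=True)
    counts.to_csv(out / "corr_counts.tsv", sep="\t", lineterminator="\n")
    manifest["stages"]["correlations"] = {
        "n_pairs_significant": int((cm.p.to_numpy() < config.alpha_corr).sum() // 2),
    }

    # ---- stage: introgression scan ----------------------------------------
    try:
        records = []
        for env in matrix.columns:
            records.extend(block_association(blocks, matrix[env], trait=trait,
                                             experiment=env))
    except ValueError as exc:
        raise PipelineError("scan", str(exc)) from exc
    rio.write_associations_tsv(records, out / "associations.tsv")
    significant = filter_significant(records, alpha=config.alpha_scan)
    regions = merge_regions(significant)
    rio.write_regions_bed(regions, out / "regions.bed")
    hotspots = detect_hotspots(regions, min_traits=config.min_traits)
    rio.write_hotspots_bed(hotspots, out / "hotspots.bed")
    manifest["stages"]["scan"] = {
        "n_tested": len(records),
        "n_significant_blocks": len(significant),
        "n_regions": len(regions),
        "n_hotspots": len(hotspots),
    }

    # ---- stage: QTL enrichment --------------------------------------------
    universe = list(blocks.windows.index)
    pop_total = config.population_total or len(universe)
    try:
        if config.annotations_path:
            annotations = rio.read_annotations_tsv(config.annotations_path)
            manifest["inputs"]["annotations"] = _sha256(config.annotations_path)
        else:
            counts_feasible = tuple(min(c, len(universe)) for c in
                                    config.qtl_window_counts)
            annotations = gen_qtl_annotations(counts_feasible,
                                              pop_total=len(universe),
                                              seed=sim.seed, universe=universe)
            rio.write_annotations_tsv(annotations, out / "annotations.tsv")
        enrichment = []
        for h in hotspots:
            rid = f"{h.chrom}:{h.start / 1e6:.1f}-{h.end / 1e6:.1f}Mb"
            enrichment.extend(enrich_region(h.windows, annotations, pop_total,
                                            region_id=rid, universe=universe))
    except ValueError as exc:
        raise PipelineError("enrich", str(exc)) from exc
    rio.write_enrichment_tsv(enrichment, out / "enrichment.tsv")
    manifest["stages"]["enrich"] = {"n_records": len(enrichment)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
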