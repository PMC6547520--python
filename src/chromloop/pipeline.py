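"""End-to-end orchestration: simulate/load inputs, run every stage, emit a
JSON metrics summary plus TSV result tables.

The pipeline mirrors the analysis order of the study design it implements:
differential accessibility -> TF-bound OCR subsetting -> chromatin-state and
regulatory-class enrichment -> fragment architecture -> loop annotation,
target-gene mapping and co-regulation topology. All randomness flows from
the seeds recorded in :class:`PipelineConfig`; reruns are bit-identical for
integers and reproducible to float precision otherwise.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .chromstate import anchor_class_enrichment, state_fold_enrichment
from .diffacc import bound_ocrs, differential_regions, split_specific_ocrs
from .fragsig import nfr_fraction
from .intervals import PeakSet
from .loopreg import (classify_coregulation_topology, coregulated_genes,
                      deregulated_fraction, expression_quartiles,
                      filter_and_classify_loops, loop_connected_genes,
                      loops_per_gene, map_ocrs_to_anchors, summarize_topology,
                      target_genes_of_ocrs)
from .sim import SimBundle, SimConfig, simulate_all

logger = logging.getLogger("chromloop")

METRICS_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Thresholds and seeds for a full run; inputs come from a simulation
    bundle (default) or from files via the CLI loaders."""

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    gene_fold_threshold: float = 1.5
    gene_padj_threshold: float = 0.05
    chicago_min: float = 5.0
    fpkm_cut: float = 1.0
    nfr_cut: int = 150
    seed: int = 0
    n_state_shuffles: int = 50
    out_dir: Optional[str] = None
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "gene_fold_threshold",
                     "gene_padj_threshold", "fpkm_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load thresholds/seeds from a YAML mapping; explicit constructor
        arguments (CLI flags) always win over file values, so callers merge
        by passing overrides to ``dataclasses.replace`` afterwards."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        sim_data = data.pop("sim", {})
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for k, v in sim_data.items():
            if not hasattr(cfg.sim, k):
                raise ValueError(f"unknown sim config key: {k}")
            setattr(cfg.sim, k, v)
        return cfg


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def run_pipeline(cfg: PipelineConfig, bundle: Optional[SimBundle] = None) -> dict:
    """Execute every stage on ``bundle`` (generated from cfg.sim when absent)
    and return the metrics dictionary; writes JSON/TSV when out_dir is set."""
    t0 = time.time()
    if bundle is None:
        cfg.sim.seed = cfg.seed
        bundle = simulate_all(cfg.sim)
    genome = bundle.genome
    timings: dict[str, float] = {}

    # --- differential accessibility -------------------------------------
    t = time.time()
    results = differential_regions(bundle.counts, fc_threshold=cfg.fc_threshold,
                                   p_threshold=cfg.p_threshold)
    ctr_ocrs, mt_ocrs = split_specific_ocrs(results)
    timings["diffacc"] = time.time() - t

    # --- TF-bound OCR subsetting ----------------------------------------
    t = time.time()
    if len(ctr_ocrs):
        tf_bound, n_tf_overlap, p_tf = bound_ocrs(ctr_ocrs, bundle.tf_bs, genome)
    else:
        tf_bound, n_tf_overlap, p_tf = PeakSet([], "bound"), 0, float("nan")
    timings["bound_ocrs"] = time.time() - t

    # --- chromatin-state / class enrichment ------------------------------
    t = time.time()
    sites_for_enrich = tf_bound if len(tf_bound) >= 50 else bundle.ocrs
    enrich = state_fold_enrichment(sites_for_enrich, bundle.segmentation,
                                   genome, n_shuffles=cfg.n_state_shuffles,
                                   seed=cfg.seed)
    promoters = PeakSet(
        [_promoter_interval(g, genome) for g in bundle.genes], label="promoter")
    enhancer_rows = bundle.loops.df[bundle.loops.df["oe_is_bait"] == 0]
    enhancers = PeakSet(
        [_iv(r.oe_chr, r.oe_start, r.oe_end)
         for r in enhancer_rows.itertuples()], label="enhancer")
    classes = anchor_class_enrichment(sites_for_enrich, promoters, enhancers,
                                      bundle.tads, genome, seed=cfg.seed)
    timings["chromstate"] = time.time() - t

    # --- fragment architecture -------------------------------------------
    t = time.time()
    nfr = {cond: nfr_fraction(frags, bundle.motif_centers, nfr_cut=cfg.nfr_cut)
           for cond, frags in bundle.fragments.items()}
    timings["fragsig"] = time.time() - t

    # --- loops ------------------------------------------------------------
    t = time.time()
    loops, loop_summary = filter_and_classify_loops(bundle.loops,
                                                    score_min=cfg.chicago_min)
    quartiles = expression_quartiles(bundle.genes, fpkm_cut=cfg.fpkm_cut)
    profiles, per_quartile, p_de_loops = loops_per_gene(loops, bundle.genes,
                                                        quartiles)
    _, n_p63_anchored, n_p63_loops, mean_p63 = map_ocrs_to_anchors(
        bundle.p63_bound_ocrs, loops)
    _, n_ctcf_anchored, n_ctcf_loops, mean_ctcf = map_ocrs_to_anchors(
        bundle.ctcf_bound_ocrs, loops)
    _, p63_targets = target_genes_of_ocrs(bundle.p63_bound_ocrs, loops)
    _, ctcf_targets = target_genes_of_ocrs(bundle.ctcf_bound_ocrs, loops)
    universe = loop_connected_genes(loops)
    coreg, p_coreg = coregulated_genes(p63_targets & universe,
                                       ctcf_targets & universe, universe)
    calls = classify_coregulation_topology(loops, bundle.p63_bound_ocrs,
                                           bundle.ctcf_bound_ocrs)
    topo = summarize_topology(calls)
    n_dereg, frac_dereg = deregulated_fraction(coreg, bundle.genes)
    timings["loopreg"] = time.time() - t

    metrics = {
        "schema_version": METRICS_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_ctr_ocrs": len(ctr_ocrs),
        "n_mt_ocrs": len(mt_ocrs),
        "n_tf_bound_ctr_ocrs": len(tf_bound),
        "p_tf_overlap": p_tf,
        "state_fold_max": max(v for v in enrich.fold.values() if v is not None),
        "class_or_promoter": classes["observed"]["promoter"].odds_ratio,
        "class_or_enhancer": classes["observed"]["enhancer"].odds_ratio,
        "class_or_tad_boundary": classes["observed"]["tad_boundary"].odds_ratio,
        "nfr_frac_control": nfr["control"][0],
        "nfr_frac_mutant": nfr["mutant"][0],
        "mono_frac_control": nfr["control"][1],
        "mono_frac_mutant": nfr["mutant"][1],
        "n_loops_retained": loop_summary.n_total,
        "pe_fraction": loop_summary.pe_fraction,
        "pp_fraction": loop_summary.pp_fraction,
        "median_loop_span_bp": loop_summary.median_span_bp,
        "p_de_vs_expressed_loops": p_de_loops,
        "mean_loops_per_quartile": {q: float(np.mean(v)) if v else 0.0
                                    for q, v in per_quartile.items()},
        "n_p63_anchored_ocrs": n_p63_anchored,
        "n_p63_anchor_loops": n_p63_loops,
        "mean_loops_per_p63_ocr": mean_p63,
        "n_ctcf_anchored_ocrs": n_ctcf_anchored,
        "n_ctcf_anchor_loops": n_ctcf_loops,
        "mean_loops_per_ctcf_ocr": mean_ctcf,
        "n_p63_target_genes": len(p63_targets),
        "n_ctcf_target_genes": len(ctcf_targets),
        "n_coregulated_genes": len(coreg),
        "p_coregulated_overlap": p_coreg,
        "topology_gene_fractions": topo["gene_topology_fractions"],
        "topology_loop_fractions": topo["loop_topology_fractions"],
        "gene_class_counts": topo["gene_class_counts"],
        "n_coreg_deregulated": n_dereg,
        "frac_coreg_deregulated": frac_dereg,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    metrics = _round6(metrics)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        _write_tables(out, cfg, results, ctr_ocrs, mt_ocrs, loops, bundle)
        logger.info("pipeline finished in %.2fs -> %s", metrics["total_s"], out)
    return metrics


def _iv(chrom, start, end):
    from .genome import Interval
    return Interval(str(chrom), int(start), int(end))


def _promoter_interval(gene, genome, halfwidth: int = 2000):
    from .genome import Interval
    length = genome.chrom_lengths[gene.chrom]
    return Interval(gene.chrom, max(0, gene.tss - halfwidth),
                    min(length, gene.tss + halfwidth))


def _write_tables(out: Path, cfg: PipelineConfig, results, ctr_ocrs, mt_ocrs,
                  loops, bundle: SimBundle) -> None:
    import pandas as pd

    header = (f"# produced by chromloop pipeline seed={cfg.seed} "
              f"fc={cfg.fc_threshold} p={cfg.p_threshold}\n")
    diff_df = pd.DataFrame([{
        "chrom": r.region.chrom, "start": r.region.start, "end": r.region.end,
        "region_id": r.region.name, "baseMean": r.baseMean,
        "log2FC": r.log2FC, "p": r.p, "padj": r.padj, "direction": r.direction,
    } for r in results])
    with open(out / "diff_regions.tsv", "w") as fh:
        fh.write(header)
        diff_df.to_csv(fh, sep="\t", index=False)
    cio.write_bed(ctr_ocrs, out / "ctr_ocrs.bed")
    cio.write_bed(mt_ocrs, out / "mt_ocrs.bed")
    cio.write_loops(loops, out / "loops_retained.tsv")
    bundle.truth.to_json(out / "sim_truth.json")
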