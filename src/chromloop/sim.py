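"""Seeded synthetic-data generator with machine-readable planted truth.

Everything the pipeline consumes can be generated here at a desk scale
(defaults ~1/10 of a genome-wide study): a small genome, gene models with
planted differentially expressed (DE) genes, an 18-state segmentation, TADs,
consensus OCRs with replicated negative-binomial ATAC counts and planted
differential regions, TF binding sites co-localised with OCRs, paired-end
fragment sets drawn from a nucleosome-free / mononucleosome length mixture
around motif centers, and bait-annotated promoter-capture loops with planted
anchor-occupancy topologies. :class:`SimTruth` records every planted
parameter so downstream stages can be scored on recovery.

One global seed spawns independent per-component substreams, so resizing one
component leaves the others' draws untouched.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chromstate import StateSegmentation, TADSet
from .diffacc import CountMatrix, GeneModel
from .genome import GenomeDef, Interval
from .intervals import PeakSet
from .loopreg import LoopSet


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the study conditions at 1/10 scale."""

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    blacklist_fraction: float = 0.0
    # genes / expression
    n_genes: int = 600
    frac_low_expressed: float = 0.2          # FPKM < 1 (Q0)
    de_gene_fraction: float = 0.1
    de_fold: float = 3.0
    n_expression_samples: int = 2
    # OCRs / counts
    n_ocrs: int = 2000
    ocr_width: int = 500
    frac_diff_ocrs: float = 0.10
    true_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    count_mean_log: float = 5.0              # lognormal baseline, ~150 reads
    count_mean_sd: float = 0.5
    n_replicates: int = 2
    # TF binding sites
    tf_in_ocr_fraction: float = 0.6          # OCRs seeded with a binding site
    tf_bs_width: int = 200
    n_tf_background: int = 500               # extra sites outside OCRs
    # fragments
    frag_n: int = 20_000
    nfr_weight: tuple[float, float] = (0.6, 0.4)   # control, mutant
    nfr_len_mean: float = 80.0
    nfr_len_sd: float = 25.0
    mono_len_mean: float = 190.0
    mono_len_sd: float = 20.0
    frag_center_sd: float = 150.0
    n_motif_centers: int = 200
    # chromatin states / TADs
    n_states: int = 18
    state_seg_mean_len: int = 20_000
    tad_mean_len: int = 800_000
    tad_boundary_halfwidth: int = 10_000
    # loops
    pp_fraction: float = 0.135
    span_log_mean: float = float(np.log(250_900.0))
    span_log_sd: float = 0.8
    score_below_threshold_frac: float = 0.1  # loops failing score >= 5
    quartile_loop_rates: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0)  # Q0..Q4
    de_loop_rate_factor: float = 2.0
    promoter_halfwidth: int = 1_000
    enhancer_width: int = 2_000
    # planted co-regulation topology
    n_topology_genes: Optional[int] = None   # default: n_genes // 4
    topology_mix: tuple[float, float, float] = (0.2, 0.6, 0.2)
    # (opposite_anchors, both_promoter, both_enhancer)

    def validate(self) -> None:
        for name in ("frac_diff_ocrs", "de_gene_fraction", "pp_fraction",
                     "tf_in_ocr_fraction", "frac_low_expressed",
                     "score_below_threshold_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(sum(self.topology_mix) - 1.0) > 1e-9:
            raise ValueError("topology_mix must sum to 1")
        if not all(0.0 <= w <= 1.0 for w in self.nfr_weight):
            raise ValueError("nfr_weight entries must lie in [0,1]")
        if self.n_topology_genes is not None and \
                self.n_topology_genes > self.n_genes:
            raise ValueError("more topology genes than genes")
        if int(self.n_ocrs * self.frac_diff_ocrs) > self.n_ocrs:
            raise ValueError("more differential OCRs than OCRs")


@dataclass
class SimTruth:
    """Planted ground truth for recovery scoring."""

    diff_region_ids: dict[str, str]          # region_id -> ctr_specific|mt_specific
    de_gene_ids: list[str]
    tf_seeded_ocr_ids: list[str]             # OCRs seeded with a binding site
    topology_by_gene: dict[str, str]         # gene_id -> planted topology
    quartile_rates: dict[str, float]
    nfr_weight: dict[str, float]             # condition -> mixture weight

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


@dataclass
class SimBundle:
    genome: GenomeDef
    genes: list[GeneModel]
    segmentation: StateSegmentation
    tads: TADSet
    ocrs: PeakSet
    counts: CountMatrix
    tf_bs: PeakSet                           # generic TF binding sites
    fragments: dict[str, pd.DataFrame]       # condition -> fragment frame
    motif_centers: list[tuple[str, int]]
    loops: LoopSet
    p63_bound_ocrs: PeakSet                  # planted anchor occupancy
    ctcf_bound_ocrs: PeakSet
    truth: SimTruth
    config: SimConfig


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _truncated_normal(rng, mean, sd, size, low=1.0):
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < low
    return out


def simulate_genome(cfg: SimConfig) -> GenomeDef:
    lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}
    return GenomeDef(lengths)


def simulate_genes(cfg: SimConfig, genome: GenomeDef,
                   rng: np.random.Generator) -> tuple[list[GeneModel], list[str]]:
    """Genes on a jittered grid; lognormal FPKM with a planted Q0 tail and a
    planted DE subset (>= de_fold change, split up/down)."""
    names = genome.chrom_names
    per_chrom = int(np.ceil(cfg.n_genes / len(names)))
    genes: list[GeneModel] = []
    gid = 0
    for chrom in names:
        length = genome.chrom_lengths[chrom]
        spacing = length // (per_chrom + 1)
        for k in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            tss = (k + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4 + 1))
            tss = int(np.clip(tss, cfg.promoter_halfwidth,
                              length - cfg.promoter_halfwidth - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id=f"G{gid:04d}", chrom=chrom, tss=tss,
                                   strand=strand))
            gid += 1
    # expression: planted Q0 tail below 1 FPKM, the rest lognormal above it
    n = len(genes)
    low = rng.random(n) < cfg.frac_low_expressed
    base = np.where(low,
                    rng.uniform(0.0, 0.9, n),
                    np.exp(rng.normal(2.0, 1.2, n)) + 1.0)
    de_idx = rng.choice(n, size=int(round(n * cfg.de_gene_fraction)), replace=False)
    de_ids = []
    for i, g in enumerate(genes):
        fold = 1.0
        if i in set(de_idx):
            up = rng.random() < 0.5
            fold = cfg.de_fold if up else 1.0 / cfg.de_fold
            g.de_flag = "up" if up else "down"
            g.de_fold = cfg.de_fold
            de_ids.append(g.gene_id)
        noise = rng.normal(1.0, 0.05, 2 * cfg.n_expression_samples)
        fpkm = {}
        for s in range(cfg.n_expression_samples):
            fpkm[f"ctr_{s + 1}"] = max(0.0, base[i] * noise[s])
            fpkm[f"mt_{s + 1}"] = max(0.0, base[i] * fold *
                                      noise[cfg.n_expression_samples + s])
        g.fpkm_by_sample = fpkm
    return genes, de_ids


def simulate_segmentation(cfg: SimConfig, genome: GenomeDef,
                          rng: np.random.Generator) -> StateSegmentation:
    segments: list[Interval] = []
    for chrom, length in genome.chrom_lengths.items():
        pos = 0
        while pos < length:
            seg_len = int(rng.exponential(cfg.state_seg_mean_len)) + 2_000
            end = min(pos + seg_len, length)
            state = int(rng.integers(1, cfg.n_states + 1))
            segments.append(Interval(chrom, pos, end, name=str(state)))
            pos = end
    return StateSegmentation(segments, genome, n_states=cfg.n_states)


def simulate_tads(cfg: SimConfig, genome: GenomeDef,
                  rng: np.random.Generator) -> TADSet:
    tads: list[Interval] = []
    for chrom, length in genome.chrom_lengths.items():
        pos = 0
        while pos < length:
            tad_len = int(rng.exponential(cfg.tad_mean_len)) + 100_000
            end = min(pos + tad_len, length)
            tads.append(Interval(chrom, pos, end))
            pos = end
    return TADSet(tads, genome, boundary_halfwidth=cfg.tad_boundary_halfwidth)


def simulate_ocrs_and_counts(
    cfg: SimConfig, genome: GenomeDef, rng: np.random.Generator
) -> tuple[PeakSet, CountMatrix, dict[str, str]]:
    """Non-overlapping OCRs on a jittered grid; NB counts with planted
    differential regions (half more accessible in control, half in mutant)."""
    names = genome.chrom_names
    per_chrom = int(np.ceil(cfg.n_ocrs / len(names)))
    intervals: list[Interval] = []
    i = 0
    for chrom in names:
        length = genome.chrom_lengths[chrom]
        spacing = length // (per_chrom + 1)
        if spacing <= cfg.ocr_width:
            raise ValueError("too many OCRs for genome size")
        for k in range(per_chrom):
            if i >= cfg.n_ocrs:
                break
            jitter = int(rng.integers(0, max(1, spacing - cfg.ocr_width)))
            start = k * spacing + jitter
            intervals.append(Interval(chrom, start, start + cfg.ocr_width,
                                      name=f"ocr_{i:05d}"))
            i += 1
    ocrs = PeakSet(intervals, label="consensus_OCR")

    n = len(intervals)
    n_diff = int(round(n * cfg.frac_diff_ocrs))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    truth: dict[str, str] = {}
    lfc = np.zeros(n)
    for j, idx in enumerate(diff_idx):
        # alternate: even -> higher in control (negative mutant/control lfc)
        if j % 2 == 0:
            lfc[idx] = -cfg.true_log2fc
            truth[intervals[idx].name] = "ctr_specific"
        else:
            lfc[idx] = cfg.true_log2fc
            truth[intervals[idx].name] = "mt_specific"

    base = np.exp(rng.normal(cfg.count_mean_log, cfg.count_mean_sd, n))
    mu_ctr = base * np.power(2.0, -lfc / 2.0)
    mu_mt = base * np.power(2.0, lfc / 2.0)
    samples = ([(f"ctr_{r + 1}", "control") for r in range(cfg.n_replicates)]
               + [(f"mt_{r + 1}", "mutant") for r in range(cfg.n_replicates)])
    counts = np.empty((n, len(samples)), dtype=np.int64)
    a = cfg.nb_dispersion
    for j, (_, cond) in enumerate(samples):
        mu = mu_ctr if cond == "control" else mu_mt
        if a > 0:
            # NB as gamma-Poisson: shape 1/a, scale a*mu
            lam = rng.gamma(1.0 / a, a * mu)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    return ocrs, CountMatrix(intervals, samples, counts), truth


def simulate_tf_sites(cfg: SimConfig, genome: GenomeDef, ocrs: PeakSet,
                      rng: np.random.Generator) -> tuple[PeakSet, list[str]]:
    """Binding sites seeded inside a fraction of OCRs plus genomic background."""
    sites: list[Interval] = []
    seeded: list[str] = []
    half = cfg.tf_bs_width // 2
    for iv in ocrs.intervals:
        if rng.random() < cfg.tf_in_ocr_fraction:
            center = int(rng.integers(iv.start + half, iv.end - half))
            sites.append(Interval(iv.chrom, center - half, center + half))
            seeded.append(iv.name)
    names = genome.chrom_names
    for _ in range(cfg.n_tf_background):
        chrom = names[int(rng.integers(len(names)))]
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - cfg.tf_bs_width))
        sites.append(Interval(chrom, start, start + cfg.tf_bs_width))
    return PeakSet(sites, label="TF_BS"), seeded


def simulate_fragments(
    cfg: SimConfig, genome: GenomeDef, centers: list[tuple[str, int]],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-condition fragments: lengths from the NFR/mononucleosome mixture
    (condition-specific NFR weight), midpoints Gaussian around motif centers."""
    out: dict[str, pd.DataFrame] = {}
    centers_arr = np.array([p for _, p in centers])
    chroms = np.array([c for c, _ in centers])
    for cond, w_nfr in zip(("control", "mutant"), cfg.nfr_weight):
        pick = rng.integers(0, len(centers), cfg.frag_n)
        is_nfr = rng.random(cfg.frag_n) < w_nfr
        lengths = np.where(
            is_nfr,
            _truncated_normal(rng, cfg.nfr_len_mean, cfg.nfr_len_sd, cfg.frag_n),
            _truncated_normal(rng, cfg.mono_len_mean, cfg.mono_len_sd, cfg.frag_n),
        ).astype(np.int64)
        lengths = np.maximum(lengths, 1)
        mids = centers_arr[pick] + rng.normal(0, cfg.frag_center_sd,
                                              cfg.frag_n).astype(np.int64)
        starts = mids - lengths // 2
        frag_chroms = chroms[pick]
        # clip into chromosome bounds
        for i in range(cfg.frag_n):
            limit = genome.chrom_lengths[frag_chroms[i]]
            starts[i] = min(max(starts[i], 0), limit - lengths[i])
        out[cond] = pd.DataFrame({
            "chrom": frag_chroms,
            "start": starts,
            "end": starts + lengths,
            "sample_id": f"{cond}_1",
        })
    return out


def _promoter(g: GeneModel, cfg: SimConfig, genome: GenomeDef) -> tuple[int, int]:
    length = genome.chrom_lengths[g.chrom]
    s = max(0, g.tss - cfg.promoter_halfwidth)
    e = min(length, g.tss + cfg.promoter_halfwidth)
    return s, e


def simulate_loops(
    cfg: SimConfig, genome: GenomeDef, genes: list[GeneModel],
    quartiles: dict[str, str], rng: np.random.Generator,
    pp_partner_exclude: Optional[set[str]] = None,
) -> tuple[LoopSet, dict[str, list[int]]]:
    """Loops per gene ~ Poisson with quartile-dependent rate (DE genes get a
    rate multiplier); each loop is PP with probability pp_fraction (other end
    = another gene's promoter), else PE (other end = a distal enhancer at a
    lognormal span from the bait). Genes in ``pp_partner_exclude`` never serve
    as the passive end of a PP loop, so planted anchor occupancy stays
    attributable. Returns the LoopSet and each gene's bait-side row indices.
    """
    exempt = pp_partner_exclude or set()
    partner_pool = [g for g in genes if g.gene_id not in exempt]
    records: list[dict] = []
    owner_rows: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    lid = 0
    for g in genes:
        rate = cfg.quartile_loop_rates[int(quartiles[g.gene_id][1])]
        if g.is_de:
            rate *= cfg.de_loop_rate_factor
        for _ in range(int(rng.poisson(rate))):
            records.append(_loop_record(cfg, genome, partner_pool, g, rng, lid))
            owner_rows[g.gene_id].append(lid)
            lid += 1
    return LoopSet(pd.DataFrame(records)), owner_rows


def _loop_record(cfg: SimConfig, genome: GenomeDef,
                 partner_pool: list[GeneModel], g: GeneModel,
                 rng: np.random.Generator, lid: int) -> dict:
    bait_s, bait_e = _promoter(g, cfg, genome)
    length = genome.chrom_lengths[g.chrom]
    eligible = [p for p in partner_pool if p.gene_id != g.gene_id]
    if eligible and rng.random() < cfg.pp_fraction:
        partner = eligible[int(rng.integers(len(eligible)))]
        oe_s, oe_e = _promoter(partner, cfg, genome)
        oe_chrom, oe_is_bait, oe_genes = partner.chrom, 1, (partner.gene_id,)
    else:
        span = float(np.exp(rng.normal(cfg.span_log_mean, cfg.span_log_sd)))
        sign = -1 if rng.random() < 0.5 else 1
        center = int(np.clip(g.tss + sign * span, cfg.enhancer_width,
                             length - cfg.enhancer_width))
        oe_s = center - cfg.enhancer_width // 2
        oe_e = center + cfg.enhancer_width // 2
        oe_chrom, oe_is_bait, oe_genes = g.chrom, 0, ()
    if rng.random() < cfg.score_below_threshold_frac:
        score = float(rng.uniform(0.0, 5.0))
    else:
        score = float(5.0 + rng.exponential(5.0))
    return dict(bait_chr=g.chrom, bait_start=bait_s, bait_end=bait_e,
                bait_genes=(g.gene_id,), oe_chr=oe_chrom, oe_start=oe_s,
                oe_end=oe_e, oe_is_bait=oe_is_bait, oe_genes=oe_genes,
                score=score, loop_id=f"loop_{lid:05d}")


def plant_topologies(
    cfg: SimConfig, genome: GenomeDef, genes: list[GeneModel], loops: LoopSet,
    owner_rows: dict[str, list[int]], topo_gene_ids: list[str],
    rng: np.random.Generator,
) -> tuple[LoopSet, PeakSet, PeakSet, dict[str, str]]:
    """Plant TF-bound OCRs at loop anchors realising the configured topology
    mix on the chosen genes.

    Each planted gene gets one qualifying promoter-enhancer loop above the
    score threshold (force-added when it has none); small OCR intervals are
    dropped strictly inside the chosen anchors. Returns the (possibly
    extended) LoopSet, the two planted bound-OCR sets and the per-gene truth.
    """
    df = loops.df.copy()
    p63: list[Interval] = []
    ctcf: list[Interval] = []
    truth: dict[str, str] = {}
    new_records: list[dict] = []
    topo_names = ("opposite_anchors", "both_promoter", "both_enhancer")
    probs = np.asarray(cfg.topology_mix)
    gene_by_id = {g.gene_id: g for g in genes}
    next_lid = len(df) + 100_000

    def _inner(chrom: str, s: int, e: int, offset: int = 0,
               width: int = 120) -> Interval:
        mid = (int(s) + int(e)) // 2 + offset
        return Interval(str(chrom), mid - width // 2, mid + width // 2)

    for gid in topo_gene_ids:
        g = gene_by_id[gid]
        pe_rows = [r for r in owner_rows[gid]
                   if df.at[r, "oe_is_bait"] == 0 and df.at[r, "score"] >= 5.0]
        if pe_rows:
            row = df.loc[pe_rows[int(rng.integers(len(pe_rows)))]]
        else:
            rec = _loop_record(cfg, genome, [], g, rng, next_lid)
            rec["score"] = max(rec["score"], 5.0)
            rec["loop_id"] = f"loop_{next_lid:05d}"
            new_records.append(rec)
            next_lid += 1
            row = pd.Series(rec)
        topo = topo_names[int(rng.choice(3, p=probs))]
        truth[gid] = topo
        if topo == "opposite_anchors":
            p63.append(_inner(row["oe_chr"], row["oe_start"], row["oe_end"]))
            ctcf.append(_inner(row["bait_chr"], row["bait_start"], row["bait_end"]))
        elif topo == "both_promoter":
            p63.append(_inner(row["bait_chr"], row["bait_start"],
                              row["bait_end"], offset=-100))
            ctcf.append(_inner(row["bait_chr"], row["bait_start"],
                               row["bait_end"], offset=100))
        else:  # both_enhancer
            p63.append(_inner(row["oe_chr"], row["oe_start"],
                              row["oe_end"], offset=-100))
            ctcf.append(_inner(row["oe_chr"], row["oe_start"],
                               row["oe_end"], offset=100))
    if new_records:
        df = pd.concat([df, pd.DataFrame(new_records)], ignore_index=True)
    return (LoopSet(df),
            PeakSet(p63, label="p63-bound_Ctr-OCR"),
            PeakSet(ctcf, label="CTCF-bound_Ctr-OCR"),
            truth)


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate the full input bundle deterministically from ``cfg.seed``."""
    cfg.validate()
    n_topo = (cfg.n_topology_genes if cfg.n_topology_genes is not None
              else cfg.n_genes // 4)
    (rng_genes, rng_seg, rng_tad, rng_ocr, rng_tf, rng_frag, rng_loop,
     rng_topo) = _spawn(cfg.seed, 8)

    genome = simulate_genome(cfg)
    genes, de_ids = simulate_genes(cfg, genome, rng_genes)
    segmentation = simulate_segmentation(cfg, genome, rng_seg)
    tads = simulate_tads(cfg, genome, rng_tad)
    ocrs, counts, diff_truth = simulate_ocrs_and_counts(cfg, genome, rng_ocr)
    tf_bs, seeded = simulate_tf_sites(cfg, genome, ocrs, rng_tf)

    motif_centers = [(iv.chrom, iv.midpoint) for iv in
                     rng_frag.choice(np.array(ocrs.intervals, dtype=object),
                                     size=min(cfg.n_motif_centers, len(ocrs)),
                                     replace=False)]
    fragments = simulate_fragments(cfg, genome, motif_centers, rng_frag)

    from .loopreg import expression_quartiles  # late import, cycle-free

    topo_gene_ids = sorted(
        g.gene_id for g in rng_topo.choice(np.array(genes, dtype=object),
                                           size=n_topo,
                                           replace=False))
    quartiles = expression_quartiles(genes)
    loops, owner_rows = simulate_loops(cfg, genome, genes, quartiles, rng_loop,
                                       pp_partner_exclude=set(topo_gene_ids))
    loops, p63_ocrs, ctcf_ocrs, topo_truth = plant_topologies(
        cfg, genome, genes, loops, owner_rows, topo_gene_ids, rng_topo)

    truth = SimTruth(
        diff_region_ids=diff_truth,
        de_gene_ids=de_ids,
        tf_seeded_ocr_ids=seeded,
        topology_by_gene=topo_truth,
        quartile_rates={f"Q{i}": r for i, r in enumerate(cfg.quartile_loop_rates)},
        nfr_weight={"control": cfg.nfr_weight[0], "mutant": cfg.nfr_weight[1]},
    )
    return SimBundle(
        genome=genome, genes=genes, segmentation=segmentation, tads=tads,
        ocrs=ocrs, counts=counts, tf_bs=tf_bs, fragments=fragments,
        motif_centers=motif_centers, loops=loops, p63_bound_ocrs=p63_ocrs,
        ctcf_bound_ocrs=ctcf_ocrs, truth=truth, config=cfg,
    )


def fixture_from_counts(n_ocrs: int, n_loops: int, incidence_total: int,
                        chrom: str = "chr1") -> tuple[PeakSet, LoopSet]:
    """Deterministic OCR/loop fixture replaying a printed accounting triple.

    Builds exactly ``n_ocrs`` anchored OCRs whose distinct-loop incidences sum
    to ``incidence_total`` over a union of exactly ``n_loops`` loops. Every
    loop's other end occupies one 500 bp slot on a 2 kb grid; an OCR with k
    incidences spans k consecutive slots — its own fresh slots, extended
    leftward over already-used slots once loops are exhausted.
    """
    if incidence_total < n_ocrs or n_loops > incidence_total or n_loops < 1:
        raise ValueError("infeasible (n_ocrs, n_loops, incidence_total) triple")
    base = incidence_total // n_ocrs
    extra = incidence_total - base * n_ocrs
    per_ocr = [base + (1 if i < extra else 0) for i in range(n_ocrs)]
    if max(per_ocr) > n_loops:
        raise ValueError("infeasible triple: an OCR would need more distinct "
                         "loops than exist")

    slot = 2_000
    records = []
    for j in range(n_loops):
        s = j * slot
        records.append(dict(
            bait_chr=chrom,
            bait_start=n_loops * slot + 50_000 + j * 5_000,
            bait_end=n_loops * slot + 50_000 + j * 5_000 + 2_000,
            bait_genes=(f"G{j:05d}",), oe_chr=chrom, oe_start=s,
            oe_end=s + 500, oe_is_bait=0, oe_genes=(), score=6.0,
            loop_id=f"loop_{j:05d}"))

    ocr_ivs: list[Interval] = []
    next_fresh = 0
    for i, k in enumerate(per_ocr):
        fresh = min(k, n_loops - next_fresh)
        reuse = k - fresh
        first_slot = next_fresh - reuse
        last_slot = next_fresh + fresh - 1
        if first_slot < 0:
            raise ValueError("infeasible triple: cannot realise reuse layout")
        ocr_ivs.append(Interval(chrom, first_slot * slot,
                                last_slot * slot + 500, name=f"ocr_{i}"))
        next_fresh += fresh
    if next_fresh != n_loops:
        raise ValueError("infeasible triple: distinct-loop union short")
    return PeakSet(ocr_ivs, label="fixture_OCR"), LoopSet(pd.DataFrame(records))
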