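"""Promoter-capture Hi-C loop annotation and co-regulation topology.

A loop links a *bait* (a captured gene promoter, annotated with its gene ids)
to an *other end* — either a distal region (promoter–enhancer, PE) or another
bait (promoter–promoter, PP). Loops below the interaction-confidence score
threshold (CHiCAGO-style score, default >= 5) are discarded up front.

The integrative questions answered here: which OCRs sit at loop anchors and
how many loops each touches; which genes an anchored OCR can regulate
(through the loop to the bait's genes, or directly when the OCR sits in a
promoter); whether highly expressed / differentially expressed genes carry
more loops; and, for genes reached by two transcription factors, whether the
two TF-bound OCR sets meet on the *same* loop (at opposite anchors, both at
the promoter, or both at the enhancer) or only on *different* loops.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .diffacc import GeneModel
from .intervals import PeakSet, hypergeom_set_overlap, rank_test

LOOP_TYPES = ("PE", "PP")
TOPOLOGIES = ("opposite_anchors", "both_promoter", "both_enhancer")
GENE_CLASSES = ("same_loop", "different_loops", "single_tf", "none")


class LoopSet:
    """Loops stored columnar: bait_chr/start/end, bait_genes (tuple), oe_*,
    oe_is_bait (0/1), oe_genes (tuple, PP only), score, loop_id."""

    def __init__(self, df: pd.DataFrame):
        if df["loop_id"].duplicated().any():
            raise ValueError("duplicate loop_id")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def loop_type(self) -> pd.Series:
        return np.where(self.df["oe_is_bait"] == 1, "PP", "PE")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "LoopSet":
        return cls(pd.DataFrame(list(records)))

    def anchor_tree(self) -> dict[str, IntervalTree]:
        """Interval trees over both anchors; payload (row index, side)."""
        trees: dict[str, IntervalTree] = {}
        for i, row in enumerate(self.df.itertuples()):
            trees.setdefault(row.bait_chr, IntervalTree()).addi(
                row.bait_start, row.bait_end, (i, "bait"))
            trees.setdefault(row.oe_chr, IntervalTree()).addi(
                row.oe_start, row.oe_end, (i, "oe"))
        return trees


@dataclass
class LoopSummary:
    n_total: int
    n_pe: int
    n_pp: int
    pe_fraction: float
    pp_fraction: float
    median_span_bp: Optional[float]  # cis loops only; None if no cis loop


@dataclass
class GeneLoopProfile:
    gene_id: str
    n_loops: int
    quartile: str  # Q0..Q4
    p63_target: bool = False
    ctcf_target: bool = False


@dataclass
class TopologyCall:
    gene_id: str
    gene_class: str  # same_loop | different_loops | single_tf | none
    per_loop: list[tuple[str, str]] = field(default_factory=list)  # (loop_id, topology)


def filter_and_classify_loops(raw: LoopSet, score_min: float = 5.0
                              ) -> tuple[LoopSet, LoopSummary]:
    """Drop sub-threshold loops (>= is inclusive) and summarise types/spans."""
    kept = LoopSet(raw.df[raw.df["score"] >= score_min])
    df = kept.df
    n = len(df)
    n_pp = int((df["oe_is_bait"] == 1).sum())
    n_pe = n - n_pp
    cis = df[df["bait_chr"] == df["oe_chr"]]
    if len(cis):
        bait_mid = (cis["bait_start"] + cis["bait_end"]) // 2
        oe_mid = (cis["oe_start"] + cis["oe_end"]) // 2
        median_span = float(np.median(np.abs(oe_mid - bait_mid)))
    else:
        median_span = None
    summary = LoopSummary(
        n_total=n, n_pe=n_pe, n_pp=n_pp,
        pe_fraction=n_pe / n if n else 0.0,
        pp_fraction=n_pp / n if n else 0.0,
        median_span_bp=median_span,
    )
    return kept, summary


def _ocr_loop_incidence(ocrs: PeakSet, loops: LoopSet
                        ) -> dict[int, dict[str, set[str]]]:
    """Per OCR index: {"bait": loop_ids overlapped on bait side,
    "oe": loop_ids overlapped on other-end side}."""
    trees = loops.anchor_tree()
    loop_ids = loops.df["loop_id"].to_numpy()
    out: dict[int, dict[str, set[str]]] = {}
    for i, iv in enumerate(ocrs.intervals):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hit: dict[str, set[str]] = {"bait": set(), "oe": set()}
        for entry in tree.overlap(iv.start, iv.end):
            row, side = entry.data
            hit[side].add(loop_ids[row])
        if hit["bait"] or hit["oe"]:
            out[i] = hit
    return out


def map_ocrs_to_anchors(ocrs: PeakSet, loops: LoopSet
                        ) -> tuple[dict[int, set[str]], int, int, float]:
    """OCR -> distinct anchored loop ids, with the headline accounting.

    Returns (incidence, n_anchored_ocrs, n_anchored_loops, mean_loops_per_ocr);
    a loop touched by one OCR at both anchors counts once for that OCR, and
    the mean is total incidences / anchored OCRs rounded to one decimal.
    """
    raw = _ocr_loop_incidence(ocrs, loops)
    incidence = {i: hit["bait"] | hit["oe"] for i, hit in raw.items()}
    n_anchored = len(incidence)
    union: set[str] = set()
    total = 0
    for s in incidence.values():
        union |= s
        total += len(s)
    mean = round(total / n_anchored, 1) if n_anchored else 0.0
    return incidence, n_anchored, len(union), mean


def expression_quartiles(genes: Sequence[GeneModel],
                         sample_ids: Optional[Sequence[str]] = None,
                         fpkm_cut: float = 1.0) -> dict[str, str]:
    """Q0 for FPKM < cut; expressed genes rank-split into Q1 (lowest) .. Q4.

    Ties are broken by gene_id order so the split is deterministic; group
    sizes differ by at most 1.
    """
    fpkm = {g.gene_id: g.mean_fpkm(sample_ids) for g in genes}
    labels = {gid: "Q0" for gid, v in fpkm.items() if v < fpkm_cut}
    expressed = sorted((v, gid) for gid, v in fpkm.items() if v >= fpkm_cut)
    n = len(expressed)
    for rank, (_, gid) in enumerate(expressed):
        labels[gid] = f"Q{1 + min(3, rank * 4 // n)}" if n else "Q0"
    return labels


def loops_per_gene(
    loops: LoopSet,
    genes: Sequence[GeneModel],
    quartiles: Optional[dict[str, str]] = None,
) -> tuple[list[GeneLoopProfile], dict[str, list[int]], float]:
    """Distinct-loop count per gene, per-quartile distributions, and the
    two-sided rank test of DE-gene loop counts vs all expressed genes.

    A gene owns a loop when it appears among the bait's genes; PP loops count
    for the genes of both ends.
    """
    known = {g.gene_id for g in genes}
    quartiles = quartiles if quartiles is not None else expression_quartiles(genes)
    n_loops: dict[str, int] = {g.gene_id: 0 for g in genes}
    for row in loops.df.itertuples():
        owners = set(row.bait_genes) | (set(row.oe_genes) if row.oe_is_bait else set())
        for gid in owners:
            if gid in known:
                n_loops[gid] += 1
    profiles = [GeneLoopProfile(g.gene_id, n_loops[g.gene_id],
                                quartiles.get(g.gene_id, "Q0"))
                for g in genes]
    per_quartile: dict[str, list[int]] = {f"Q{i}": [] for i in range(5)}
    for p in profiles:
        per_quartile[p.quartile].append(p.n_loops)
    de_counts = [n_loops[g.gene_id] for g in genes if g.is_de]
    expr_counts = [p.n_loops for p in profiles if p.quartile != "Q0"]
    p_de = (rank_test(de_counts, expr_counts, mode="normal_approx")
            if de_counts and expr_counts else float("nan"))
    return profiles, per_quartile, p_de


def target_genes_of_ocrs(ocrs: PeakSet, loops: LoopSet
                         ) -> tuple[dict[int, set[str]], set[str]]:
    """Loop-mediated target genes of each anchored OCR.

    An OCR at the other end of a loop targets the paired bait's genes; an OCR
    inside a bait (promoter) targets that bait's own genes directly, plus —
    for PP loops — the genes of the interacting promoter.
    """
    raw = _ocr_loop_incidence(ocrs, loops)
    by_id = loops.df.set_index("loop_id")
    targets: dict[int, set[str]] = {}
    for i, hit in raw.items():
        genes: set[str] = set()
        for lid in hit["oe"]:
            genes.update(by_id.at[lid, "bait_genes"])
        for lid in hit["bait"]:
            genes.update(by_id.at[lid, "bait_genes"])
            if by_id.at[lid, "oe_is_bait"] == 1:
                genes.update(by_id.at[lid, "oe_genes"])
        targets[i] = genes
    union = set().union(*targets.values()) if targets else set()
    return targets, union


def loop_connected_genes(loops: LoopSet) -> set[str]:
    """All genes reachable from >= 1 retained loop (the default test universe)."""
    out: set[str] = set()
    for row in loops.df.itertuples():
        out.update(row.bait_genes)
        if row.oe_is_bait:
            out.update(row.oe_genes)
    return out


def coregulated_genes(targets_a: set[str], targets_b: set[str],
                      universe: set[str]) -> tuple[set[str], float]:
    """Intersection of two target-gene sets with its upper-tail hypergeometric p."""
    stray = (targets_a | targets_b) - universe
    if stray:
        raise ValueError(f"target genes outside universe: {sorted(stray)[:5]}...")
    overlap = targets_a & targets_b
    p = hypergeom_set_overlap(len(targets_a), len(targets_b), len(overlap),
                              len(universe))
    return overlap, p


def _anchor_occupancy(loops: LoopSet, peaks: PeakSet) -> tuple[np.ndarray, np.ndarray]:
    """(at_bait, at_oe) boolean arrays per loop row for one TF-bound OCR set."""
    n = len(loops.df)
    at_bait = np.zeros(n, dtype=bool)
    at_oe = np.zeros(n, dtype=bool)
    raw = _ocr_loop_incidence(peaks, loops)
    idx = {lid: i for i, lid in enumerate(loops.df["loop_id"])}
    for hit in raw.values():
        for lid in hit["bait"]:
            at_bait[idx[lid]] = True
        for lid in hit["oe"]:
            at_oe[idx[lid]] = True
    return at_bait, at_oe


def classify_coregulation_topology(
    loops: LoopSet,
    p63_ocrs: PeakSet,
    ctcf_ocrs: PeakSet,
    genes: Optional[Iterable[str]] = None,
) -> dict[str, TopologyCall]:
    """Per-gene same-loop / different-loops co-regulation classification.

    For each loop of a gene, each TF-bound OCR set's presence is resolved per
    anchor. A gene is ``same_loop`` when some loop carries both TFs (any
    anchor combination); those loops get a topology — both at the bait →
    ``both_promoter`` (also when both sit on the promoter-side other end of a
    PP loop), both at a PE other end → ``both_enhancer``, otherwise one TF at
    each anchor → ``opposite_anchors``. Precedence for mixed occupancy:
    both_promoter > both_enhancer > opposite_anchors. ``different_loops``
    marks genes both TFs reach but never on one loop; ``single_tf`` / ``none``
    otherwise.
    """
    p63_bait, p63_oe = _anchor_occupancy(loops, p63_ocrs)
    ctcf_bait, ctcf_oe = _anchor_occupancy(loops, ctcf_ocrs)
    df = loops.df
    gene_loops: dict[str, list[int]] = {}
    for i, row in enumerate(df.itertuples()):
        owners = set(row.bait_genes) | (set(row.oe_genes) if row.oe_is_bait else set())
        for gid in owners:
            gene_loops.setdefault(gid, []).append(i)
    if genes is None:
        genes = sorted(gene_loops)

    loop_ids = df["loop_id"].to_numpy()
    is_pp = (df["oe_is_bait"] == 1).to_numpy()
    calls: dict[str, TopologyCall] = {}
    for gid in genes:
        rows = gene_loops.get(gid, [])
        per_loop: list[tuple[str, str]] = []
        has_p63 = False
        has_ctcf = False
        for i in rows:
            p63_here = p63_bait[i] or p63_oe[i]
            ctcf_here = ctcf_bait[i] or ctcf_oe[i]
            has_p63 |= bool(p63_here)
            has_ctcf |= bool(ctcf_here)
            if not (p63_here and ctcf_here):
                continue
            if p63_bait[i] and ctcf_bait[i]:
                topo = "both_promoter"
            elif p63_oe[i] and ctcf_oe[i]:
                topo = "both_promoter" if is_pp[i] else "both_enhancer"
            else:
                topo = "opposite_anchors"
            per_loop.append((str(loop_ids[i]), topo))
        if per_loop:
            cls = "same_loop"
        elif has_p63 and has_ctcf:
            cls = "different_loops"
        elif has_p63 or has_ctcf:
            cls = "single_tf"
        else:
            cls = "none"
        calls[gid] = TopologyCall(gene_id=gid, gene_class=cls, per_loop=per_loop)
    return calls


_TOPO_PRECEDENCE = {"both_promoter": 0, "both_enhancer": 1, "opposite_anchors": 2}


def summarize_topology(calls: dict[str, TopologyCall]) -> dict:
    """Cohort summary: gene-class counts, per-loop topology fractions over all
    qualifying loops of same-loop genes, and gene-level topology fractions
    (each same-loop gene labelled by precedence over its qualifying loops)."""
    class_counts = {c: 0 for c in GENE_CLASSES}
    loop_topo_counts = {t: 0 for t in TOPOLOGIES}
    gene_topo_counts = {t: 0 for t in TOPOLOGIES}
    for call in calls.values():
        class_counts[call.gene_class] += 1
        if call.gene_class != "same_loop":
            continue
        seen_loops = set()
        for lid, topo in call.per_loop:
            if lid not in seen_loops:
                loop_topo_counts[topo] += 1
                seen_loops.add(lid)
        gene_topo = min((t for _, t in call.per_loop),
                        key=_TOPO_PRECEDENCE.__getitem__)
        gene_topo_counts[gene_topo] += 1
    n_loop = sum(loop_topo_counts.values())
    n_gene = sum(gene_topo_counts.values())
    return {
        "gene_class_counts": class_counts,
        "loop_topology_counts": loop_topo_counts,
        "loop_topology_fractions": {t: c / n_loop if n_loop else 0.0
                                    for t, c in loop_topo_counts.items()},
        "gene_topology_counts": gene_topo_counts,
        "gene_topology_fractions": {t: c / n_gene if n_gene else 0.0
                                    for t, c in gene_topo_counts.items()},
    }


def deregulated_fraction(coreg_genes: set[str], genes: Sequence[GeneModel]
                         ) -> tuple[int, Optional[float]]:
    """How many co-regulated genes are differentially expressed."""
    de_ids = {g.gene_id for g in genes if g.is_de}
    n = len(coreg_genes & de_ids)
    return n, (n / len(coreg_genes) if coreg_genes else None)
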