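"""Loop filtering/typing, anchor mapping, expression quartiles, target genes
and the same-loop/different-loop co-regulation topology classifier."""
import numpy as np
import pandas as pd
import pytest

from chromloop import (GeneModel, Interval, LoopSet, PeakSet, SimConfig,
                       classify_coregulation_topology, coregulated_genes,
                       deregulated_fraction, expression_quartiles,
                       filter_and_classify_loops, loop_connected_genes,
                       loops_per_gene, map_ocrs_to_anchors, simulate_all,
                       summarize_topology, target_genes_of_ocrs)
from chromloop.sim import fixture_from_counts


def _loop(lid, bait=(1000, 3000), oe=(100_000, 102_000), genes=("G1",),
          score=6.0, pp=0, oe_genes=(), chrom="chr1", oe_chrom=None):
    return dict(bait_chr=chrom, bait_start=bait[0], bait_end=bait[1],
                bait_genes=genes, oe_chr=oe_chrom or chrom, oe_start=oe[0],
                oe_end=oe[1], oe_is_bait=pp, oe_genes=oe_genes, score=score,
                loop_id=lid)


# ------------------------------------------------------------------ filtering

def test_score_threshold_inclusive():
    loops = LoopSet.from_records([
        _loop("L1", score=4.9), _loop("L2", score=5.0), _loop("L3", score=7.0)])
    kept, summary = filter_and_classify_loops(loops, score_min=5)
    assert summary.n_total == 2
    assert set(kept.df["loop_id"]) == {"L2", "L3"}


def test_type_fractions_and_median_span():
    loops = LoopSet.from_records([
        _loop("L1", oe=(101_000, 103_000)),                      # span 100 kb
        _loop("L2", oe=(201_000, 203_000)),                      # span 200 kb
        _loop("L3", oe=(301_000, 303_000)),                      # span 300 kb
        _loop("L4", pp=1, oe=(51_000, 53_000), oe_genes=("G2",)),
    ])
    kept, summary = filter_and_classify_loops(loops)
    assert summary.n_pe == 3 and summary.n_pp == 1
    assert summary.pe_fraction + summary.pp_fraction == pytest.approx(1.0)
    spans_expected = np.median([100_000, 200_000, 300_000, 50_000])
    assert summary.median_span_bp == pytest.approx(spans_expected)


def test_trans_loops_excluded_from_span():
    loops = LoopSet.from_records([
        _loop("L1", oe=(101_000, 103_000)),
        _loop("L2", oe=(0, 2000), oe_chrom="chr2"),
    ])
    _, summary = filter_and_classify_loops(loops)
    assert summary.median_span_bp == pytest.approx(100_000)
    assert summary.n_total == 2  # trans retained for anchor logic


# ------------------------------------------------------------ anchor mapping

def test_map_ocrs_shared_loop_accounting():
    loops = LoopSet.from_records([
        _loop("L1", oe=(10_000, 12_000)),
        _loop("L2", oe=(20_000, 22_000)),
        _loop("L3", oe=(30_000, 32_000)),
    ])
    ocrs = PeakSet([Interval("chr1", 10_500, 31_000, name="a"),  # L1,L2,L3
                    Interval("chr1", 31_500, 31_900, name="b")])  # L3
    _, n_ocr, n_loop, mean = map_ocrs_to_anchors(ocrs, loops)
    assert (n_ocr, n_loop, mean) == (2, 3, 2.0)


def test_ocr_touching_both_anchors_counts_loop_once():
    loops = LoopSet.from_records([_loop("L1", bait=(1000, 3000),
                                        oe=(4000, 6000))])
    ocrs = PeakSet([Interval("chr1", 2000, 5000, name="wide")])
    incidence, n_ocr, n_loop, mean = map_ocrs_to_anchors(ocrs, loops)
    assert incidence[0] == {"L1"}
    assert (n_ocr, n_loop, mean) == (1, 1, 1.0)


def test_printed_incidence_fixtures():
    for (n_ocr, n_loop, total), expect_mean in [
            ((388, 1674, 1674), 4.3), ((191, 1093, 1093), 5.7)]:
        ocrs, loops = fixture_from_counts(n_ocr, n_loop, total)
        _, got_ocr, got_loop, got_mean = map_ocrs_to_anchors(ocrs, loops)
        assert (got_ocr, got_loop) == (n_ocr, n_loop)
        assert got_mean == expect_mean


def test_fixture_infeasible_triples_rejected():
    with pytest.raises(ValueError):
        fixture_from_counts(2, 1, 4)
    with pytest.raises(ValueError):
        fixture_from_counts(3, 5, 4)


# -------------------------------------------------------- expression quartiles

def _gene(gid, fpkm, de="none", chrom="chr1", tss=5000):
    return GeneModel(gene_id=gid, chrom=chrom, tss=tss,
                     fpkm_by_sample={"s1": fpkm}, de_flag=de)


def test_quartile_split_examples():
    genes = [_gene("a", 0.5), _gene("b", 2), _gene("c", 4), _gene("d", 8),
             _gene("e", 16)]
    q = expression_quartiles(genes)
    assert q == {"a": "Q0", "b": "Q1", "c": "Q2", "d": "Q3", "e": "Q4"}
    all_low = expression_quartiles([_gene("x", 0.1), _gene("y", 0.9)])
    assert set(all_low.values()) == {"Q0"}


def test_quartile_sizes_balanced():
    genes = [_gene(f"g{i:03d}", 1 + i) for i in range(41)]  # 4k+1 expressed
    q = expression_quartiles(genes)
    sizes = [sum(1 for v in q.values() if v == f"Q{k}") for k in (1, 2, 3, 4)]
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == 41


# ------------------------------------------------------------- loops per gene

def test_loops_per_gene_counts_and_pp_both_ends():
    loops = LoopSet.from_records([
        _loop("L1", genes=("G1",)),
        _loop("L2", genes=("G1",), oe=(200_000, 202_000)),
        _loop("L3", genes=("G2",), pp=1, oe=(50_000, 52_000),
              oe_genes=("G1",)),
    ])
    genes = [_gene("G1", 5), _gene("G2", 5), _gene("G3", 5)]
    profiles, per_q, _ = loops_per_gene(loops, genes)
    by_id = {p.gene_id: p.n_loops for p in profiles}
    assert by_id == {"G1": 3, "G2": 1, "G3": 0}  # PP counts for both baits


def test_planted_quartile_rates_monotone_and_de_power():
    """Quartile loop-rate means (1,2,4,6,8) produce strictly increasing
    empirical means Q0..Q4, and 2x-rate DE genes give rank-test p < 0.01."""
    bundle = simulate_all(SimConfig(seed=13))
    kept, _ = filter_and_classify_loops(bundle.loops, score_min=0.0)
    quart = expression_quartiles(bundle.genes)
    profiles, per_q, p_de = loops_per_gene(kept, bundle.genes, quart)
    means = [np.mean(per_q[f"Q{k}"]) for k in range(5)]
    assert all(a < b for a, b in zip(means, means[1:]))
    assert p_de < 0.01


# ---------------------------------------------------------------- target genes

def test_target_genes_rules():
    loops = LoopSet.from_records([
        _loop("L1", genes=("G1",), oe=(100_000, 102_000)),
        _loop("L2", genes=("G1",), pp=1, oe=(200_000, 202_000),
              oe_genes=("G2",)),
    ])
    # OCR at the other end of L1 -> bait genes of L1
    ocr_oe = PeakSet([Interval("chr1", 100_500, 100_700, name="x")])
    targets, union = target_genes_of_ocrs(ocr_oe, loops)
    assert targets[0] == {"G1"} and union == {"G1"}
    # OCR inside the bait of the PP loop: own genes + interacting promoter's
    ocr_bait = PeakSet([Interval("chr1", 1500, 1700, name="y")])
    targets, union = target_genes_of_ocrs(ocr_bait, loops)
    assert targets[0] == {"G1", "G2"}


def test_target_union_matches_exhaustive_scan():
    bundle = simulate_all(SimConfig(seed=23, n_genes=200, n_ocrs=500))
    kept, _ = filter_and_classify_loops(bundle.loops)
    ocrs = bundle.p63_bound_ocrs
    targets, union = target_genes_of_ocrs(ocrs, kept)
    expect: set[str] = set()
    for iv in ocrs.intervals:
        for row in kept.df.itertuples():
            hit_oe = (row.oe_chr == iv.chrom and iv.start < row.oe_end
                      and row.oe_start < iv.end)
            hit_bait = (row.bait_chr == iv.chrom and iv.start < row.bait_end
                        and row.bait_start < iv.end)
            if hit_oe or hit_bait:
                expect.update(row.bait_genes)
            if hit_bait and row.oe_is_bait:
                expect.update(row.oe_genes)
    assert union == expect


# ------------------------------------------------------------- co-regulation

def test_coregulated_overlap_and_p():
    overlap, p = coregulated_genes({"A", "B", "C"}, {"B", "C", "D"},
                                   set("ABCDEFGHIJ"))
    assert overlap == {"B", "C"}
    assert 0 < p < 1
    _, p_disjoint = coregulated_genes({"A"}, {"B"}, set("ABCDEFGHIJ"))
    assert p_disjoint == pytest.approx(1.0)
    with pytest.raises(ValueError):
        coregulated_genes({"Z"}, {"B"}, set("AB"))


def test_deregulated_fraction():
    genes = [_gene("a", 1, de="up"), _gene("b", 1), _gene("c", 1),
             _gene("d", 1)]
    n, frac = deregulated_fraction({"a", "b", "c", "d"}, genes)
    assert (n, frac) == (1, 0.25)
    n0, frac0 = deregulated_fraction(set(), genes)
    assert n0 == 0 and frac0 is None


# ------------------------------------------------------------------- topology

def _topo_fixture():
    return LoopSet.from_records([
        _loop("L1", genes=("G1",), bait=(1000, 3000), oe=(100_000, 102_000)),
        _loop("L2", genes=("G2",), bait=(301_000, 303_000),
              oe=(400_000, 402_000)),
        _loop("L3", genes=("G2",), bait=(301_000, 303_000),
              oe=(500_000, 502_000)),
        _loop("L4", genes=("G3",), bait=(601_000, 603_000),
              oe=(700_000, 702_000)),
    ])


def test_topology_opposite_anchors():
    loops = _topo_fixture()
    p63 = PeakSet([Interval("chr1", 100_500, 100_700)])   # L1 other end
    ctcf = PeakSet([Interval("chr1", 1500, 1700)])        # L1 bait
    calls = classify_coregulation_topology(loops, p63, ctcf)
    assert calls["G1"].gene_class == "same_loop"
    assert calls["G1"].per_loop == [("L1", "opposite_anchors")]


def test_topology_different_loops():
    loops = _topo_fixture()
    p63 = PeakSet([Interval("chr1", 400_500, 400_700)])   # L2 other end
    ctcf = PeakSet([Interval("chr1", 500_500, 500_700)])  # L3 other end
    calls = classify_coregulation_topology(loops, p63, ctcf)
    assert calls["G2"].gene_class == "different_loops"
    assert calls["G2"].per_loop == []


def test_topology_both_promoter_and_single_tf_and_none():
    loops = _topo_fixture()
    p63 = PeakSet([Interval("chr1", 601_200, 601_400)])
    ctcf = PeakSet([Interval("chr1", 602_000, 602_200)])
    calls = classify_coregulation_topology(loops, p63, ctcf)
    assert calls["G3"].gene_class == "same_loop"
    assert calls["G3"].per_loop == [("L4", "both_promoter")]
    assert calls["G1"].gene_class == "none"
    # single TF
    calls2 = classify_coregulation_topology(loops, p63, PeakSet([]))
    assert calls2["G3"].gene_class == "single_tf"


def test_topology_both_enhancer_and_pp_promoter_rule():
    loops = LoopSet.from_records([
        _loop("L1", genes=("G1",), oe=(100_000, 102_000)),
        _loop("L2", genes=("G2",), bait=(301_000, 303_000), pp=1,
              oe=(400_000, 402_000), oe_genes=("G4",)),
    ])
    both_at_oe_pe = classify_coregulation_topology(
        loops, PeakSet([Interval("chr1", 100_200, 100_400)]),
        PeakSet([Interval("chr1", 101_000, 101_200)]))
    assert both_at_oe_pe["G1"].per_loop == [("L1", "both_enhancer")]
    # both TFs at the promoter-side other end of a PP loop -> both_promoter
    both_at_oe_pp = classify_coregulation_topology(
        loops, PeakSet([Interval("chr1", 400_200, 400_400)]),
        PeakSet([Interval("chr1", 401_000, 401_200)]))
    assert both_at_oe_pp["G2"].per_loop == [("L2", "both_promoter")]


def test_gene_classes_partition_connected_genes():
    bundle = simulate_all(SimConfig(seed=29))
    kept, _ = filter_and_classify_loops(bundle.loops)
    calls = classify_coregulation_topology(kept, bundle.p63_bound_ocrs,
                                           bundle.ctcf_bound_ocrs)
    connected = loop_connected_genes(kept)
    assert set(calls) == connected
    summary = summarize_topology(calls)
    assert sum(summary["gene_class_counts"].values()) == len(connected)
    fr = summary["loop_topology_fractions"]
    assert sum(fr.values()) == pytest.approx(1.0)


def test_planted_topology_mixture_recovered():
    """Planted per-gene topology mix (0.2, 0.6, 0.2) over 500 genes is
    recovered within +-0.05 per category."""
    cfg = SimConfig(seed=17, n_chrom=4, chrom_length=25_000_000, n_genes=1000,
                    n_topology_genes=500)
    bundle = simulate_all(cfg)
    kept, _ = filter_and_classify_loops(bundle.loops)
    planted = bundle.truth.topology_by_gene
    calls = classify_coregulation_topology(
        kept, bundle.p63_bound_ocrs, bundle.ctcf_bound_ocrs,
        genes=list(planted))
    summary = summarize_topology({g: c for g, c in calls.items()})
    fr = summary["gene_topology_fractions"]
    for topo, expect in zip(("opposite_anchors", "both_promoter",
                             "both_enhancer"), (0.2, 0.6, 0.2)):
        assert abs(fr[topo] - expect) <= 0.05
    # and per-gene agreement with the planted labels is high
    agree = sum(
        1 for gid, t in planted.items()
        if calls[gid].gene_class == "same_loop"
        and min((x for _, x in calls[gid].per_loop),
                key=("both_promoter", "both_enhancer",
                     "opposite_anchors").index) == t)
    assert agree / len(planted) >= 0.95
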