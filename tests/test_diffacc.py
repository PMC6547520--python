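"""Differential accessibility: size factors, NB Wald calibration and
recovery, OCR subsetting, nearest-gene assignment, coverage tracks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromloop import (CountMatrix, GeneModel, GenomeDef, Interval, PeakSet,
                       SimConfig, assign_nearest_de_gene, bound_ocrs,
                       coverage_track, differential_regions, simulate_all,
                       size_factors, split_specific_ocrs)


def _regions(n):
    return [Interval("chr1", 1000 * i, 1000 * i + 500, name=f"r{i}")
            for i in range(n)]


SAMPLES_2V2 = [("c1", "control"), ("c2", "control"),
               ("m1", "mutant"), ("m2", "mutant")]


# ---------------------------------------------------------------- size factors

def test_size_factors_hand_computed():
    counts = np.array([[10, 20], [30, 60]])
    sf = size_factors(counts)
    assert sf == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_identical_samples_are_one():
    counts = np.tile([[10], [30], [7]], (1, 4))
    assert size_factors(counts) == pytest.approx([1, 1, 1, 1])


def test_size_factors_scale_equivariant_and_order_invariant():
    """Scaling one sample's column by c scales its factor *relative to every
    other sample* by c (the geometric-mean reference absorbs c^(1/m), so the
    raw factor itself moves by c^((m-1)/m)); region order is irrelevant."""
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 500, size=(100, 4))
    sf = size_factors(counts)
    scaled = counts.astype(float).copy()
    scaled[:, 2] *= 3.0
    sf_scaled = size_factors(scaled)
    for j in (0, 1, 3):
        assert sf_scaled[2] / sf_scaled[j] == pytest.approx(3.0 * sf[2] / sf[j])
    assert sf_scaled[2] == pytest.approx(3.0 ** (3 / 4) * sf[2])
    perm = rng.permutation(100)
    assert size_factors(counts[perm]) == pytest.approx(sf)


def test_size_factors_require_reference_region():
    with pytest.raises(ValueError, match="pseudo-count"):
        size_factors(np.array([[0, 5], [3, 0]]))


# ------------------------------------------------------- differential regions

def test_null_region_is_ns():
    counts = np.full((20, 4), 100)
    rng = np.random.default_rng(1)
    counts = counts + rng.integers(0, 5, counts.shape)  # break exact ties
    m = CountMatrix(_regions(20), SAMPLES_2V2, counts)
    res = differential_regions(m)
    assert all(abs(r.log2FC) < 0.2 for r in res)
    assert all(r.direction == "ns" for r in res)
    assert all(r.padj >= r.p for r in res)


def test_needs_two_replicates():
    m = CountMatrix(_regions(2), [("c1", "control"), ("m1", "mutant"),
                                  ("m2", "mutant")],
                    np.full((2, 3), 10))
    with pytest.raises(ValueError, match="replicates"):
        differential_regions(m)


def test_planted_recovery_and_fdr():
    """2000 regions, 10% with |log2FC| = 2 at dispersion 0.05: recall >= 0.8,
    empirical FDR <= 0.15."""
    bundle = simulate_all(SimConfig(seed=7, n_ocrs=2000, frac_diff_ocrs=0.10,
                                    true_log2fc=2.0, nb_dispersion=0.05))
    res = differential_regions(bundle.counts)
    truth = bundle.truth.diff_region_ids
    called = {r.region.name: r.direction for r in res if r.direction != "ns"}
    tp = sum(1 for rid, d in called.items() if truth.get(rid) == d)
    assert tp / len(truth) >= 0.8
    assert 1 - tp / len(called) <= 0.15


def test_label_permutation_yields_uniform_p():
    """Swapping one replicate per condition (a null relabeling) gives
    uniform-ish p-values (KS test)."""
    bundle = simulate_all(SimConfig(seed=5, n_ocrs=2000, frac_diff_ocrs=0.0))
    m = bundle.counts
    permuted = CountMatrix(m.regions,
                           [("c1", "control"), ("m1", "control"),
                            ("c2", "mutant"), ("m2", "mutant")],
                           m.counts)
    p = np.array([r.p for r in differential_regions(permuted)])
    assert stats.kstest(p, "uniform").pvalue > 0.001


def test_split_partition():
    res = differential_regions(CountMatrix(
        _regions(3), SAMPLES_2V2,
        np.array([[400, 380, 40, 44], [40, 44, 400, 380], [100, 104, 99, 102]])))
    ctr, mt = split_specific_ocrs(res)
    assert (len(ctr), len(mt)) == (1, 1)
    assert ctr.label == "Ctr-OCR" and mt.label == "Mt-OCR"
    n_called = sum(1 for r in res if r.direction != "ns")
    assert len(ctr) + len(mt) == n_called
    empty_ctr, empty_mt = split_specific_ocrs([])
    assert len(empty_ctr) == 0 and len(empty_mt) == 0


# ------------------------------------------------------------------ bound OCRs

def test_bound_ocrs_basic():
    genome = GenomeDef({"chr1": 10_000})
    ocrs = PeakSet([Interval("chr1", 0, 100)], label="OCR")
    bs = PeakSet([Interval("chr1", 90, 95)], label="TF")
    bound, n, p = bound_ocrs(ocrs, bs, genome)
    assert len(bound) == 1 and n == 1
    assert 0 <= p <= 1


def test_bound_ocrs_planted_colocalization_fraction():
    """60% of OCRs seeded with a binding site -> bound fraction 0.60 +- 0.05
    (background sites add a little)."""
    bundle = simulate_all(SimConfig(seed=11, tf_in_ocr_fraction=0.6,
                                    n_tf_background=0))
    bound, n, p = bound_ocrs(bundle.ocrs, bundle.tf_bs, bundle.genome)
    frac = n / len(bundle.ocrs)
    assert abs(frac - 0.60) <= 0.05
    assert p < 0.001


# ---------------------------------------------------------------- nearest gene

def _gene(gid, chrom, tss, strand="+", de="up"):
    return GeneModel(gene_id=gid, chrom=chrom, tss=tss, strand=strand,
                     de_flag=de)


def test_nearest_de_gene_sign_and_tie():
    ocrs = PeakSet([Interval("chr1", 450, 550)])  # midpoint 500
    genes = [_gene("gA", "chr1", 400), _gene("gB", "chr1", 700),
             _gene("gC", "chr1", 5000, de="none")]
    out = assign_nearest_de_gene(ocrs, genes)
    # nearest DE TSS is 400; OCR midpoint is downstream of it on + strand
    assert out[0] == ("gA", 100)
    # minus strand flips the sign
    genes_minus = [_gene("gA", "chr1", 400, strand="-")]
    assert assign_nearest_de_gene(ocrs, genes_minus)[0] == ("gA", -100)
    # equidistant: lexicographically smaller gene id wins
    tie = [_gene("gZ", "chr1", 400), _gene("gB", "chr1", 600)]
    assert assign_nearest_de_gene(ocrs, tie)[0][0] == "gB"
    # chromosome without DE genes -> unassigned
    assert assign_nearest_de_gene(PeakSet([Interval("chr2", 0, 10)]), genes)[0] is None


def test_nearest_matches_bruteforce():
    rng = np.random.default_rng(9)
    genes = [_gene(f"g{i:03d}", "chr1", int(rng.integers(0, 100_000)))
             for i in range(50)]
    ocrs = PeakSet([Interval("chr1", int(s), int(s) + 100)
                    for s in rng.integers(0, 99_000, 100)])
    out = assign_nearest_de_gene(ocrs, genes)
    for i, iv in enumerate(ocrs.intervals):
        mid = iv.midpoint
        best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
        assert out[i][0] == best.gene_id


# -------------------------------------------------------------- coverage track

def test_coverage_track_closed_form_and_invariance():
    genome = GenomeDef({"chr1": 50})
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [30],
                          "sample_id": ["s"]})
    track = coverage_track(frags, genome, extend_to=200, bin_size=50)
    assert track["chr1"][0] == pytest.approx(1e9 / 50)
    doubled = pd.concat([frags, frags], ignore_index=True)
    track2 = coverage_track(doubled, genome, extend_to=200, bin_size=50)
    assert track2["chr1"][0] == pytest.approx(track["chr1"][0])


def test_coverage_track_matches_per_bp_oracle():
    genome = GenomeDef({"chr1": 2000})
    rng = np.random.default_rng(13)
    starts = rng.integers(0, 1900, 200)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts,
                          "end": starts + 80, "sample_id": "s"})
    ext = 100
    bin_size = 50
    track = coverage_track(frags, genome, extend_to=ext, bin_size=bin_size)
    for b in range(2000 // bin_size):
        lo, hi = b * bin_size, (b + 1) * bin_size
        n = sum(1 for s in starts if s < hi and min(s + ext, 2000) > lo)
        assert track["chr1"][b] == pytest.approx(n * 1e9 / (200 * bin_size))


def test_coverage_track_rejects_empty():
    genome = GenomeDef({"chr1": 100})
    with pytest.raises(ValueError):
        coverage_track(pd.DataFrame(columns=["chrom", "start", "end",
                                             "sample_id"]), genome)


def test_log2fc_concordant_with_independent_nb_fitter():
    """log2FC estimates agree with an independent negative-binomial GLM
    implementation (pydeseq2) on a planted simulation: near-perfect rank
    agreement and small absolute error on the strong effects."""
    import pandas as pd
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    bundle = simulate_all(SimConfig(seed=7, n_ocrs=300, frac_diff_ocrs=0.2))
    m = bundle.counts
    lfc_my = np.array([r.log2FC for r in differential_regions(m)])

    counts = pd.DataFrame(m.counts.T, index=[s for s, _ in m.samples],
                          columns=[r.name for r in m.regions])
    meta = pd.DataFrame({"condition": [c for _, c in m.samples]},
                        index=counts.index)
    dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition",
                       quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "mutant", "control"],
                    quiet=True)
    ds.summary()
    lfc_ref = ds.results_df["log2FoldChange"].to_numpy()
    assert np.corrcoef(lfc_ref, lfc_my)[0, 1] > 0.999
    strong = np.abs(lfc_ref) > 1
    assert np.max(np.abs(lfc_ref - lfc_my)[strong]) < 0.1
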