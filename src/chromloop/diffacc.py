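"""Differential open-chromatin-region calling and OCR annotation.

Replicated ATAC-seq read counts over consensus OCRs are modelled as negative
binomial: ``Var(K) = mu + alpha * mu^2``. Library depth is removed with
median-of-ratios size factors; per-region dispersion is estimated by method
of moments and stabilised by averaging (weight 0.5) with a fitted
``alpha(mu) = a0 + a1/mu`` mean-dispersion trend — the information-sharing
step that makes two-replicate designs testable at all. Accessibility change
is a Wald test on log2(mutant/control) with a delta-method standard error
from the NB variance.

Regions passing ``|log2FC| >= log2(fc_threshold)`` at ``p < p_threshold`` are
split into control-specific (Ctr-OCR, more accessible in control) and
mutant-specific (Mt-OCR) sets; those sets feed TF-binding-site intersection
and nearest-differentially-expressed-gene association.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeDef, Interval
from .intervals import PeakSet, fisher_overlap, intersecting_mask

CONDITIONS = ("control", "mutant")


@dataclass
class CountMatrix:
    """Region x sample integer counts with a two-condition design."""

    regions: list[Interval]
    samples: list[tuple[str, str]]  # (sample_id, condition)
    counts: np.ndarray  # shape (n_regions, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape does not match regions x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero sample column")
        for _, cond in self.samples:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([j for j, (_, c) in enumerate(self.samples) if c == condition])


@dataclass(frozen=True)
class DiffResult:
    region: Interval
    baseMean: float
    log2FC: float
    p: float
    padj: float
    direction: str  # ctr_specific | mt_specific | ns


@dataclass
class GeneModel:
    """A gene reduced to its TSS, expression levels and DE status."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    fpkm_by_sample: dict[str, float] = field(default_factory=dict)
    de_flag: str = "none"  # up | down | none
    de_fold: float = 1.0

    @property
    def is_de(self) -> bool:
        return self.de_flag != "none"

    def mean_fpkm(self, sample_ids: Optional[Sequence[str]] = None) -> float:
        vals = [v for k, v in self.fpkm_by_sample.items()
                if sample_ids is None or k in sample_ids]
        return float(np.mean(vals)) if vals else 0.0


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors.

    For each sample j, the factor is the median over reference-able regions
    (all-positive counts) of counts[r, j] / geometric-mean_r. Scaling one
    sample's column by c multiplies its factor by c.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no region with all-positive counts; add a pseudo-count or "
            "filter regions before estimating size factors"
        )
    log_geo = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def _fit_dispersion_trend(base_mean: np.ndarray, disp_mom: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0 + a1/mu on regions with positive
    moment estimates; coefficients floored at 0; constant fallback."""
    use = (disp_mom > 0) & (base_mean > 0)
    if use.sum() >= 10:
        x = 1.0 / base_mean[use]
        design = np.column_stack([np.ones(use.sum()), x])
        coef, *_ = np.linalg.lstsq(design, disp_mom[use], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = float(np.median(disp_mom[use]))
    elif use.any():
        a0, a1 = float(np.median(disp_mom[use])), 0.0
    else:
        a0, a1 = 0.01, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    return trend


def differential_regions(
    m: CountMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    shrink_weight: float = 0.5,
) -> list[DiffResult]:
    """NB Wald test per region, mutant over control.

    Requires >= 2 replicates per condition. Direction is ``ctr_specific`` when
    log2FC <= -log2(fc_threshold) at p < p_threshold, ``mt_specific`` for the
    mirrored case, else ``ns``. padj is Benjamini-Hochberg over all regions.
    """
    ctr_cols = m.condition_columns("control")
    mut_cols = m.condition_columns("mutant")
    if len(ctr_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")

    sf = size_factors(m.counts)
    q = m.counts / sf  # normalized counts
    base_mean = q.mean(axis=1)

    means = {}
    disps = {}
    for cond, cols in (("control", ctr_cols), ("mutant", mut_cols)):
        qc = q[:, cols]
        mu = qc.mean(axis=1)
        var = qc.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        means[cond] = mu
        disps[cond] = a
    disp_mom = np.clip((disps["control"] + disps["mutant"]) / 2.0, 0.0, 10.0)
    trend = _fit_dispersion_trend(base_mean, disp_mom)
    alpha = np.maximum(shrink_weight * disp_mom + (1 - shrink_weight) * trend, 1e-8)

    pseudo = 0.5
    mu_c = means["control"]
    mu_m = means["mutant"]
    log2fc = np.log2((mu_m + pseudo) / (mu_c + pseudo))

    # delta-method variance of ln(mean_c): Var(mean) / mean^2, with
    # Var(mean) = (1/n^2) sum_j (mu/sf_j + alpha mu^2) from NB sampling
    def _var_log(mu: np.ndarray, cols: np.ndarray) -> np.ndarray:
        inv_sf = (1.0 / sf[cols]).sum()
        n = len(cols)
        var_mean = (mu * inv_sf + alpha * mu**2 * n) / n**2
        return var_mean / np.maximum(mu + pseudo, 1e-8) ** 2

    se_ln = np.sqrt(_var_log(mu_c, ctr_cols) + _var_log(mu_m, mut_cols))
    se_log2 = np.maximum(se_ln / np.log(2), 1e-12)
    z = log2fc / se_log2
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    padj = np.maximum(padj, p)

    lfc_cut = np.log2(fc_threshold)
    results = []
    for i, region in enumerate(m.regions):
        if p[i] < p_threshold and log2fc[i] <= -lfc_cut:
            direction = "ctr_specific"
        elif p[i] < p_threshold and log2fc[i] >= lfc_cut:
            direction = "mt_specific"
        else:
            direction = "ns"
        results.append(DiffResult(
            region=region, baseMean=float(base_mean[i]),
            log2FC=float(log2fc[i]), p=float(p[i]), padj=float(padj[i]),
            direction=direction,
        ))
    return results


def split_specific_ocrs(results: Sequence[DiffResult]) -> tuple[PeakSet, PeakSet]:
    """Partition differential regions into Ctr-OCR / Mt-OCR peak sets."""
    ctr = [r.region for r in results if r.direction == "ctr_specific"]
    mt = [r.region for r in results if r.direction == "mt_specific"]
    return PeakSet(ctr, label="Ctr-OCR"), PeakSet(mt, label="Mt-OCR")


def bound_ocrs(
    ocrs: PeakSet, bs: PeakSet, genome: GenomeDef
) -> tuple[PeakSet, int, float]:
    """OCRs intersecting >= 1 TF binding site, with Fisher overlap enrichment p."""
    mask = intersecting_mask(ocrs, bs)
    bound = PeakSet([iv for iv, keep in zip(ocrs.intervals, mask) if keep],
                    label=f"{bs.label or 'TF'}-bound_{ocrs.label or 'OCR'}")
    n_overlap = int(mask.sum())
    p_enrich = fisher_overlap(ocrs, bs, genome).p_two_sided if n_overlap >= 0 else 1.0
    return bound, n_overlap, p_enrich


def assign_nearest_de_gene(
    ocrs: PeakSet, genes: Sequence[GeneModel]
) -> dict[int, Optional[tuple[str, int]]]:
    """Nearest DE-gene TSS per OCR (by midpoint distance, same chromosome).

    Returns {ocr index -> (gene_id, signed distance)} with None where the
    chromosome carries no DE gene. Distance sign is strand-aware: negative
    means the OCR lies upstream of the TSS (before it in the gene's reading
    direction). Ties go to the lexicographically smaller gene_id.
    """
    de_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.is_de:
            de_by_chrom.setdefault(g.chrom, []).append(g)

    out: dict[int, Optional[tuple[str, int]]] = {}
    for i, iv in enumerate(ocrs.intervals):
        candidates = de_by_chrom.get(iv.chrom)
        if not candidates:
            out[i] = None
            continue
        mid = iv.midpoint
        best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
        signed = mid - best.tss if best.strand != "-" else best.tss - mid
        out[i] = (best.gene_id, int(signed))
    return out


def coverage_track(
    fragments: pd.DataFrame,
    genome: GenomeDef,
    extend_to: int = 200,
    bin_size: int = 50,
    size_factor: float = 1.0,
) -> dict[str, np.ndarray]:
    """RPKM-normalised binned coverage of start-extended fragments.

    Each fragment is replaced by [start, start+extend_to); a bin's count is
    the number of extended fragments overlapping it; RPKM = count * 1e9 /
    (total_fragments * bin_size), then divided by ``size_factor`` so tracks
    from different libraries are comparable.
    """
    if len(fragments) == 0:
        raise ValueError("no fragments")
    total = len(fragments)
    tracks: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        n_bins = length // bin_size
        tracks[chrom] = np.zeros(n_bins, dtype=float)
    for chrom, grp in fragments.groupby("chrom"):
        if chrom not in tracks:
            continue
        track = tracks[chrom]
        n_bins = len(track)
        starts = grp["start"].to_numpy()
        ends = np.minimum(starts + extend_to, genome.chrom_lengths[chrom])
        first = np.clip(starts // bin_size, 0, n_bins - 1)
        last = np.clip((ends - 1) // bin_size, 0, n_bins - 1)
        for f, l in zip(first, last):
            track[f:l + 1] += 1
    scale = 1e9 / (total * bin_size) / size_factor
    return {c: t * scale for c, t in tracks.items()}
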