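"""ATAC fragment-architecture statistics.

A paired-end ATAC fragment's length carries nucleosome information: sub-150 bp
fragments come from nucleosome-free DNA, fragments a bit under 200 bp from a
single wrapped (mono)nucleosome. The V-plot is the 2-D histogram of fragment
length against signed distance of the fragment *midpoint* from an anchor
point (a TF motif center); the band fractions summarise the same mixture as
two numbers per condition.

Fragments live in a pandas DataFrame with columns chrom/start/end/sample_id;
length is ``end - start`` and midpoint ``floor((start+end)/2)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, merge_intervals

GenomicPoint = tuple[str, int]  # (chrom, position)


def fragment_frame(records: Sequence[tuple[str, int, int, str]]) -> pd.DataFrame:
    """Build a validated fragment DataFrame from (chrom, start, end, sample) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "sample_id"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("fragment with end <= start")
    return df


@dataclass
class VPlotMatrix:
    """2-D (signed distance x fragment length) count histogram."""

    dist_edges: np.ndarray  # len n_dist_bins + 1, spanning [-W, +W]
    len_edges: np.ndarray   # len n_len_bins + 1
    counts: np.ndarray      # (n_dist_bins, n_len_bins) ints
    n_total: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("VPlot mass mismatch: counts do not sum to n_total")


def _midpoints(frags: pd.DataFrame) -> np.ndarray:
    return (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2


def vplot(
    frags: pd.DataFrame,
    centers: Sequence[GenomicPoint],
    window: int = 1000,
    len_range: tuple[int, int] = (1, 500),
    dist_bin: int = 10,
    len_bin: int = 10,
) -> VPlotMatrix:
    """Aggregate V-plot over all (fragment, center) incidences.

    A fragment contributes one count per center with |midpoint - center| <=
    window and length inside ``len_range`` (inclusive); fragments near two
    centers count twice, once per center.
    """
    if len(centers) == 0:
        raise ValueError("vplot requires at least one center")
    if window <= 0 or dist_bin <= 0 or len_bin <= 0:
        raise ValueError("window and bin widths must be positive")
    l_min, l_max = len_range

    dist_edges = np.arange(-window, window + dist_bin, dist_bin)
    len_edges = np.arange(l_min, l_max + len_bin, len_bin)

    dists: list[np.ndarray] = []
    lens: list[np.ndarray] = []
    for chrom, grp in frags.groupby("chrom"):
        mids = _midpoints(grp)
        order = np.argsort(mids)
        mids = mids[order]
        lengths = (grp["end"].to_numpy() - grp["start"].to_numpy())[order]
        for c_chrom, pos in centers:
            if c_chrom != chrom:
                continue
            lo = np.searchsorted(mids, pos - window, side="left")
            hi = np.searchsorted(mids, pos + window, side="right")
            d = mids[lo:hi] - pos
            ln = lengths[lo:hi]
            keep = (ln >= l_min) & (ln <= l_max)
            dists.append(d[keep])
            lens.append(ln[keep])
    if dists:
        d_all = np.concatenate(dists)
        l_all = np.concatenate(lens)
        # clip the single right-edge value into the last bin (half-open bins
        # otherwise drop midpoint == center + window)
        counts, _, _ = np.histogram2d(
            np.clip(d_all, -window, window - 1e-9),
            np.clip(l_all, l_min, l_max - 1e-9),
            bins=[dist_edges, len_edges],
        )
        counts = counts.astype(np.int64)
    else:
        counts = np.zeros((len(dist_edges) - 1, len(len_edges) - 1), dtype=np.int64)
    return VPlotMatrix(dist_edges=dist_edges, len_edges=len_edges,
                       counts=counts, n_total=int(counts.sum()))


def insert_size_density(
    frags: pd.DataFrame,
    regions: PeakSet,
    len_bin: int = 5,
    max_len: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Normalised fragment-length histogram for fragments whose midpoint falls
    inside any region.

    Returns (bin_edges, density, empty_flag); density sums to 1 unless no
    fragment qualifies, in which case the flag is set instead of raising.
    """
    if not regions.intervals:
        raise ValueError("insert_size_density requires non-empty regions")
    region_arr = merge_intervals(regions).by_chrom()
    qual_lengths: list[np.ndarray] = []
    for chrom, grp in frags.groupby("chrom"):
        arr = region_arr.get(chrom)
        if arr is None:
            continue
        mids = _midpoints(grp)
        idx = np.searchsorted(arr[:, 0], mids, side="right") - 1
        inside = (idx >= 0) & (mids < arr[np.clip(idx, 0, None), 1])
        lengths = grp["end"].to_numpy() - grp["start"].to_numpy()
        qual_lengths.append(lengths[inside])
    edges = np.arange(0, max_len + len_bin, len_bin)
    if not qual_lengths or sum(len(x) for x in qual_lengths) == 0:
        return edges, np.zeros(len(edges) - 1), True
    lengths = np.concatenate(qual_lengths)
    hist, _ = np.histogram(np.clip(lengths, 0, max_len - 1e-9), bins=edges)
    return edges, hist / hist.sum(), False


def nfr_fraction(
    frags: pd.DataFrame,
    centers: Sequence[GenomicPoint],
    window: int = 500,
    nfr_cut: int = 150,
    mono_band: tuple[int, int] = (150, 250),
) -> tuple[float, float]:
    """Nucleosome-free and mononucleosome band fractions near anchor points.

    Among fragments whose midpoint lies within +-window of any center (each
    fragment counted once however many centers it is near): the fraction with
    length < nfr_cut, and the fraction with length in [mono_band) —
    nfr + mono + rest = 1 exactly.
    """
    if len(centers) == 0:
        raise ValueError("nfr_fraction requires centers")
    centers_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in centers:
        centers_by_chrom.setdefault(chrom, [])
        centers_by_chrom[chrom].append(pos)
    centers_by_chrom = {c: np.sort(np.asarray(v)) for c, v in centers_by_chrom.items()}

    qual: list[np.ndarray] = []
    for chrom, grp in frags.groupby("chrom"):
        cpos = centers_by_chrom.get(chrom)
        if cpos is None:
            continue
        mids = _midpoints(grp)
        # nearest center distance via sorted positions
        idx = np.searchsorted(cpos, mids)
        left = np.abs(mids - cpos[np.clip(idx - 1, 0, len(cpos) - 1)])
        right = np.abs(cpos[np.clip(idx, 0, len(cpos) - 1)] - mids)
        near = np.minimum(left, right) <= window
        lengths = grp["end"].to_numpy() - grp["start"].to_numpy()
        qual.append(lengths[near])
    if not qual or sum(len(x) for x in qual) == 0:
        raise ValueError("no fragment qualifies near any center")
    lengths = np.concatenate(qual)
    nfr = float((lengths < nfr_cut).mean())
    mono = float(((lengths >= mono_band[0]) & (lengths < mono_band[1])).mean())
    return nfr, mono
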