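"""Chromatin-state and regulatory-class enrichment of peak sets.

Two distinct enrichment pathways are kept separate on purpose:

* shuffle-based fold enrichment — observed fraction of sites (by midpoint)
  per chromatin state over the mean of the same statistic across length- and
  count-preserving shuffles of the sites;
* Fisher-odds-ratio pathways — the bedtools-``fisher``-style 2x2 odds ratio
  of a peak set against a class of regions, and the *relative score* that
  divides a subset's per-state odds ratio by its parent set's.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import GenomeDef, Interval
from .intervals import (OverlapTestResult, PeakSet, fisher_overlap,
                        merge_intervals, shuffle_intervals)

N_STATES_DEFAULT = 18


@dataclass
class StateSegmentation:
    """Non-overlapping genome segments, each labelled with a chromatin state."""

    segments: list[Interval]  # state label carried in Interval.name
    genome: GenomeDef
    n_states: int = N_STATES_DEFAULT

    def __post_init__(self) -> None:
        self.genome.validate_all(self.segments)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for seg in self.segments:
            label = self.state_of(seg)
            if not 1 <= label <= self.n_states:
                raise ValueError(f"state label {label} outside 1..{self.n_states}")
            by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")

    @staticmethod
    def state_of(seg: Interval) -> int:
        return int(seg.name)

    def states_present(self) -> set[int]:
        return {self.state_of(s) for s in self.segments}

    def state_peakset(self, state: int) -> PeakSet:
        return PeakSet([s for s in self.segments if self.state_of(s) == state],
                       label=f"state_{state}")

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chrom (sorted (n,2) spans, state labels) for midpoint lookup."""
        out = {}
        for chrom in {s.chrom for s in self.segments}:
            segs = sorted((s.start, s.end, self.state_of(s))
                          for s in self.segments if s.chrom == chrom)
            arr = np.array([(s, e) for s, e, _ in segs], dtype=np.int64)
            lab = np.array([l for _, _, l in segs], dtype=np.int64)
            out[chrom] = (arr, lab)
        return out


@dataclass
class StateEnrichment:
    """Observed vs shuffle-expected state occupancy of a site set."""

    observed_frac: dict[int, float]
    expected_frac: dict[int, float]
    fold: dict[int, Optional[float]]  # None when expected is 0 (undefined)
    n_shuffles: int


@dataclass
class TADSet:
    """Topologically associating domains; boundaries = +-halfwidth around edges."""

    tads: list[Interval]
    genome: GenomeDef
    boundary_halfwidth: int = 10_000

    def boundaries(self) -> PeakSet:
        out = []
        for tad in self.tads:
            length = self.genome.chrom_lengths[tad.chrom]
            for edge in (tad.start, tad.end):
                s = max(0, edge - self.boundary_halfwidth)
                e = min(length, edge + self.boundary_halfwidth)
                if e > s:
                    out.append(Interval(tad.chrom, s, e))
        return merge_intervals(PeakSet(out, label="TAD_boundary"))


def _observed_fracs(sites: PeakSet, seg_arrays, n_states: int) -> np.ndarray:
    """Fraction of sites (midpoint rule) per state 1..n_states; denominator is
    all sites, so unassigned midpoints simply dilute every state."""
    counts = np.zeros(n_states + 1, dtype=np.int64)
    n_sites = len(sites.intervals)
    for iv in sites.intervals:
        entry = seg_arrays.get(iv.chrom)
        if entry is None:
            continue
        arr, lab = entry
        mid = iv.midpoint
        idx = np.searchsorted(arr[:, 0], mid, side="right") - 1
        if idx >= 0 and mid < arr[idx, 1]:
            counts[lab[idx]] += 1
    return counts[1:] / max(n_sites, 1)


def state_fold_enrichment(
    sites: PeakSet,
    seg: StateSegmentation,
    genome: Optional[GenomeDef] = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> StateEnrichment:
    """Fold enrichment/depletion per chromatin state against shuffled sites."""
    if not sites.intervals:
        raise ValueError("state_fold_enrichment requires non-empty sites")
    genome = genome or seg.genome
    arrays = seg.arrays()
    obs = _observed_fracs(sites, arrays, seg.n_states)
    rng = np.random.default_rng(seed)
    acc = np.zeros(seg.n_states)
    for _ in range(n_shuffles):
        shuf = shuffle_intervals(sites, genome, rng)
        acc += _observed_fracs(shuf, arrays, seg.n_states)
    exp = acc / n_shuffles
    fold = {}
    for s in range(1, seg.n_states + 1):
        fold[s] = float(obs[s - 1] / exp[s - 1]) if exp[s - 1] > 0 else None
    return StateEnrichment(
        observed_frac={s: float(obs[s - 1]) for s in range(1, seg.n_states + 1)},
        expected_frac={s: float(exp[s - 1]) for s in range(1, seg.n_states + 1)},
        fold=fold, n_shuffles=n_shuffles,
    )


def relative_state_score(
    subset: PeakSet,
    all_set: PeakSet,
    seg: StateSegmentation,
    genome: Optional[GenomeDef] = None,
) -> dict[int, Optional[float]]:
    """Ratio of Fisher odds ratios: OR(subset vs state) / OR(parent vs state).

    > 1 means the subset is enriched in that state *relative to* its parent
    set; None marks states with no segments or an undefined denominator.
    """
    genome = genome or seg.genome
    scores: dict[int, Optional[float]] = {}
    for s in range(1, seg.n_states + 1):
        state_peaks = seg.state_peakset(s)
        if not state_peaks.intervals:
            scores[s] = None
            continue
        or_sub = fisher_overlap(subset, state_peaks, genome).odds_ratio
        or_all = fisher_overlap(all_set, state_peaks, genome).odds_ratio
        scores[s] = float(or_sub / or_all) if or_all > 0 and math.isfinite(or_all) else None
    return scores


def anchor_class_enrichment(
    sites: PeakSet,
    promoters: PeakSet,
    enhancers: PeakSet,
    tads: TADSet,
    genome: GenomeDef,
    seed: int = 0,
) -> dict[str, dict[str, OverlapTestResult]]:
    """Fisher overlap of a site set with promoters, enhancers and TAD
    boundaries, plus the same three tests for one shuffled replicate of the
    sites (the randomization control)."""
    classes = {
        "promoter": promoters,
        "enhancer": enhancers,
        "tad_boundary": tads.boundaries(),
    }
    for name, ps in classes.items():
        if not ps.intervals:
            raise ValueError(f"empty class set {name!r}")
    shuffled = shuffle_intervals(sites, genome, seed)
    return {
        "observed": {n: fisher_overlap(sites, ps, genome) for n, ps in classes.items()},
        "shuffled": {n: fisher_overlap(shuffled, ps, genome) for n, ps in classes.items()},
    }
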