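"""Interval-set algebra and overlap statistics.

Implements the primitives every downstream stage leans on: merging, overlap
pair counting, a bedtools-``fisher``-style 2x2 contingency test, length- and
count-preserving interval shuffling (the randomization null), upper-tail
hypergeometric set overlap, and a two-sample rank test with an exact
enumeration mode.

Overlap is defined as >= 1 shared bp; abutting half-open intervals do not
overlap. Sets are merged before any overlap counting, so duplicates within a
set never double-count.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeDef, Interval

__all__ = [
    "PeakSet",
    "OverlapTestResult",
    "merge_intervals",
    "count_intersections",
    "fisher_overlap",
    "shuffle_intervals",
    "hypergeom_set_overlap",
    "rank_test",
]


@dataclass
class PeakSet:
    """A labelled collection of genomic intervals (OCRs, TF binding sites...)."""

    intervals: list[Interval]
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """(n,2) start/end arrays per chromosome, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
            for c, spans in out.items()
        }

    @property
    def total_bp(self) -> int:
        """Union bp covered (after implicit merge)."""
        return sum(iv.length for iv in merge_intervals(self).intervals)

    def mean_length(self) -> float:
        if not self.intervals:
            raise ValueError(f"empty peak set {self.label!r}")
        return float(np.mean([iv.length for iv in self.intervals]))

    def midpoints(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv.midpoint)
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


@dataclass(frozen=True)
class OverlapTestResult:
    """2x2 overlap contingency table with Fisher p and odds ratio."""

    n11: int
    n12: int
    n21: int
    n22: int
    odds_ratio: float
    p_two_sided: float

    def as_table(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


def merge_intervals(peaks: PeakSet, genome: Optional[GenomeDef] = None) -> PeakSet:
    """Return the sorted, non-overlapping union of ``peaks``.

    Idempotent; covers exactly the same bp. Abutting intervals ([0,10),[10,20))
    are merged into one, matching the union-of-coverage semantics overlap
    counting requires.
    """
    if genome is not None:
        genome.validate_all(peaks.intervals)
    merged: list[Interval] = []
    for chrom in sorted({iv.chrom for iv in peaks.intervals}):
        arr = sorted(
            (iv.start, iv.end) for iv in peaks.intervals if iv.chrom == chrom
        )
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s > cur_e:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        merged.append(Interval(chrom, cur_s, cur_e))
    return PeakSet(merged, label=peaks.label)


def _overlap_counts_per_a(a_arr: np.ndarray, b_arr: np.ndarray) -> np.ndarray:
    """For each merged-A interval, number of merged-B intervals it overlaps.

    Both inputs are sorted non-overlapping (n,2) arrays, so starts and ends
    are each individually sorted and searchsorted suffices.
    """
    b_starts = b_arr[:, 0]
    b_ends = b_arr[:, 1]
    lo = np.searchsorted(b_ends, a_arr[:, 0], side="right")  # B fully left of A
    hi = np.searchsorted(b_starts, a_arr[:, 1], side="left")  # B starting before A ends
    return np.maximum(hi - lo, 0)


def count_intersections(a: PeakSet, b: PeakSet) -> int:
    """Number of intersecting interval pairs between merged A and merged B.

    Each overlapping (merged-A, merged-B) pair counts once; the count is
    symmetric in its arguments.
    """
    if not a.intervals or not b.intervals:
        return 0
    a_chrom = merge_intervals(a).by_chrom()
    b_chrom = merge_intervals(b).by_chrom()
    total = 0
    for chrom, a_arr in a_chrom.items():
        if chrom not in b_chrom:
            continue
        total += int(_overlap_counts_per_a(a_arr, b_chrom[chrom]).sum())
    return total


def intersecting_mask(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Boolean mask, per *original* query interval, of >=1 bp overlap with subject."""
    subj = merge_intervals(subject).by_chrom() if subject.intervals else {}
    mask = np.zeros(len(query.intervals), dtype=bool)
    for i, iv in enumerate(query.intervals):
        arr = subj.get(iv.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr[:, 1], iv.start, side="right")
        hi = np.searchsorted(arr[:, 0], iv.end, side="left")
        mask[i] = hi > lo
    return mask


def _haldane_odds_ratio(n11: int, n12: int, n21: int, n22: int) -> float:
    cells = [n11, n12, n21, n22]
    if any(c == 0 for c in cells):
        n11, n12, n21, n22 = (c + 0.5 for c in cells)
    return (n11 * n22) / (n12 * n21)


def fisher_overlap(a: PeakSet, b: PeakSet, genome: GenomeDef) -> OverlapTestResult:
    """bedtools-``fisher``-style overlap enrichment test between two peak sets.

    The 2x2 table is built as:

    * ``n11`` — intersecting merged-pair count,
    * ``n12`` — ``|A| - n11``, ``n21`` — ``|B| - n11`` (clipped at 0; a merged
      interval may span several of the other set),
    * ``n22`` — ``max(0, floor(G_eff / (meanLen(A) + meanLen(B))) - n11 - n12
      - n21)`` with ``G_eff`` the genome length minus blacklisted bp, i.e. the
      effective genome expressed in units of a typical A+B interval footprint.

    p is the exact two-sided Fisher probability; the odds ratio gets a
    Haldane–Anscombe +0.5 on every cell whenever any cell is zero.
    """
    if not a.intervals or not b.intervals:
        raise ValueError("fisher_overlap requires two non-empty peak sets")
    g_eff = genome.effective_length
    if g_eff <= 0:
        raise ValueError("effective genome length is zero (blacklist covers genome)")
    a_m = merge_intervals(a, genome)
    b_m = merge_intervals(b, genome)
    n11 = count_intersections(a_m, b_m)
    n12 = max(0, len(a_m) - n11)
    n21 = max(0, len(b_m) - n11)
    slots = int(g_eff // (a_m.mean_length() + b_m.mean_length()))
    n22 = max(0, slots - n11 - n12 - n21)
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return OverlapTestResult(
        n11=n11, n12=n12, n21=n21, n22=n22,
        odds_ratio=_haldane_odds_ratio(n11, n12, n21, n22),
        p_two_sided=float(min(1.0, p)),
    )


def shuffle_intervals(
    peaks: PeakSet,
    genome: GenomeDef,
    seed,
    within_chrom: bool = True,
    max_tries: int = 1000,
) -> PeakSet:
    """Random re-placement of intervals preserving the length multiset.

    Placements are uniform over valid start positions, rejected if they
    intersect the genome's exclusion set. ``within_chrom`` keeps each interval
    on its own chromosome; otherwise the target chromosome is sampled with
    probability proportional to its length. ``seed`` may be an int or an
    already-constructed :class:`numpy.random.Generator`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl = (
        merge_intervals(PeakSet(list(genome.exclude))).by_chrom()
        if genome.exclude else {}
    )
    names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()

    out: list[Interval] = []
    for iv in peaks.intervals:
        placed = False
        for _ in range(max_tries):
            if within_chrom:
                chrom = iv.chrom
            else:
                chrom = names[rng.choice(len(names), p=probs)]
            room = genome.chrom_lengths[chrom] - iv.length
            if room < 0:
                continue
            start = int(rng.integers(0, room + 1))
            end = start + iv.length
            arr = excl.get(chrom)
            if arr is not None:
                lo = np.searchsorted(arr[:, 1], start, side="right")
                hi = np.searchsorted(arr[:, 0], end, side="left")
                if hi > lo:
                    continue
            out.append(Interval(chrom, start, end, name=iv.name, strand=iv.strand))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place shuffled interval of length {iv.length} "
                f"({iv.chrom}:{iv.start}-{iv.end}) after {max_tries} tries"
            )
    return PeakSet(out, label=f"{peaks.label}_shuffled" if peaks.label else "shuffled")


def hypergeom_set_overlap(n_a: int, n_b: int, n_ab: int, universe: int) -> float:
    """Upper-tail P(X >= n_ab) for X ~ Hypergeom(universe, n_b successes, n_a draws)."""
    if n_ab > min(n_a, n_b) or n_a > universe or n_b > universe or min(n_a, n_b, n_ab, universe) < 0:
        raise ValueError(
            f"inconsistent overlap counts: nA={n_a}, nB={n_b}, nAB={n_ab}, "
            f"universe={universe}"
        )
    if n_ab == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_ab - 1, universe, n_b, n_a))


def _rank_sum(values: np.ndarray, n_a: int) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(values)  # midranks for ties
    return float(ranks[:n_a].sum()), ranks


def rank_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> float:
    """Two-sided two-sample rank-sum (Wilcoxon/Mann-Whitney) p-value.

    ``exact`` enumerates every C(nA+nB, nA) relabeling of the pooled midranks
    (valid under ties) and is only allowed for nA+nB <= 20; ``normal_approx``
    uses the tie- and continuity-corrected normal approximation; ``auto``
    picks exact when feasible.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_test requires two non-empty groups")
    n, m = a.size, b.size
    if mode == "auto":
        mode = "exact" if n + m <= 20 else "normal_approx"
    if mode == "normal_approx":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return float(res.pvalue)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if n + m > 20:
        raise ValueError("exact mode limited to nA+nB <= 20")
    pooled = np.concatenate([a, b])
    w_obs, ranks = _rank_sum(pooled, n)
    mean_w = ranks.sum() * n / (n + m)
    dev_obs = abs(w_obs - mean_w)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total
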