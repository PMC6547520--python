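"""Genome definition and elementary interval records.

Coordinates are 0-based half-open ``[start, end)`` throughout (BED
convention). A :class:`GenomeDef` declares chromosome names and lengths and
optionally carries an exclusion set (e.g. an ENCODE-style blacklist) that is
subtracted from the effective genome size and avoided by interval shuffling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional


@dataclass(frozen=True)
class Interval:
    """A genomic interval, half-open ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeDef:
    """Chromosome names/lengths plus an optional exclusion (blacklist) set."""

    chrom_lengths: dict[str, int]
    exclude: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) == 0:
            raise ValueError("genome must declare at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for iv in self.exclude:
            self.validate(iv)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def excluded_bp(self) -> int:
        """Total blacklisted bp (exclusion intervals merged per chromosome)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.exclude:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        total = 0
        for spans in by_chrom.values():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total

    @property
    def effective_length(self) -> int:
        """Genome length minus blacklisted bp."""
        return self.total_length - self.excluded_bp

    def validate(self, iv: Interval) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_lengths[iv.chrom]}"
            )

    def validate_all(self, intervals: Iterable[Interval]) -> None:
        for iv in intervals:
            self.validate(iv)
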