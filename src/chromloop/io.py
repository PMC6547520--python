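"""Readers and writers for the plain-text formats the pipeline consumes.

All coordinates on disk are BED-style 0-based half-open. Every writer emits a
dialect its paired reader round-trips losslessly.

Formats
-------
* BED3/BED6 and ENCODE narrowPeak for peak sets; chrom.sizes (two-column TSV);
  BED4 chromatin-state segmentations (state label in the name column).
* Region x sample count matrices: ``chrom  start  end  region_id  <sample>...``
  with a ``#condition:`` header comment mapping samples to conditions.
* Gene tables: ``gene_id  chrom  tss  strand  fpkm_<sample>...  de_flag  de_fold``.
* Loop tables (ibed-like): ``bait_chr bait_start bait_end bait_genes oe_chr
  oe_start oe_end oe_is_bait oe_genes score loop_id`` with genes
  semicolon-joined.
* Fragments: BED3+sample, or BEDPE collapsed to the outer fragment.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genome import GenomeDef, Interval
from .intervals import PeakSet

PathLike = Union[str, Path]


# ---------------------------------------------------------------- chrom.sizes

def read_chrom_sizes(path: PathLike, blacklist: Optional[PathLike] = None) -> GenomeDef:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise ValueError(f"duplicate chromosome {dup!r} in {path}")
    genome = GenomeDef(dict(zip(df["chrom"], df["length"])))
    if blacklist is not None:
        genome.exclude = read_bed(blacklist).intervals
        genome.validate_all(genome.exclude)
    return genome


def write_chrom_sizes(genome: GenomeDef, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


# ------------------------------------------------------------------- BED/peak

def read_bed(path: PathLike, label: str = "") -> PeakSet:
    """BED3/BED4/BED6 or narrowPeak; extra columns beyond 6 are ignored."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            intervals.append(Interval(chrom, start, end, name=name,
                                      score=score, strand=strand))
    return PeakSet(intervals, label=label or Path(path).stem)


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                     f"{score}\t{iv.strand}\n")


# ------------------------------------------------------------- count matrices

def write_count_matrix(regions: list[Interval], samples: list[tuple[str, str]],
                       counts: np.ndarray, path: PathLike) -> None:
    """``samples`` is a list of (sample_id, condition) pairs."""
    cond_line = "#condition:" + ",".join(f"{sid}={cond}" for sid, cond in samples)
    df = pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "region_id": [r.name or f"region_{i}" for i, r in enumerate(regions)],
    })
    for j, (sid, _) in enumerate(samples):
        df[sid] = counts[:, j]
    with open(path, "w") as fh:
        fh.write(cond_line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_count_matrix(path: PathLike):
    """Returns (regions, samples, counts) as written by :func:`write_count_matrix`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#condition:"):
            raise ValueError(f"{path}: missing #condition: header line")
        cond = dict(item.split("=") for item in header[len("#condition:"):].split(","))
        df = pd.read_csv(fh, sep="\t")
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end", "region_id")]
    samples = [(sid, cond[sid]) for sid in sample_ids]
    regions = [Interval(r.chrom, r.start, r.end, name=r.region_id)
               for r in df.itertuples()]
    counts = df[sample_ids].to_numpy(dtype=np.int64)
    return regions, samples, counts


# ------------------------------------------------------------------ gene TSVs

def write_genes(genes: list, path: PathLike) -> None:
    rows = []
    for g in genes:
        row = {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
               "strand": g.strand}
        for sid, v in g.fpkm_by_sample.items():
            row[f"fpkm_{sid}"] = v
        row["de_flag"] = g.de_flag
        row["de_fold"] = g.de_fold
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: PathLike) -> list:
    from .diffacc import GeneModel  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t")
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm_")]
    genes = []
    for r in df.itertuples():
        genes.append(GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom), tss=int(r.tss),
            strand=str(r.strand),
            fpkm_by_sample={c[len("fpkm_"):]: float(getattr(r, c)) for c in fpkm_cols},
            de_flag=str(r.de_flag), de_fold=float(r.de_fold),
        ))
    return genes


# ----------------------------------------------------------------- loop table

LOOP_COLUMNS = ["bait_chr", "bait_start", "bait_end", "bait_genes",
                "oe_chr", "oe_start", "oe_end", "oe_is_bait", "oe_genes",
                "score", "loop_id"]


def write_loops(loops, path: PathLike) -> None:
    df = loops.df.copy()
    df["bait_genes"] = df["bait_genes"].map(";".join)
    df["oe_genes"] = df["oe_genes"].map(";".join).replace("", ".")
    df[LOOP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_loops(path: PathLike):
    from .loopreg import LoopSet  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t")
    missing = set(LOOP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing loop columns {sorted(missing)}")
    for col, row_offset in (("bait_start", 2), ("oe_start", 2)):
        bad = df[col] >= df[col.replace("start", "end")]
        if bad.any():
            raise ValueError(
                f"{path}: line {int(bad.idxmax()) + row_offset}: start >= end"
            )
    df["bait_genes"] = df["bait_genes"].map(lambda s: tuple(str(s).split(";")))
    df["oe_genes"] = df["oe_genes"].map(
        lambda s: () if s in (".", "", "nan") or (isinstance(s, float) and np.isnan(s))
        else tuple(str(s).split(";"))
    )
    df["oe_is_bait"] = df["oe_is_bait"].astype(int)
    return LoopSet(df)


# ------------------------------------------------------------------ fragments

def write_fragments(frag_df: pd.DataFrame, path: PathLike) -> None:
    frag_df[["chrom", "start", "end", "sample_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_fragments(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "sample_id"],
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "sample_id": str})
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: fragment with end <= start")
    return df


def read_bedpe_fragments(path: PathLike, sample_id: str = "s1") -> pd.DataFrame:
    """Collapse BEDPE mate pairs to outer fragments [min start, max end)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                     names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
    if (df["chrom1"] != df["chrom2"]).any():
        raise ValueError(f"{path}: inter-chromosomal mate pair")
    return pd.DataFrame({
        "chrom": df["chrom1"],
        "start": df[["start1", "start2"]].min(axis=1),
        "end": df[["end1", "end2"]].max(axis=1),
        "sample_id": sample_id,
    })


# -------------------------------------------------------------------- v-plots

def write_vplot(vp, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#dist_edges:" + ",".join(map(str, vp.dist_edges)) + "\n")
        fh.write("#len_edges:" + ",".join(map(str, vp.len_edges)) + "\n")
        np.savetxt(fh, vp.counts, fmt="%d", delimiter="\t")


def read_vplot(path: PathLike):
    from .fragsig import VPlotMatrix  # deferred

    with open(path) as fh:
        dist_edges = np.array(fh.readline().split(":", 1)[1].split(","), dtype=np.int64)
        len_edges = np.array(fh.readline().split(":", 1)[1].split(","), dtype=np.int64)
        counts = np.loadtxt(fh, dtype=np.int64, delimiter="\t", ndmin=2)
    return VPlotMatrix(dist_edges=dist_edges, len_edges=len_edges, counts=counts,
                       n_total=int(counts.sum()))
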