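# chromloop

Integrative regulatory-genomics analysis linking **differential chromatin
accessibility** to **3-D promoter–enhancer wiring**, built for the study
design where ATAC-seq in two conditions (control vs p63-mutant
keratinocytes, as in EEC-syndrome models) is combined with transcription
factor ChIP peaks (p63, CTCF), an 18-state chromatin segmentation, TADs,
RNA-seq expression, and promoter-capture Hi-C (PCHiC) loops.

The package is a library first: every stage is an importable function, the
`examples/` scripts show one capability each, and a thin `chromloop` CLI
wraps the pipeline for shell use. All inputs can be produced by a seeded
synthetic-data generator that records its planted truth, so every statistic
the package reports can be validated by parameter recovery.

## What it computes

* **Differential OCRs** — region×sample ATAC counts are modelled as negative
  binomial, `Var(K) = μ + αμ²`, with median-of-ratios size factors. Per-region
  dispersion is a method-of-moments estimate averaged (weight 0.5) with a
  fitted `α(μ) = a₀ + a₁/μ` trend; accessibility change is a Wald test on
  `log₂(mutant/control)`. Regions with `|log₂FC| ≥ log₂ 2` at `p < 0.05`
  split into Ctr-OCRs and Mt-OCRs.
* **TF-bound OCRs and overlap statistics** — peak-level intersections, a
  bedtools-`fisher`-style 2×2 exact test (effective genome divided into
  `G_eff / (meanLen A + meanLen B)` slots), length-preserving interval
  shuffling as the randomization null, and upper-tail hypergeometric
  gene-set overlap.
* **Fragment architecture** — V-plots (fragment length × midpoint distance
  from a motif center), insert-size spectra, and nucleosome-free (<150 bp) /
  mononucleosome ([150, 250) bp) band fractions.
* **Chromatin-state enrichment** — per-state fold enrichment against
  shuffled placements, and the *relative score*
  `OR(subset vs state) / OR(parent set vs state)`.
* **Loop regulation** — CHiCAGO-score filtering (≥ 5), promoter–enhancer /
  promoter–promoter typing and span statistics, OCR→anchor mapping with
  loops-per-OCR accounting, expression quartiles (Q0 = FPKM < 1, Q1–Q4),
  loops-per-gene vs expression and DE status (rank-sum test), anchored-OCR →
  target-gene assignment through the loops, co-regulated gene overlap, and
  the **same-loop / different-loop topology classifier**: for a gene reached
  by both TFs, does one loop carry both TF-bound OCRs (at opposite anchors,
  both at the promoter, or both at the enhancer), or do the TFs only meet
  the gene through different loops?

## Worked example

`python examples/04_loop_topology.py` prints (seed 17):

```
retained 2412 loops: 86.9% promoter-enhancer, 13.1% promoter-promoter; median cis span 263.2 kb
mean loops per gene by expression bin: {'Q0': 1.52, 'Q1': 2.65, 'Q2': 4.14, 'Q3': 6.22, 'Q4': 8.82}
DE genes vs all expressed, rank-test p = 0.00033 (DE genes sit on more loops)
214 p63-target and 226 CTCF-target genes; overlap 203 (hypergeometric p = 3.4e-112)
gene classes: {'same_loop': 203, 'different_loops': 0, 'single_tf': 34, 'none': 336}
same-loop topology fractions (per gene): {'opposite_anchors': 0.128, 'both_promoter': 0.65, 'both_enhancer': 0.222}
24 of 203 co-regulated genes are differentially expressed (11.8%)
```

Reading it: loop types split ~87/13 as configured; loops per gene rise
monotonically with expression bin; genes targeted by both TF-bound OCR sets
overlap far beyond chance; and among genes where both TFs act on one loop,
most carry both TF-bound OCRs at the promoter anchor — the planted 0.2 /
0.6 / 0.2 mixture of opposite-anchor / both-promoter / both-enhancer
configurations, recovered.

The other examples cover differential calling (`01`), V-plots and band
fractions (`02`), state/class enrichment with shuffled controls (`03`), and
the deterministic accounting fixtures (`05`).

## Command line

```bash
chromloop simulate --seed 1 --out-dir sim/      # inputs + manifest + truth
chromloop diffacc  --counts sim/counts.tsv --out diff.tsv
chromloop loops    --loops sim/loops.tsv --score-min 5
chromloop report   --seed 1 --out-dir out/      # full pipeline, metrics.json
```

## Layout

```
src/chromloop/   intervals, diffacc, fragsig, chromstate, loopreg, sim,
                 pipeline, cli, io, genome
examples/        one narrative script per capability
tests/           pytest suite (unit, hypothesis properties, acceptance)
docs/methods.md  model, assumptions, parameter choices, limitations
```
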