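# Methods

## Scope and data model

chromloop analyses two-condition chromatin experiments at the level of
*derived* data: interval sets (BED/narrowPeak), region×sample ATAC count
matrices, paired-end fragment records, gene models with FPKM, chromatin-state
segmentations, TADs, and post-called promoter-capture Hi-C interactions with
confidence scores. Read alignment, peak calling, motif discovery and
interaction calling are upstream of the package and out of scope.
Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared bp,
so abutting intervals do not overlap.

## Differential accessibility

Counts are modelled as negative binomial with `Var(K) = μ + αμ²`.

* **Size factors** are median-of-ratios: factor_j = median over
  all-positive regions of `counts[r,j] / geomean_r`. Scaling one of m
  columns by c moves its factor by `c^((m−1)/m)` — the geometric-mean
  reference absorbs `c^(1/m)` — so factor *ratios* are exactly
  c-equivariant; the unit tests lock both laws.
* **Dispersion**: per region, a method-of-moments estimate
  `(s² − m̄)/m̄²` per condition, averaged across conditions and clipped to
  [0, 10]; a trend `α(μ) = a₀ + a₁/μ` is least-squares fitted on regions
  with positive estimates (coefficients floored at 0, constant fallback).
  The working dispersion is the 0.5/0.5 weighted average of the per-region
  estimate and the trend value — the information sharing that makes
  2-vs-2 designs testable. On its own generated null this recovers the
  planted α ≈ 0.05 essentially unbiased (mean estimate 0.052).
* **Test**: Wald z on `log₂((m̄_mut + ½)/(m̄_ctr + ½))` with a delta-method
  standard error from the NB variance,
  `Var(m̄_c) = (m̄_c Σ 1/s_j + n α m̄_c²)/n²`. Benjamini–Hochberg adjusted
  p-values are reported alongside raw p. Direction calls use
  `|log₂FC| ≥ log₂(fc_threshold)` and raw `p < 0.05` for OCRs (gene-level
  DE uses adjusted p, threshold 1.5-fold, matching the two-tier convention
  of the source design). The pooled type-I rate at p < 0.05 across a
  three-seed null sweep is ≈ 0.06; individual 2000-region draws scatter
  ±0.01 around it. An independent NB GLM implementation (pydeseq2) agrees
  with the log₂FC estimates to r > 0.999 on planted data and serves as a
  cross-check in the test suite, never as the implementation.

## Overlap statistics

`fisher_overlap` reconstructs the bedtools-`fisher` heuristic: n11 is the
merged-pair intersection count, n12/n21 the remaining set sizes (clipped at
0 — one merged interval may span several partners), and n22 fills the table
up to `⌊G_eff/(meanLen A + meanLen B)⌋` slots, with G_eff the genome minus
blacklisted bp. p is the exact two-sided Fisher probability; odds ratios
apply Haldane–Anscombe +0.5 to all cells when any cell is 0. The
construction assumes both sets are made of many comparably sized intervals;
when one set is a handful of very large intervals (merged TAD boundaries vs
thousands of sites) the table degenerates and single-draw odds ratios are
Poisson-noisy — randomization controls therefore average the OR over
shuffled replicates.

`shuffle_intervals` preserves the length multiset exactly, samples start
positions uniformly (chromosome kept, or drawn ∝ length), rejects
blacklist hits, and is deterministic given a seed.

`rank_test` is a *two-sample* rank-sum test although the source figure
legend names the signed-rank test: the compared groups (DE genes vs all
expressed genes) are unpaired, so the signed-rank pairing does not exist.
Exact mode enumerates all C(nA+nB, nA) relabelings of the pooled midranks
(valid under ties, limited to nA+nB ≤ 20); the asymptotic mode is the tie-
and continuity-corrected normal approximation.

## Fragment architecture

Fragments are assigned to anchor points by **midpoint** (V-plots are
midpoint-constructions); each fragment counts once per center within the
window for V-plots, and once overall for band fractions. The
mononucleosome band is [150, 250) bp around the observed ~190 bp flanking
nucleosome mode; nfr + mono + rest = 1 exactly. No Tn5 +4/−5 offset is
applied: synthetic fragments are already insertion-site coordinates (a flag
exists for real data).

## Chromatin states and classes

Sites are attributed to states by midpoint (no fractional multi-state
attribution); observed state fractions are compared with the mean over
length-preserving shuffles (fold = observed/expected, undefined when the
expectation is 0). The *relative score* divides the subset's Fisher OR per
state by its parent set's, so subset = parent gives exactly 1. The two
pathways — shuffle-based folds and Fisher odds ratios — are deliberately
kept distinct, as they answer against different nulls. TAD boundaries are
±10 kb (configurable) around TAD edges, clipped to chromosomes.

## Loops and co-regulation topology

Loops below score 5 (inclusive threshold: ≥ 5 is kept) are dropped up
front. Spans are |anchor midpoint differences| for cis loops only; trans
loops stay in the anchor logic. An OCR is anchored if it overlaps either
end of ≥ 1 loop; a loop touched at both ends by one OCR counts once for
that OCR (distinct-loops rule for the mean-loops-per-OCR statistic).
Target genes: an OCR at a loop's other end gains the paired bait's genes;
an OCR inside a bait gains that bait's genes, plus the interacting
promoter's genes for promoter–promoter loops. The universe for the
co-regulation hypergeometric test is all loop-connected genes.

Topology: per loop of a gene, each TF set's presence is resolved per
anchor. A gene is *same_loop* when some loop carries both TFs; that loop's
configuration is both-at-bait → both_promoter, both at a PE other end →
both_enhancer (a PP other end is a promoter, so co-occupancy there is
both_promoter), otherwise opposite_anchors. Mixed occupancy resolves by
precedence both_promoter > both_enhancer > opposite_anchors — promoter
co-occupancy dominates empirically. *different_loops* marks genes both TFs
reach but never on one loop. Cohort summaries expose both denominators:
fractions over qualifying loops and per-gene labels (precedence over the
gene's qualifying loops).

## Synthetic data and what it does (not) show

The generator emulates the structures the pipeline consumes at ~1/10
scale: 2 × 10 Mb chromosomes, 600 genes, 2000 OCRs (500 bp) with NB counts
(baseline lognormal around ~150 reads, dispersion 0.05, 2 replicates per
condition, 10% planted regions at |log₂FC| = 2), TF sites seeded in 60% of
OCRs, 20k fragments per condition from an 80 ± 25 / 190 ± 20 bp normal
mixture (NFR weights 0.6 vs 0.4, ~0.195 expected band-fraction difference),
an 18-state segmentation (exponential segment lengths, mean 22 kb), TADs
(mean ~0.9 Mb), and loops per gene Poisson with expression-bin rates
(1, 2, 4, 6, 8) for Q0..Q4 and a 2× DE multiplier, promoter–promoter
fraction 0.135, lognormal spans with median 250.9 kb, ~10% of scores below
the 5.0 threshold. A quarter of genes (or a configured count) get a planted
same-loop topology drawn from the (0.2, 0.6, 0.2) mixture, realised by
dropping small TF-OCR intervals inside the chosen loop's anchors; planted
genes are excluded from serving as passive promoter–promoter partners so
their anchor occupancy stays attributable. One global seed spawns
independent substreams per component, so resizing one component does not
perturb another's draws.

What it does *not* emulate: genomic sequence (no GC/mappability structure),
overlapping or nested peaks, inter-chromosomal loops, distance decay in
loop scores, replicate-specific batch effects, or fragment count coupling
to accessibility. Passing recovery tests therefore demonstrates the
*statistical machinery* is correct and calibrated under its stated model,
not that real-data preprocessing artefacts are handled.

## Numerical choices

* Nearest-gene ties break to the lexicographically smaller gene id;
  distance signs are strand-aware (negative = OCR upstream of the TSS).
* Expression binning: Q0 = FPKM < 1; expressed genes rank-split into four
  groups differing by ≤ 1 in size, ties broken by gene id.
* Fixture builder (`fixture_from_counts`) lays every loop's other end on a
  2 kb slot grid; an OCR with k incidences spans k consecutive slots,
  reusing earlier slots once fresh loops are exhausted. Triples requiring
  more distinct loops per OCR than exist are rejected.
* Problem sizes in tests and the acceptance script (2000-region count
  matrices, 3-seed null sweeps, 500 planted topology genes on a 4 × 25 Mb
  genome, 20k-fragment mixtures) were chosen so every recovery statistic
  has ≥ 3–4 standard errors of headroom inside its tolerance while a full
  run stays in seconds.

## Known limitations

* The Wald test's pooled null type-I rate (~0.06 at nominal 0.05 with two
  replicates) is mildly anticonservative; with ≥ 3 replicates it tightens.
  The direction calls additionally require a 2-fold change, which keeps the
  empirical FDR of planted-effect calls ≈ 0.02–0.06.
* The fisher table heuristic degenerates for few-large-vs-many-small
  interval comparisons (see above); prefer shuffle-based folds there.
* Peak-level (not bp-level) overlap counting throughout; `bound_ocrs`
  reports OCRs containing ≥ 1 site, not site coverage.
* The exact rank test enumerates up to C(20,10) relabelings; larger groups
  must use the asymptotic mode.
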