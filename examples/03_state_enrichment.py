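"""Chromatin-state and regulatory-class enrichment with randomization nulls.

Scores a TF-bound OCR set against an 18-state segmentation (fold enrichment
over shuffled placements) and against promoters / enhancers / TAD boundaries
(bedtools-fisher-style odds ratios), with a shuffled control alongside.
"""
from chromloop import (PeakSet, SimConfig, anchor_class_enrichment,
                       simulate_all, state_fold_enrichment)
from chromloop.genome import Interval
from chromloop.pipeline import _promoter_interval

bundle = simulate_all(SimConfig(seed=5))
genome = bundle.genome

enr = state_fold_enrichment(bundle.ocrs, bundle.segmentation, genome,
                            n_shuffles=50, seed=5)
folds = {s: f for s, f in enr.fold.items() if f is not None}
top = max(folds, key=folds.get)
print(f"state folds span {min(folds.values()):.2f}..{max(folds.values()):.2f} "
      f"(top state {top}); uniform placement should hover near 1.0")

promoters = PeakSet([_promoter_interval(g, genome) for g in bundle.genes],
                    "promoter")
pe_rows = bundle.loops.df[bundle.loops.df["oe_is_bait"] == 0]
enhancers = PeakSet([Interval(str(r.oe_chr), int(r.oe_start), int(r.oe_end))
                     for r in pe_rows.itertuples()], "enhancer")
res = anchor_class_enrichment(bundle.p63_bound_ocrs, promoters, enhancers,
                              bundle.tads, genome, seed=5)
for name, r in res["observed"].items():
    ctrl = res["shuffled"][name].odds_ratio
    print(f"{name:>12}: OR = {r.odds_ratio:6.2f} (p = {r.p_two_sided:.2g}); "
          f"shuffled control OR = {ctrl:.2f}")
print("-> bound OCRs planted at loop anchors hit promoters/enhancers far "
      "above the shuffled baseline.")
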