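"""Promoter-capture Hi-C loops: filtering, expression quartiles, target
genes and same-loop/different-loop co-regulation topology.

Loops are score-filtered (CHiCAGO-style >= 5), genes binned by expression
(Q0 = FPKM < 1, then quartiles Q1..Q4), anchored OCRs mapped to their target
genes through the loops, and genes reached by both TFs classified by whether
the two TF-bound OCR sets meet on one loop or only on different loops.
"""
from chromloop import (SimConfig, classify_coregulation_topology,
                       coregulated_genes, deregulated_fraction,
                       expression_quartiles, filter_and_classify_loops,
                       loop_connected_genes, loops_per_gene, simulate_all,
                       summarize_topology, target_genes_of_ocrs)

bundle = simulate_all(SimConfig(seed=17))
loops, summary = filter_and_classify_loops(bundle.loops, score_min=5)
print(f"retained {summary.n_total} loops: "
      f"{summary.pe_fraction:.1%} promoter-enhancer, "
      f"{summary.pp_fraction:.1%} promoter-promoter; "
      f"median cis span {summary.median_span_bp / 1000:.1f} kb")

quart = expression_quartiles(bundle.genes)
profiles, per_q, p_de = loops_per_gene(loops, bundle.genes, quart)
means = {q: sum(v) / len(v) if v else 0.0 for q, v in per_q.items()}
print("mean loops per gene by expression bin:",
      {q: round(m, 2) for q, m in means.items()})
print(f"DE genes vs all expressed, rank-test p = {p_de:.2g} "
      "(DE genes sit on more loops)")

_, p63_targets = target_genes_of_ocrs(bundle.p63_bound_ocrs, loops)
_, ctcf_targets = target_genes_of_ocrs(bundle.ctcf_bound_ocrs, loops)
universe = loop_connected_genes(loops)
coreg, p = coregulated_genes(p63_targets & universe, ctcf_targets & universe,
                             universe)
print(f"{len(p63_targets)} p63-target and {len(ctcf_targets)} CTCF-target "
      f"genes; overlap {len(coreg)} (hypergeometric p = {p:.2g})")

calls = classify_coregulation_topology(loops, bundle.p63_bound_ocrs,
                                       bundle.ctcf_bound_ocrs)
topo = summarize_topology(calls)
print("gene classes:", topo["gene_class_counts"])
print("same-loop topology fractions (per gene):",
      {k: round(v, 3) for k, v in topo["gene_topology_fractions"].items()})
n_dereg, frac = deregulated_fraction(coreg, bundle.genes)
print(f"{n_dereg} of {len(coreg)} co-regulated genes are differentially "
      f"expressed ({frac:.1%})")
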