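"""ATAC fragment architecture around motif centers.

Builds per-condition fragment sets from a nucleosome-free (~80 bp) /
mononucleosome (~190 bp) length mixture with different weights, then
measures the V-plot mass and the band fractions the mixture predicts.
"""
from chromloop import SimConfig, nfr_fraction, simulate_all, vplot

bundle = simulate_all(SimConfig(seed=3, nfr_weight=(0.6, 0.4)))

for cond, frags in bundle.fragments.items():
    vp = vplot(frags, bundle.motif_centers, window=1000)
    nfr, mono = nfr_fraction(frags, bundle.motif_centers)
    print(f"{cond}: {vp.n_total} fragment-center incidences in the V-plot; "
          f"NFR fraction (<150 bp) = {nfr:.3f}, "
          f"mononucleosome fraction [150,250) = {mono:.3f}")

print("-> the control condition carries ~0.2 more sub-150 bp (nucleosome-"
      "free) fragments than the mutant, matching the planted mixture "
      "weights 0.6 vs 0.4.")
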