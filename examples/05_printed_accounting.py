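"""Replay the study-scale loop accounting with deterministic fixtures.

fixture_from_counts builds the smallest interval layout realising a given
(anchored OCRs, distinct loops, total incidences) triple, so the headline
means can be recomputed rather than quoted.
"""
from chromloop import map_ocrs_to_anchors
from chromloop.sim import fixture_from_counts

for label, triple in (("p63-bound OCRs", (388, 1674, 1674)),
                      ("CTCF-bound OCRs", (191, 1093, 1093))):
    ocrs, loops = fixture_from_counts(*triple)
    _, n_ocr, n_loop, mean = map_ocrs_to_anchors(ocrs, loops)
    print(f"{label}: {n_ocr} OCRs anchor {n_loop} loops "
          f"-> mean {mean} loops per OCR")
print("-> the CTCF-bound set is connected by more loops per OCR than the "
      "p63-bound set.")
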