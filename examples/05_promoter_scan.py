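"""Scan upstream regions for a degenerate -10 promoter element.

Plants the canonical bacterial -10 hexamer TATAAT at a known offset in
simulated upstream regions, builds the position-information matrix
(sequence-LOGO content) and scans each sequence for the consensus,
reporting positions relative to the downstream start codon.
"""

import numpy as np

from cladescan.promoter import (
    annotate_relative_position,
    build_position_matrix,
    scan_consensus,
)
from cladescan.simulate import simulate_upstream_regions

MOTIF = "TATAAT"
ANCHOR = 101  # start codon begins right after the 100-nt upstream region

seqs, truth = simulate_upstream_regions(
    n_sequences=18, length=100, motif=MOTIF, offset=83, seed=3
)

matrix = build_position_matrix(list(seqs.values()))
window = matrix.info[82 : 82 + len(MOTIF)]
print(f"mean information inside planted motif:  {np.mean(window):.2f} bits/position")
print(f"mean information elsewhere:             "
      f"{np.mean(np.delete(matrix.info, range(82, 88))):.2f} bits/position")

sid, seq = next(iter(seqs.items()))
hits = scan_consensus(seq, MOTIF, max_mismatch=0, sequence_id=sid)
for h in hits:
    rel = annotate_relative_position(h, ANCHOR)
    print(f"{sid}: {h.matched_text} at offset {h.offset} "
          f"({-rel} bases upstream of the start codon)")
print(f"planted offset: {truth.planted_promoter_offsets[sid]}")
# The planted element is fully informative (2 bits/position) against a
# near-zero random background, and the scan recovers its position
# relative to the start codon.
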