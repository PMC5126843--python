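"""NtcA binding-site geometry relative to a transcriptional start site.

Places the conserved activating site GTAACATTTGTGAC so that it spans
TSS-relative positions -48..-35 and scans the promoter.  An even-length site
has a half-integer center (-41.5 here, the canonical activating position);
the floored form matches the common "centered 42 nt upstream" phrasing.
"""

import numpy as np

from smorfkit import scan_motif

rng = np.random.default_rng(0)
site = "GTAACATTTGTGAC"
upstream, downstream = 80, 10
seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, size=upstream + downstream + 1)))
tss_index = upstream
start = tss_index - 34 - len(site)  # site ends 35 nt upstream of the TSS
seq[start : start + len(site)] = site

for hit in scan_motif("".join(seq), tss_index):
    print(f"site {hit.matched_sequence}  center {hit.center_offset}  "
          f"floored {hit.floor_offset}  -> {hit.classification}")
print("\nCenters within [-45.5, -37.5] are classified as activating-range,")
print("the geometry at which NtcA activates transcription.")
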