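"""Physicochemical report with 3xFLAG fusion arithmetic.

For each protein: length, average mass (kDa), isoelectric point, putative
transmembrane segment count (Kyte-Doolittle windows), and the same numbers
for the C-terminally 3xFLAG-tagged variant (the 69-nt tag DNA adds 23
residues, ~2.84 kDa, and drags the pI down - it carries 11 aspartates).
"""

from smorfkit import TagSpec, feature_table, translate
from smorfkit.features import FLAG_3X_DNA

tag = TagSpec()
print(f"3xFLAG tag: {len(FLAG_3X_DNA)} nt -> {tag.peptide} ({len(tag.peptide)} aa)\n")

proteins = [
    ("soluble_acidic", "MSVFPAEDDEEFIKAQESGLDEATIKAVNEQTGLSPEQVAEMIKRDAEGK"),
    ("membrane_like", "MSNLIAVLFLLIGLLVVAGLLSVAPWLLIGAGALGLLAKKFGGSE"),
    ("basic_short", "MKRKQTLRKIAKRSGAKSMRVAKK"),
]
table = feature_table(proteins, tag=tag)
print(table.to_string(index=False))
print("\nmw_tagged - mw_untagged is the same for every protein (the tag's")
print("residue mass); 'tmr' counts hydropathy segments, so the membrane-like")
print("sequence shows one and the others none.")
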