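"""Tile a mature allergen into overlapping 15-mers and round-trip it.

Builds the peanut nsLTP (Ara h 9) record from the bundled reference
peptides, re-tiles it with the array design (15-mers offset by 5) and
shows that the overlapping tiles reconstruct the mature sequence.
"""
from ltpmap import reference, reconstruct_sequence, tile_protein

record = {r.allergen_name: r for r in reference.protein_records()}["Ara h 9"]
tiles = tile_protein(record)

print(f"{record.allergen_name} ({record.isoform_label}), {len(record)} aa")
for t in tiles:
    print(f"  tile {t.index:2d}  {t.start:2d}-{t.end:2d}  {t.sequence}")
print("round-trip ok:", reconstruct_sequence(tiles) == record.mature_sequence)
# 17 tiles; the final one is a truncated 12-mer. Each prints its 1-based
# residue span on the mature protein.
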