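"""Property-distance search of an epitope peptide against homologous LTPs.

Slides the N-terminal major IgE epitope of Ara h 9 along the walnut and
peach homologs and reports each protein's best-matching window. PD of 0
is identity; 0-3 high physicochemical similarity; above 10 unrelated.
"""
from ltpmap import pd_search, reference

query = reference.TILE_SEQUENCES["Ara h 9"][0]  # LSCGQVNSALAPCIT
targets = [r for r in reference.protein_records()
           if r.allergen_name != "Ara h 9"]

print(f"query: {query}")
for match in pd_search(query, targets, best_per_target_only=True):
    print(f"  {match.target_protein}: PD {match.pd:5.2f}  "
          f"{match.start}-{match.end}  {match.window_sequence}")
# Both homologs match in their own N-terminal region with PD in the
# "recognizable similarity" band, consistent with cross-reactive epitopes.
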