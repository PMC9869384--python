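"""Published reference data for the three nsLTP allergens under study.

This module collects the printed study inputs that the rest of the package
consumes: the overlapping 15-mer peptide tables for Ara h 9.0201 (peanut),
Jug r 3.0101 (walnut) and Pru p 3.03 (peach); the per-peptide counts of
subjects with positive IgE binding in the US (n=55) and Spanish (n=17)
peanut-allergic cohorts; the intact-protein (ISAC) positivity rates; and a
published property-distance reference set for the N-terminal Ara h 9
peptide used to calibrate and validate the peptide-similarity metric.

The mature protein sequences are not stored directly: they are
reconstructed from the overlapping tiles, which both documents their
provenance and exercises the tiling round-trip.
"""

from __future__ import annotations

from functools import lru_cache

PROTEINS = ("Ara h 9", "Jug r 3", "Pru p 3")

#: N-terminal residues removed as signal peptide relative to the published
#: precursor sequence (Jug r 3: residues 1-25 absent from the array).
PRECURSOR_OFFSETS = {"Ara h 9": 0, "Jug r 3": 25, "Pru p 3": 0}

ISOFORMS = {"Ara h 9": "Ara h 9.0201", "Jug r 3": "Jug r 3.0101", "Pru p 3": "Pru p 3.03"}

#: The 17 overlapping peptides per protein as printed on the array
#: (15-mers offset by 5 residues; truncated final tile).
TILE_SEQUENCES: dict[str, list[str]] = {
    "Ara h 9": [
        "LSCGQVNSALAPCIT",
        "VNSALAPCITFLTKG",
        "APCITFLTKGGVPSG",
        "FLTKGGVPSGPCCSG",
        "GVPSGPCCSGVRGLL",
        "PCCSGVRGLLGAAKT",
        "VRGLLGAAKTTADRQ",
        "GAAKTTADRQAACNC",
        "TADRQAACNCLKAAA",
        "AACNCLKAAAGSLHG",
        "LKAAAGSLHGLNQGN",
        "GSLHGLNQGNAAALP",
        "LNQGNAAALPGRCGV",
        "AAALPGRCGVSIPYK",
        "GRCGVSIPYKISTST",
        "SIPYKISTSTNCATI",
        "ISTSTNCATIKF",
    ],
    "Jug r 3": [
        "AVITCGQVASSVGSC",
        "GQVASSVGSCIGYLR",
        "SVGSCIGYLRGTVPT",
        "IGYLRGTVPTVPPSC",
        "GTVPTVPPSCCNGVK",
        "VPPSCCNGVKSLNKA",
        "CNGVKSLNKAAATTA",
        "SLNKAAATTADRQAA",
        "AATTADRQAACECLK",
        "DRQAACECLKKTSGS",
        "CECLKKTSGSIPGLN",
        "KTSGSIPGLNPGLAA",
        "IPGLNPGLAAGLPGK",
        "PGLAAGLPGKCGVSV",
        "GLPGKCGVSVPYKIS",
        "CGVSVPYKISTSTNC",
        "PYKISTSTNCKAVK",
    ],
    "Pru p 3": [
        "LTCPQIQAGLAPCLG",
        "IQAGLAPCLGYLQRG",
        "APCLGYLQRGGVPAG",
        "YLQRGGVPAGGCCPG",
        "GVPAGGCCPGIKRLV",
        "GCCPGIKRLVGSATT",
        "IKRLVGSATTTADRQ",
        "GSATTTADRQNACKC",
        "TADRQNACKCLKTVA",
        "NACKCLKTVAGAVKG",
        "LKTVAGAVKGINPGY",
        "GAVKGINPGYAAALP",
        "INPGYAAALPSLCGV",
        "AAALPSLCGVKIPYK",
        "SLCGVKIPYKISAST",
        "KIPYKISASTNCNSV",
        "ISASTNCNSVK",
    ],
}

#: Cohort sizes for the two geographical regions.
COHORT_SIZES = {"USA": 55, "Spain": 17}

#: Published per-peptide counts of subjects with positive IgE binding
#: (median spot SNR >= 3), as (USA of 55, Spain of 17).
PREVALENCE_COUNTS: dict[str, list[tuple[int, int]]] = {
    "Ara h 9": [
        (53, 11), (28, 4), (46, 10), (53, 16), (42, 13), (33, 6), (3, 1),
        (2, 0), (16, 4), (41, 7), (23, 8), (1, 1), (0, 0), (45, 15),
        (30, 9), (15, 3), (1, 0),
    ],
    "Jug r 3": [
        (37, 4), (0, 2), (31, 4), (55, 14), (19, 7), (36, 13), (32, 10),
        (1, 0), (26, 17), (21, 3), (17, 8), (2, 2), (12, 5), (14, 3),
        (55, 17), (55, 16), (31, 13),
    ],
    "Pru p 3": [
        (21, 0), (38, 4), (22, 7), (3, 4), (54, 13), (8, 0), (2, 1),
        (0, 0), (4, 3), (10, 2), (2, 0), (4, 1), (14, 2), (54, 16),
        (40, 10), (22, 4), (0, 0),
    ],
}

#: Fraction of each cohort with intact-protein IgE binding (> 0.3 ISU-E).
#: US subjects essentially did not bind the folded proteins.
ISAC_POSITIVE_RATES = {
    "USA": {"Ara h 9": 0.02, "Jug r 3": 0.02, "Pru p 3": 0.02},
    "Spain": {"Ara h 9": 0.71, "Jug r 3": 0.65, "Pru p 3": 0.76},
}

#: Published peptide-similarity reference set for the query LSCGQVNSALAPCIT
#: (Ara h 9 peptide 1): allergen, property-distance value, start residue,
#: matching 15-mer window, end residue. Used to calibrate the scale of the
#: descriptor-based distance and to validate its rank ordering.
PD_REFERENCE_QUERY = "LSCGQVNSALAPCIT"
PD_REFERENCE_WINDOWS: list[tuple[str, float, int, str, int]] = [
    ("Ara h 9.0201", 0.0, 1, "LSCGQVNSALAPCIT", 15),
    ("Ara h 9.0101", 1.55, 25, "ISCGQVNSALAPCIP", 39),
    ("Pru p 3", 2.51, 1, "ITCGQVSSALAPCIP", 15),
    ("Zea m 14.0101", 2.69, 29, "ISCGQVASAIAPCIS", 43),
    ("Pru av 3", 3.06, 27, "LTCGQVSSNLAPCIA", 41),
    ("Mor n 3.0101", 3.2, 1, "ITCGQVSSSLAPCIN", 15),
    ("Pru d 3", 3.41, 1, "ITCGQVSSNLAPCIN", 15),
    ("Pru ar 3", 3.47, 1, "ITCGQVSSSLAPCIG", 15),
    ("Pru p 3", 3.52, 1, "ITCGQVSSSLAPCIP", 15),
    ("Hev b 12", 3.56, 25, "ITCGQVQSALVPCLS", 39),
    ("Mal d 3", 3.67, 25, "ITCGQVTSSLAPCIG", 39),
    ("Pha v 3.0201", 4.19, 27, "ISCGQVTSSLASCIP", 41),
    ("Lyc e 3", 4.19, 25, "LSCGEVTSGLAPCLP", 39),
    ("Vit v 1", 4.25, 2, "VTCGQVASALSPCID", 16),
    ("Sin a 3.0101", 4.43, 2, "LSCGTVNSNLAACIG", 16),
    ("Pha v 3.0101", 4.44, 25, "MTCGQVQSNLVPCVT", 39),
    ("Hor v 1", 4.92, 27, "LNCGQVDSKMKPCLT", 41),
    ("Len c 3.0101", 5.02, 27, "ISCGAVTSDLSPCLT", 41),
    ("Pyr c 3", 5.12, 25, "ITCSQVSANLAPCIN", 39),
    ("Fra a 3.0102", 5.28, 27, "ITCGQVASNISPCVT", 41),
    ("Cit l 3", 5.3, 1, "ITCGQVTGSLAPXIP", 15),
    ("Fra a 3.0101", 5.43, 27, "ITCGQVASNISPCLT", 41),
    ("Bra o 3.0101", 5.49, 2, "ISCGTVTSNLAPCAV", 16),
    ("Rub i 3.0101", 5.52, 27, "ITCGQVTQNVAPCFN", 41),
    ("Pru du 3.0101", 5.63, 31, "VSCGQVVNNLTPCIN", 45),
    ("Fra a 3.0201", 5.79, 27, "ITCGQVASSISPCVN", 41),
    ("Cit r 3.0101", 6.04, 1, "ITXGQVTGSLAPXIA", 15),
    ("Tri a 14.0101", 6.18, 1, "IDCGHVDSLVRPCLS", 15),
    ("Cas s 8", 6.23, 2, "ITCTQVSKSLMPCLT", 16),
    ("Art v 3.0301", 6.54, 27, "LTCSDVSTKISPCLS", 41),
    ("Art v 3.0101", 6.63, 2, "LTCSDVSNKISPCLS", 16),
    ("Pla a 3.0101", 6.7, 28, "ITCGTVVTRLTPCLT", 42),
    ("Art v 3.0202", 6.78, 26, "LTCSDVSNKITPCLN", 40),
    ("Api g 2", 6.89, 28, "LTCGQVTGKLGGCLG", 42),
    ("Jug r 3", 6.91, 2, "ITCGQVASSVGSCIG", 16),
]


@lru_cache(maxsize=None)
def mature_sequence(protein: str) -> str:
    """Mature amino-acid sequence reconstructed from the overlapping tiles."""
    from .tiling import PeptideTile, reconstruct_sequence

    tiles = []
    for i, seq in enumerate(TILE_SEQUENCES[protein]):
        start = 1 + 5 * i
        tiles.append(
            PeptideTile(protein=protein, index=i + 1, start=start,
                        end=start + len(seq) - 1, sequence=seq)
        )
    return reconstruct_sequence(tiles)


def protein_records():
    """ProteinRecord objects for the three allergens on the array."""
    from .tiling import ProteinRecord

    return [
        ProteinRecord(
            allergen_name=name,
            isoform_label=ISOFORMS[name],
            mature_sequence=mature_sequence(name),
            precursor_offset=PRECURSOR_OFFSETS[name],
        )
        for name in PROTEINS
    ]
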