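from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ltpmap import reference
from ltpmap.calling import prevalence_from_counts
from ltpmap.tiling import ProteinRecord, tile_protein

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRINTED_DISPLAYS = {
    "Ara h 9": ["0.03", "0.24", "0.24", ">0.99", ">0.99", "0.33", ">0.99",
                ">0.99", ">0.99", "0.15", ">0.99", ">0.99", ">0.99", ">0.99",
                ">0.99", ">0.99", ">0.99"],
    "Jug r 3": ["0.02", "0.18", "0.11", "0.06", "0.94", "0.79", ">0.99",
                ">0.99", "<0.001", "0.40", "0.43", "0.43", "0.79", "0.94",
                ">0.99", "0.43", "0.40"],
    "Pru p 3": ["0.01", "0.01", ">0.99", "0.21", "0.06", "0.63", "0.87",
                ">0.99", "0.69", ">0.99", ">0.99", ">0.99", "0.69", "0.71",
                "0.69", "0.69", ">0.99"],
}

# Published major-peptide memberships per cohort.
PRINTED_MAJORS = {
    ("Ara h 9", "USA"): {1, 2, 3, 4, 5, 6, 10, 14, 15},
    ("Ara h 9", "Spain"): {1, 3, 4, 5, 14, 15},
    ("Jug r 3", "USA"): {1, 3, 4, 6, 7, 15, 16, 17},
    ("Jug r 3", "Spain"): {4, 6, 7, 9, 15, 16, 17},
    ("Pru p 3", "USA"): {2, 5, 14, 15},
    ("Pru p 3", "Spain"): {5, 14, 15},
}

PRINTED_REGIONS = {
    ("Ara h 9", "USA"): ((1, 40), (46, 60), (66, 85)),
    ("Ara h 9", "Spain"): ((1, 35), (66, 85)),
    ("Jug r 3", "USA"): ((1, 45), (71, 94)),
    ("Jug r 3", "Spain"): ((16, 55), (71, 94)),
    ("Pru p 3", "USA"): ((6, 35), (66, 85)),
    ("Pru p 3", "Spain"): ((21, 35), (66, 85)),
}


@pytest.fixture(scope="session")
def protein_records() -> dict[str, ProteinRecord]:
    return {r.allergen_name: r for r in reference.protein_records()}


@pytest.fixture(scope="session")
def tiles_by_protein(protein_records):
    return {name: tile_protein(rec) for name, rec in protein_records.items()}


@pytest.fixture(scope="session")
def printed_prevalence() -> pd.DataFrame:
    """Prevalence table built from the published per-peptide counts."""
    return prevalence_from_counts(
        reference.PREVALENCE_COUNTS, reference.COHORT_SIZES)
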