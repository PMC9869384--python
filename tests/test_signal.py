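"""Spot-table ingestion, SNR computation and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ltpmap.signal import (
    SignalError,
    SpotRecord,
    aggregate_replicates,
    compute_snr,
    read_isac_table,
    read_spot_table,
    write_isac_table,
    write_spot_table,
)
from ltpmap.signal import IsacRecord


def spot(subject="S1", region="USA", protein="Ara h 9", peptide=1, rep=1, snr=5.0):
    return SpotRecord(subject_id=subject, region_label=region, protein=protein,
                      peptide_index=peptide, replicate_ordinal=rep, snr=snr)


@pytest.mark.parametrize(
    "fg, bg, sd, expected",
    [(900, 100, 50, 16.0), (100, 100, 50, 0.0), (90, 100, 5, -2.0)],
)
def test_compute_snr(fg, bg, sd, expected):
    assert compute_snr(fg, bg, sd) == pytest.approx(expected)


def test_compute_snr_rejects_nonpositive_sd():
    with pytest.raises(SignalError):
        compute_snr(900, 100, 0)


def test_plain_table_roundtrip_and_record_count(tmp_path):
    records = [
        spot(peptide=p, rep=r, snr=float(p + r))
        for p in range(1, 18)
        for r in range(1, 4)
    ]
    path = tmp_path / "spots.tsv"
    write_spot_table(records, path)
    back = read_spot_table(path)
    assert len(back) == 51
    assert back == records


def test_duplicate_spot_rejected(tmp_path):
    records = [spot(rep=2), spot(rep=2)]
    path = tmp_path / "dup.tsv"
    write_spot_table(records, path)
    with pytest.raises(SignalError, match="duplicate"):
        read_spot_table(path)


def test_missing_column_named(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"subject_id": ["S1"], "snr": [3.0]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(SignalError, match="protein"):
        read_spot_table(path)


def test_snr_column_wins_over_statistics(tmp_path):
    path = tmp_path / "both.tsv"
    pd.DataFrame(
        {"subject_id": ["S1"], "region": ["USA"], "protein": ["Ara h 9"],
         "peptide_index": [1], "replicate": [1], "snr": [7.5],
         "fg_median": [900.0], "bg_median": [100.0], "bg_sd": [50.0]}
    ).to_csv(path, sep="\t", index=False)
    (rec,) = read_spot_table(path)
    assert rec.snr == 7.5  # scanner-reported SNR preferred over recomputation


def test_genepix_dialect_computes_snr_and_drops_flagged(tmp_path):
    path = tmp_path / "slide.gpr.txt"
    pd.DataFrame(
        {"Block": [1, 1, 1], "Row": [1, 1, 2], "Column": [1, 2, 1],
         "Name": ["Ara h 9_1", "Ara h 9_1", "Ara h 9_2"],
         "ID": ["p1", "p1", "p2"],
         "F532 Median": [900.0, 600.0, 500.0],
         "B532 Median": [100.0, 100.0, 100.0],
         "B532 SD": [50.0, 50.0, 50.0],
         "Flags": [0, 0, -100]}
    ).to_csv(path, sep="\t", index=False)
    records = read_spot_table(path, dialect="genepix",
                              subject_id="S9", region_label="Spain")
    assert len(records) == 2  # flagged spot dropped
    assert records[0].snr == pytest.approx(16.0)
    assert [r.replicate_ordinal for r in records] == [1, 2]
    assert records[0].subject_id == "S9"


@pytest.mark.parametrize(
    "values, expected",
    [((2.0, 4.0, 9.0), 4.0), ((5.0, 7.0), 6.0), ((3.2,), 3.2)],
)
def test_replicate_median(values, expected):
    records = [spot(rep=i + 1, snr=v) for i, v in enumerate(values)]
    matrix = aggregate_replicates(records)
    assert matrix.values["Ara h 9"].loc["S1", 1] == pytest.approx(expected)


@given(st.lists(st.floats(-50, 500, allow_nan=False), min_size=1, max_size=6),
       st.permutations(range(6)))
def test_median_matches_sort_oracle_and_permutation_invariance(values, perm):
    records = [spot(rep=i + 1, snr=v) for i, v in enumerate(values)]
    shuffled = [spot(rep=i + 1, snr=values[j % len(values)])
                for i, j in enumerate(perm[: len(values)])]
    m1 = aggregate_replicates(records).values["Ara h 9"].loc["S1", 1]
    # sort-based oracle
    s = sorted(values)
    n = len(s)
    oracle = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
    assert m1 == pytest.approx(oracle)
    if sorted(v.snr for v in shuffled) == sorted(values):
        m2 = aggregate_replicates(shuffled).values["Ara h 9"].loc["S1", 1]
        assert m2 == pytest.approx(m1)


def test_missing_cells_stay_missing():
    records = [spot(peptide=1), spot(subject="S2", peptide=2)]
    matrix = aggregate_replicates(records)
    df = matrix.values["Ara h 9"]
    assert np.isnan(df.loc["S1", 2])
    assert np.isnan(df.loc["S2", 1])


def test_conflicting_region_labels_rejected():
    with pytest.raises(SignalError, match="conflicting region"):
        aggregate_replicates([spot(rep=1), spot(rep=2, region="Spain")])


def test_isac_reading_flags_and_errors(tmp_path):
    path = tmp_path / "isac.tsv"
    write_isac_table(
        [IsacRecord("S1", "Spain", "Ara h 9", 2.4),
         IsacRecord("S2", "USA", "Pru p 3", 0.1)], path)
    records = read_isac_table(path)
    assert records[0].out_of_range is False
    assert records[1].out_of_range is True  # below 0.3 ISU-E operating range
    bad = tmp_path / "neg.tsv"
    write_isac_table([IsacRecord("S3", "USA", "Jug r 3", 0.0)], bad)
    pd.read_csv(bad, sep="\t").assign(isu_e=-1.0).to_csv(bad, sep="\t", index=False)
    with pytest.raises(SignalError, match="negative"):
        read_isac_table(bad)
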