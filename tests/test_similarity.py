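"""Property-distance metric, global alignment and epitope projection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ltpmap import reference
from ltpmap.calling import EpitopeRegion
from ltpmap.similarity import (
    AlignmentParams,
    SimilarityError,
    global_align,
    pd_distance,
    pd_search,
    percent_identity_similarity,
    project_epitopes,
)
from ltpmap.tiling import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA, min_size=1, max_size=15)


# -- property distance ----------------------------------------------------

def test_pd_self_distance_zero():
    assert pd_distance("LSCGQVNSALAPCIT", "LSCGQVNSALAPCIT") == 0.0


def test_conservative_substitution_closer_than_radical():
    base = "LSCGQVNSALAPCIT"
    conservative = "LSCGQVNSALAPCLT"  # I -> L
    radical = "LSCGQVNSALAPCDT"  # I -> D
    assert pd_distance(base, conservative) < pd_distance(base, radical)


@given(peptides, st.data())
def test_pd_metric_axioms(a, data):
    b = data.draw(st.text(alphabet=AA, min_size=len(a), max_size=len(a)))
    c = data.draw(st.text(alphabet=AA, min_size=len(a), max_size=len(a)))
    dab, dba = pd_distance(a, b), pd_distance(b, a)
    assert dab >= 0
    assert dab == pytest.approx(dba)
    assert (dab == 0) == (a == b)
    assert pd_distance(a, c) <= dab + pd_distance(b, c) + 1e-9


def test_pd_length_mismatch_rejected():
    with pytest.raises(SimilarityError):
        pd_distance("AC", "ACD")


def test_pd_rank_agreement_with_published_reference_windows():
    query = reference.PD_REFERENCE_QUERY
    published = [row[1] for row in reference.PD_REFERENCE_WINDOWS]
    ours = [pd_distance(query, row[3]) for row in reference.PD_REFERENCE_WINDOWS]
    rho = spearmanr(published, ours).statistic
    assert rho >= 0.9


def test_pd_search_best_windows(protein_records):
    query = reference.TILE_SEQUENCES["Ara h 9"][0]
    matches = pd_search(query, [protein_records["Jug r 3"]])
    best = matches[0]
    # the same window is numbered from 2 in database coordinates that lack
    # the N-terminal Ala of the array's mature sequence
    assert best.start == 3
    assert best.window_sequence == "ITCGQVASSVGSCIG"
    # self-search: exact match at the query's own location
    self_target = ProteinRecord("q", "q", query)
    self_best = pd_search(query, [self_target])[0]
    assert (self_best.pd, self_best.start) == (0.0, 1)


def test_pd_search_skips_short_targets_and_rejects_empty():
    with pytest.raises(SimilarityError):
        pd_search("ACDEF", [])
    short = ProteinRecord("tiny", "tiny", "ACD")
    with pytest.warns(UserWarning, match="skipped"):
        matches = pd_search("ACDEF", [short, ProteinRecord("ok", "ok", "ACDEFGH")])
    assert all(m.target_protein == "ok" for m in matches)


# -- alignment ------------------------------------------------------------

def test_self_alignment_identity_and_similarity():
    seq = reference.mature_sequence("Ara h 9")
    aln = global_align(seq, seq)
    assert aln.identity_percent == 100.0
    assert aln.similarity_percent == 100.0


def test_cross_identity_within_published_tolerance(protein_records):
    published = {("Ara h 9", "Jug r 3"): 61.3, ("Ara h 9", "Pru p 3"): 59.3,
                 ("Jug r 3", "Pru p 3"): 54.8}
    for (a, b), expected in published.items():
        aln = global_align(protein_records[a].mature_sequence,
                           protein_records[b].mature_sequence)
        assert aln.identity_percent == pytest.approx(expected, abs=3.0)
        assert aln.identity_percent <= aln.similarity_percent <= 100.0


def test_conservative_pair_counts_as_similar_not_identical():
    ident, sim = percent_identity_similarity("KR", "RK")
    assert ident == 0.0
    assert sim == 100.0  # K and R share a basic group


def test_forced_deletion_gives_single_gap_column():
    aln = global_align("ACDE", "ACE")
    assert (aln.aligned_a.count("-") + aln.aligned_b.count("-")) == 1
    assert aln.aligned_a.replace("-", "") == "ACDE"
    assert aln.aligned_b.replace("-", "") == "ACE"


def test_all_gap_overlap_rejected():
    with pytest.raises(SimilarityError):
        percent_identity_similarity("AC--", "--GT")


def test_empty_sequence_rejected():
    with pytest.raises(SimilarityError):
        global_align("", "ACD")


def _gotoh_score(a, b, matrix, gap_open, gap_extend):
    """Independent affine-gap DP (three-state Gotoh) for the optimal score."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


@given(st.text(alphabet=AA, min_size=1, max_size=12),
       st.text(alphabet=AA, min_size=1, max_size=12))
def test_alignment_score_matches_dp_oracle(a, b):
    from Bio.Align import substitution_matrices

    params = AlignmentParams()
    matrix = substitution_matrices.load(params.matrix)
    expected = _gotoh_score(a, b, matrix, params.gap_open, params.gap_extend)
    assert global_align(a, b, params).score == pytest.approx(expected)


# -- projection -----------------------------------------------------------

def test_projection_examples(protein_records, tiles_by_protein):
    ara = protein_records["Ara h 9"].mature_sequence
    region = EpitopeRegion("Ara h 9", "USA", ranges=((16, 30),))
    for target, expected_tile in (("Jug r 3", 4), ("Pru p 3", 5)):
        aln = global_align(ara, protein_records[target].mature_sequence)
        (link,) = project_epitopes(aln, region, target, tiles_by_protein[target])
        assert expected_tile in link.target_tile_indices


def test_projection_self_alignment_is_identity(protein_records, tiles_by_protein):
    ara = protein_records["Ara h 9"].mature_sequence
    region = EpitopeRegion("Ara h 9", "USA", ranges=((16, 30),), peptide_indices=(4,))
    aln = global_align(ara, ara)
    (link,) = project_epitopes(aln, region, "Ara h 9", tiles_by_protein["Ara h 9"])
    assert link.target_range == (16, 30)
    assert 4 in link.target_tile_indices


def test_projection_inverse_consistency(protein_records):
    ara = protein_records["Ara h 9"].mature_sequence
    jug = protein_records["Jug r 3"].mature_sequence
    region = EpitopeRegion("Ara h 9", "USA", ranges=((16, 30),))
    fwd = global_align(ara, jug)
    (link,) = project_epitopes(fwd, region, "Jug r 3")
    back_region = EpitopeRegion("Jug r 3", "USA", ranges=(link.target_range,))
    rev = global_align(jug, ara)
    (back,) = project_epitopes(rev, back_region, "Ara h 9")
    assert back.target_range is not None
    s, e = back.target_range
    assert s <= 16 and e >= 30 or (s <= 30 and e >= 16)  # recovered range overlaps origin


def test_projection_against_all_gaps_is_empty():
    from ltpmap.similarity import PairwiseAlignment

    aln = PairwiseAlignment(aligned_a="AAAA----", aligned_b="----GGGG",
                            score=0.0, identity_percent=0.0,
                            similarity_percent=0.0, params=AlignmentParams())
    region = EpitopeRegion("src", "USA", ranges=((1, 4),))
    (link,) = project_epitopes(aln, region, "dst")
    assert link.target_range is None
    assert link.target_tile_indices == ()


def test_projection_outside_source_rejected():
    from ltpmap.similarity import PairwiseAlignment

    aln = PairwiseAlignment(aligned_a="AAAA", aligned_b="AAAA", score=0.0,
                            identity_percent=100.0, similarity_percent=100.0,
                            params=AlignmentParams())
    region = EpitopeRegion("src", "USA", ranges=((2, 9),))
    with pytest.raises(SimilarityError):
        project_epitopes(aln, region, "dst")
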