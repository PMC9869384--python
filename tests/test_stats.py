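"""Fisher exact test, FDR adjustment and rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from ltpmap.calling import AnalysisConfig
from ltpmap.signal import IsacRecord
from ltpmap.stats import (
    ContingencyTable2x2,
    StatsError,
    bh_adjust,
    compare_isac,
    compare_regions,
    fisher_exact_two_sided,
    format_pvalue,
    hypergeom_point_probabilities,
    wilcoxon_rank_sum,
)


# -- Fisher ---------------------------------------------------------------

def test_fisher_single_feasible_table_is_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(5, 0, 5, 0)) == 1.0


@pytest.mark.parametrize(
    "table, expected",
    [((53, 2, 11, 6), 1.63e-3),  # tail = sum_{j>=6} C(17,j)C(55,8-j)/C(72,8)
     ((26, 29, 17, 0), 3.644e-5)],
)
def test_fisher_known_values(table, expected):
    p = fisher_exact_two_sided(ContingencyTable2x2(*table))
    assert p == pytest.approx(expected, rel=0.02)


def test_fisher_negative_count_rejected():
    with pytest.raises(StatsError):
        ContingencyTable2x2(-1, 2, 3, 4)


@given(st.integers(1, 60), st.integers(1, 60), st.data())
def test_fisher_matches_scipy(n1, n2, data):
    if n1 + n2 > 80:
        n2 = 80 - n1
    a = data.draw(st.integers(0, n1))
    c = data.draw(st.integers(0, n2))
    table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
    ours = fisher_exact_two_sided(table)
    ref = scipy_stats.fisher_exact([[a, n1 - a], [c, n2 - c]]).pvalue
    assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


@given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 80))
def test_hypergeom_point_probabilities_normalized(r1, r2, col1):
    col1 = min(col1, r1 + r2)
    probs = hypergeom_point_probabilities(r1, r2, col1)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)


# -- BH -------------------------------------------------------------------

def test_bh_single_value_identity():
    assert bh_adjust([0.05]).tolist() == [0.05]


def test_bh_hand_worked_example():
    np.testing.assert_allclose(
        bh_adjust([0.001, 0.01, 0.03]), [0.003, 0.015, 0.03])


def test_bh_all_equal_inputs_unchanged():
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_rejects_out_of_range():
    with pytest.raises(StatsError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_statsmodels_and_permutation_invariant(pvals):
    from statsmodels.stats.multitest import multipletests

    ours = bh_adjust(pvals)
    _, ref, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(ours, ref, atol=1e-12)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(pvals))
    permuted = bh_adjust(np.asarray(pvals)[perm])
    np.testing.assert_allclose(permuted, ours[perm], atol=1e-12)
    # adjusted never below raw/m
    assert np.all(ours >= np.asarray(pvals) / len(pvals) - 1e-12)


# -- display --------------------------------------------------------------

@pytest.mark.parametrize(
    "value, expected",
    [(0.0005, "<0.001"), (0.034, "0.03"), (0.991, ">0.99"), (0.99, "0.99"),
     (0.154, "0.15")],
)
def test_pvalue_display_conventions(value, expected):
    assert format_pvalue(value) == expected


# -- compare_regions ------------------------------------------------------

def test_printed_comparison_displays(printed_prevalence):
    from conftest import PRINTED_DISPLAYS

    result = compare_regions(printed_prevalence)
    for protein, expected in PRINTED_DISPLAYS.items():
        got = result[result.protein == protein].sort_values(
            "peptide_index")["display"].tolist()
        assert got == expected


def test_identical_prevalences_all_adjusted_one():
    rows = []
    for idx in range(1, 6):
        for region in ("USA", "Spain"):
            rows.append({"protein": "p", "peptide_index": idx, "region": region,
                         "n_positive": 3, "n_total": 10, "percent": 30.0})
    result = compare_regions(pd.DataFrame(rows))
    assert (result["p_adjusted"] == 1.0).all()


def test_mismatched_grid_rejected():
    rows = [
        {"protein": "p", "peptide_index": 1, "region": "USA",
         "n_positive": 3, "n_total": 10, "percent": 30.0},
        {"protein": "p", "peptide_index": 2, "region": "Spain",
         "n_positive": 3, "n_total": 10, "percent": 30.0},
    ]
    with pytest.raises(StatsError):
        compare_regions(pd.DataFrame(rows))


# -- Wilcoxon -------------------------------------------------------------

def test_wilcoxon_identical_samples():
    assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0


def test_wilcoxon_exact_small_sample():
    assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)


def test_wilcoxon_empty_sample_rejected():
    with pytest.raises(StatsError):
        wilcoxon_rank_sum([], [1.0])


@given(
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=10),
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=10),
)
def test_wilcoxon_exact_matches_scipy(x, y):
    pooled = x + y
    if len(set(pooled)) != len(pooled):
        return  # tie handling covered separately
    ours = wilcoxon_rank_sum(x, y)
    ref = scipy_stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
    assert ours == pytest.approx(ref, abs=1e-9)


def test_wilcoxon_approximation_close_to_scipy_with_ties():
    rng = np.random.default_rng(42)
    x = np.round(rng.normal(5, 2, size=40), 1)
    y = np.round(rng.normal(6, 2, size=25), 1)
    ours = wilcoxon_rank_sum(x, y)
    ref = scipy_stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue
    assert ours == pytest.approx(ref, rel=1e-6)


# -- ISAC -----------------------------------------------------------------

def make_isac(region, allergen, values):
    return [IsacRecord(f"{region}{i}", region, allergen, v)
            for i, v in enumerate(values)]


def test_isac_positivity_strictly_above_threshold():
    records = (make_isac("USA", "Ara h 9", [0.3, 0.31]) +
               make_isac("Spain", "Ara h 9", [1.0, 0.2]))
    result = compare_isac(records)
    row = result.iloc[0]
    assert row.usa_percent_positive == 50.0  # 0.3 itself is negative
    assert row.spain_percent_positive == 50.0


def test_isac_degenerate_separation():
    records = (make_isac("USA", "Pru p 3", [0.0] * 5) +
               make_isac("Spain", "Pru p 3", [1.0] * 5))
    result = compare_isac(records)
    row = result.iloc[0]
    assert row.usa_percent_positive == 0.0
    assert row.spain_percent_positive == 100.0


def test_isac_missing_region_rejected():
    with pytest.raises(StatsError):
        compare_isac(make_isac("USA", "Ara h 9", [1.0, 2.0]))
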