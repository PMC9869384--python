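"""Exact regional comparisons: Fisher tests, FDR, rank-sum tests.

Per-peptide positivity prevalences in the two cohorts are compared with
two-sided Fisher exact tests, adjusted for multiple comparisons with the
Benjamini-Hochberg step-up procedure applied within each protein (one
family of 17 peptides per protein). Intact-protein IgE levels are
compared with the Wilcoxon rank-sum test.

The Fisher p-value follows the "sum of small p-values" convention: with
all margins fixed, it is the sum of hypergeometric point probabilities of
every table whose probability does not exceed the observed table's (up to
a small relative tolerance for ties). Point probabilities are evaluated
in log space from a cumulative log-factorial table, then summed by direct
enumeration over the feasible range, so the test is exact at any of the
cohort sizes involved here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import AnalysisConfig
from .signal import IsacRecord

#: Relative tolerance when deciding whether an alternative table is "as
#: extreme as" the observed one (guards against floating-point ties).
_FISHER_REL_TOL = 1e-7


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Positive/negative counts for one peptide in two regions.

    ``a``/``b``: region-1 positives/negatives; ``c``/``d``: region-2.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError(f"negative count in 2x2 table {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RegionComparison:
    protein: str
    peptide_index: int
    table: ContingencyTable2x2
    p_raw: float
    p_adjusted: float
    display: str
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """Regional comparison of intact-protein IgE levels for one allergen."""

    allergen: str
    n_region1: int
    n_region2: int
    percent_positive_region1: float
    percent_positive_region2: float
    p_value: float


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_LOGFACT = [0.0]


def _log_factorial(n: int) -> float:
    while len(_LOGFACT) <= n:
        _LOGFACT.append(_LOGFACT[-1] + math.log(len(_LOGFACT)))
    return _LOGFACT[n]


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(first cell = a) with both row sums and the first column sum fixed."""
    n = row1 + row2
    b = row1 - a
    c = col1 - a
    d = row2 - c
    return (
        _log_factorial(row1) + _log_factorial(row2)
        + _log_factorial(col1) + _log_factorial(n - col1)
        - _log_factorial(n)
        - _log_factorial(a) - _log_factorial(b)
        - _log_factorial(c) - _log_factorial(d)
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by enumeration of the feasible range.

    Sums the point probabilities of every table with the observed margins
    whose probability is at most the observed one (within a relative
    tolerance of 1e-7 to absorb floating-point ties).
    """
    row1, row2 = table.a + table.b, table.c + table.d
    col1 = table.a + table.c
    if row1 == 0 or row2 == 0:
        raise StatsError("empty region in contingency table")
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    log_obs = _log_hypergeom_pmf(table.a, row1, row2, col1)
    cutoff = log_obs + math.log1p(_FISHER_REL_TOL)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(a, row1, row2, col1)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


def hypergeom_point_probabilities(row1: int, row2: int, col1: int) -> np.ndarray:
    """Point probabilities over the feasible first-cell range (sums to 1)."""
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return np.array(
        [math.exp(_log_hypergeom_pmf(a, row1, row2, col1)) for a in range(lo, hi + 1)]
    )


# ---------------------------------------------------------------------------
# FDR adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj(i) = min over j >= i (sorted order) of p_(j) * m / j, capped at 1;
    tied raw p-values share an adjusted value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def format_pvalue(adjusted: float, config: AnalysisConfig | None = None) -> str:
    """Render an adjusted p-value the way the comparison tables print it."""
    config = config or AnalysisConfig()
    if adjusted < config.pvalue_floor_display:
        return f"<{config.pvalue_floor_display:g}"
    if adjusted > config.pvalue_ceiling_display:
        return f">{config.pvalue_ceiling_display:g}"
    return f"{adjusted:.{config.pvalue_decimals}f}"


def compare_regions(
    prevalence: pd.DataFrame,
    config: AnalysisConfig | None = None,
    region_order: Sequence[str] = ("USA", "Spain"),
) -> pd.DataFrame:
    """Fisher tests with per-protein FDR for every peptide's 2x2 table.

    ``prevalence`` must hold both regions on the same (protein, peptide)
    grid. Returns one row per peptide with raw and adjusted p-values, the
    display string and a significance flag at adjusted < 0.05.
    """
    config = config or AnalysisConfig()
    r1, r2 = region_order
    wide = prevalence.pivot_table(
        index=["protein", "peptide_index"], columns="region",
        values=["n_positive", "n_total"], aggfunc="first",
    )
    for region in (r1, r2):
        if ("n_positive", region) not in wide.columns:
            raise StatsError(f"prevalence table lacks region {region!r}")
    if wide.isna().any().any():
        raise StatsError("peptide grids differ between the two regions")
    rows = []
    for (protein, peptide), rec in wide.iterrows():
        a = int(rec[("n_positive", r1)])
        b = int(rec[("n_total", r1)]) - a
        c = int(rec[("n_positive", r2)])
        d = int(rec[("n_total", r2)]) - c
        table = ContingencyTable2x2(a, b, c, d)
        rows.append(
            {"protein": protein, "peptide_index": int(peptide),
             f"{r1.lower()}_positive": a, f"{r1.lower()}_total": a + b,
             f"{r2.lower()}_positive": c, f"{r2.lower()}_total": c + d,
             "p_raw": fisher_exact_two_sided(table)}
        )
    out = pd.DataFrame(rows).sort_values(["protein", "peptide_index"]).reset_index(drop=True)
    if config.fdr_scope == "per-protein":
        out["p_adjusted"] = out.groupby("protein")["p_raw"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    elif config.fdr_scope == "global":
        out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    else:
        raise StatsError(f"unknown fdr_scope {config.fdr_scope!r}")
    out["display"] = [format_pvalue(v, config) for v in out["p_adjusted"]]
    out["significant"] = out["p_adjusted"] < config.significance_level
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating the null distribution of the
    rank-sum statistic (no ties, both samples small)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mean_w = nx * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), nx):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact permutation null when both samples have at most 12
    observations and there are no ties; otherwise the normal approximation
    with tie correction and a continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if no_ties and x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N:
        return _rank_sum_exact_p(x, y)
    # normal approximation with tie correction
    nx, ny = x.size, y.size
    n = nx + ny
    order = pooled.argsort(kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    # average ranks for ties
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return 1.0
    dev = abs(w - mean_w)
    z = max(dev - 0.5, 0.0) / math.sqrt(var_w)
    return min(1.0, math.erfc(z / math.sqrt(2)))


def compare_isac(
    records: Sequence[IsacRecord],
    config: AnalysisConfig | None = None,
    region_order: Sequence[str] = ("USA", "Spain"),
) -> pd.DataFrame:
    """Per-allergen regional comparison of intact-protein IgE levels.

    Positivity is strictly above the ISU-E threshold (0.3 by default);
    levels are compared between regions with the Wilcoxon rank-sum test.
    """
    config = config or AnalysisConfig()
    if not records:
        raise StatsError("no ISAC records")
    df = pd.DataFrame(
        [
            {"allergen": r.allergen, "region": r.region_label, "isu_e": r.isu_e}
            for r in records
        ]
    )
    r1, r2 = region_order
    rows = []
    for allergen, sub in df.groupby("allergen"):
        v1 = sub.loc[sub["region"] == r1, "isu_e"].to_numpy()
        v2 = sub.loc[sub["region"] == r2, "isu_e"].to_numpy()
        if v1.size == 0 or v2.size == 0:
            raise StatsError(f"allergen {allergen!r} missing a region")
        thr = config.isac_positive_threshold
        rows.append(
            {
                "allergen": allergen,
                f"{r1.lower()}_n": v1.size,
                f"{r2.lower()}_n": v2.size,
                f"{r1.lower()}_percent_positive": round(
                    100.0 * float(np.mean(v1 > thr)), config.proportion_decimals),
                f"{r2.lower()}_percent_positive": round(
                    100.0 * float(np.mean(v2 > thr)), config.proportion_decimals),
                "wilcoxon_p": wilcoxon_rank_sum(v1, v2),
            }
        )
    return pd.DataFrame(rows)
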