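"""Positivity calling, prevalence, major-peptide classification, regions.

A peptide is called positive for a subject when its median spot SNR is 3
or greater (inclusive). Peptides positive in at least half of a cohort's
sera are "major IgE-reactive" peptides; the residue intervals of a
cohort's major tiles, with overlapping or abutting intervals merged, form
its epitope regions. Both thresholds are inclusive, and the major call
uses the exact fraction rather than the rounded percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signal import BindingMatrix
from .tiling import PeptideTile


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and formatting conventions for the analysis.

    snr_positive_threshold : median SNR at or above which a peptide is
        called positive for a subject (inclusive).
    major_fraction : minimum fraction of a cohort's sera that must be
        positive for a peptide to count as major IgE-reactive (inclusive).
    isac_positive_threshold : ISU-E value strictly above which intact-
        protein binding is positive.
    fdr_scope : family for the false-discovery-rate adjustment;
        "per-protein" adjusts across the peptides of one protein.
    """

    snr_positive_threshold: float = 3.0
    major_fraction: float = 0.5
    isac_positive_threshold: float = 0.3
    fdr_method: str = "benjamini-hochberg"
    fdr_scope: str = "per-protein"
    proportion_decimals: int = 1
    pvalue_decimals: int = 2
    pvalue_floor_display: float = 0.001
    pvalue_ceiling_display: float = 0.99
    significance_level: float = 0.05

    def __post_init__(self) -> None:
        if self.snr_positive_threshold <= 0 or self.isac_positive_threshold <= 0:
            raise CallingError("thresholds must be positive")
        if not 0 < self.major_fraction <= 1:
            raise CallingError("major_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PeptidePrevalence:
    """Positive-call count for one peptide in one regional cohort."""

    protein: str
    peptide_index: int
    region_label: str
    n_positive: int
    n_total: int
    percent: float

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_total


@dataclass(frozen=True)
class EpitopeRegion:
    """Merged residue intervals covered by a cohort's major peptides."""

    protein: str
    region_label: str
    ranges: tuple[tuple[int, int], ...]
    peptide_indices: tuple[int, ...] = ()

    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)


def call_positivity(matrix: BindingMatrix, config: AnalysisConfig | None = None) -> dict[str, pd.DataFrame]:
    """Threshold median SNRs into per-subject positivity calls.

    Returns one DataFrame per protein with values 1.0 (positive), 0.0
    (negative) or NaN (no measurement).
    """
    config = config or AnalysisConfig()
    calls = {}
    for protein, df in matrix.values.items():
        out = (df >= config.snr_positive_threshold).astype(float)
        out[df.isna()] = np.nan
        calls[protein] = out
    return calls


def summarize_prevalence(
    calls: dict[str, pd.DataFrame],
    regions: pd.Series,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per (protein, peptide, region) positive counts and percentages.

    ``n_total`` counts subjects with a non-missing call; the percentage is
    rounded to ``proportion_decimals`` for display while downstream major
    classification uses the exact counts.
    """
    config = config or AnalysisConfig()
    if regions.empty:
        raise CallingError("no subjects with region labels")
    rows = []
    for protein, df in calls.items():
        unlabeled = df.index.difference(regions.index)
        if len(unlabeled):
            raise CallingError(f"subjects without region label: {list(unlabeled)}")
        for region_label, subjects in regions.groupby(regions):
            sub = df.loc[df.index.intersection(subjects.index)]
            if sub.empty:
                raise CallingError(f"region {region_label!r} has no subjects")
            for peptide in df.columns:
                col = sub[peptide]
                n_total = int(col.notna().sum())
                n_positive = int(col.sum(skipna=True)) if n_total else 0
                percent = (
                    round(100.0 * n_positive / n_total, config.proportion_decimals)
                    if n_total else float("nan")
                )
                rows.append(
                    {"protein": protein, "peptide_index": int(peptide),
                     "region": region_label, "n_positive": n_positive,
                     "n_total": n_total, "percent": percent}
                )
    return pd.DataFrame(rows).sort_values(
        ["protein", "region", "peptide_index"]).reset_index(drop=True)


def prevalence_from_counts(
    counts: dict[str, Sequence[tuple[int, int]]],
    cohort_sizes: dict[str, int],
    region_order: Sequence[str] = ("USA", "Spain"),
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Build a prevalence table directly from per-peptide positive counts.

    ``counts`` maps protein -> list of per-peptide tuples, one entry per
    region in ``region_order``; ``cohort_sizes`` gives each region's
    denominator. This is the entry point for re-analyzing published count
    tables without spot-level data.
    """
    config = config or AnalysisConfig()
    rows = []
    for protein, pairs in counts.items():
        for idx, tup in enumerate(pairs, start=1):
            for region, n_pos in zip(region_order, tup):
                n_tot = cohort_sizes[region]
                rows.append(
                    {"protein": protein, "peptide_index": idx, "region": region,
                     "n_positive": int(n_pos), "n_total": n_tot,
                     "percent": round(100.0 * n_pos / n_tot, config.proportion_decimals)}
                )
    return pd.DataFrame(rows)


def classify_major(
    prevalence: pd.DataFrame | PeptidePrevalence,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame | bool:
    """Flag major IgE-reactive peptides (positive in >= half the cohort).

    Accepts a single :class:`PeptidePrevalence` (returns bool) or a
    prevalence DataFrame (returns a copy with a boolean ``major`` column).
    The comparison uses the exact fraction n_positive/n_total, inclusive
    at the boundary.
    """
    config = config or AnalysisConfig()
    if isinstance(prevalence, PeptidePrevalence):
        return prevalence.fraction >= config.major_fraction
    out = prevalence.copy()
    out["major"] = (out["n_positive"] / out["n_total"]) >= config.major_fraction
    return out


def merge_major_regions(
    tiles: Sequence[PeptideTile],
    protein: str | None = None,
    region_label: str = "",
) -> EpitopeRegion:
    """Union the residue intervals of major tiles into epitope regions.

    Overlapping and abutting intervals (end + 1 == next start) are merged,
    since per-residue coverage is contiguous across such tiles. An empty
    tile list yields an empty range list.
    """
    if tiles:
        names = {t.protein for t in tiles}
        if len(names) > 1:
            raise CallingError(f"tiles from multiple proteins: {sorted(names)}")
        protein = protein or names.pop()
    intervals = sorted((t.start, t.end) for t in tiles)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return EpitopeRegion(
        protein=protein or "",
        region_label=region_label,
        ranges=tuple((s, e) for s, e in merged),
        peptide_indices=tuple(sorted(t.index for t in tiles)),
    )


HEATMAP_BINS = ("snr_lt_3", "snr_3_to_10", "snr_gt_10")
STRUCTURE_BINS = ("none", "pink", "purple")


def bin_intensity(median_snr: float, scheme: str = "heatmap") -> str:
    """Categorize a median SNR for display.

    ``heatmap``: below 3 / 3 to 10 inclusive / above 10 (the three shades
    used in subject-level heat maps). ``structure``: none (< 3), ``pink``
    (3 <= SNR < 5) or ``purple`` (>= 5), the classes used to color epitope
    regions on structure models.
    """
    if scheme == "heatmap":
        if median_snr < 3:
            return HEATMAP_BINS[0]
        if median_snr <= 10:
            return HEATMAP_BINS[1]
        return HEATMAP_BINS[2]
    if scheme == "structure":
        if median_snr < 3:
            return STRUCTURE_BINS[0]
        if median_snr < 5:
            return STRUCTURE_BINS[1]
        return STRUCTURE_BINS[2]
    raise CallingError(f"unknown intensity scheme {scheme!r}")


def major_tiles(
    prevalence: pd.DataFrame,
    tiles: Sequence[PeptideTile],
    region_label: str,
    config: AnalysisConfig | None = None,
) -> list[PeptideTile]:
    """Select the tiles classified major for one protein and cohort."""
    config = config or AnalysisConfig()
    flagged = classify_major(prevalence, config)
    by_index = {t.index: t for t in tiles}
    proteins = {t.protein for t in tiles}
    if len(proteins) != 1:
        raise CallingError("major_tiles expects tiles from a single protein")
    wanted = flagged[
        (flagged["protein"] == proteins.pop())
        & (flagged["region"] == region_label)
        & flagged["major"]
    ]
    missing = set(wanted["peptide_index"]) - set(by_index)
    if missing:
        raise CallingError(f"prevalence refers to unknown tiles: {sorted(missing)}")
    return [by_index[i] for i in sorted(wanted["peptide_index"])]
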