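"""Ingestion of peptide-array spot measurements and intact-protein assays.

Spot-level fluorescence signal-to-noise ratios (SNR, as produced by the
scanner software) arrive either as a plain long-format table or as a
minimal GenePix-style tab-delimited file. Replicate spots (nominally
triplicate) are summarized by taking the median of the available
replicates, giving one subject x peptide matrix of median SNRs per
protein. Intact-protein IgE levels come from ISAC microarrays in ISU-E
units with a stated operating range of 0.3-100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISAC_OPERATING_RANGE = (0.3, 100.0)

PLAIN_COLUMNS = ["subject_id", "region", "protein", "peptide_index", "replicate", "snr"]


class SignalError(ValueError):
    """Raised for malformed measurement tables."""


@dataclass(frozen=True)
class SpotRecord:
    """A single microarray spot measurement for one subject."""

    subject_id: str
    region_label: str
    protein: str
    peptide_index: int
    replicate_ordinal: int
    snr: float
    fg_median: float | None = None
    bg_median: float | None = None
    bg_sd: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.snr):
            raise SignalError(f"non-finite SNR for {self.subject_id}/{self.protein}"
                              f"/{self.peptide_index}")
        if self.replicate_ordinal < 1:
            raise SignalError("replicate_ordinal must be >= 1")


@dataclass(frozen=True)
class IsacRecord:
    """One intact-allergen IgE measurement (ISU-E units).

    ``out_of_range`` flags values outside the assay's stated operating
    range; such records are retained, not dropped.
    """

    subject_id: str
    region_label: str
    allergen: str
    isu_e: float
    out_of_range: bool = False


@dataclass
class BindingMatrix:
    """Subject x peptide median-SNR matrices, one per protein.

    ``values`` maps protein name to a DataFrame indexed by subject_id with
    peptide indices as columns; missing cells are NaN. ``regions`` maps
    subject_id to its region label.
    """

    values: dict[str, pd.DataFrame]
    regions: pd.Series

    def region_sizes(self) -> dict[str, int]:
        return self.regions.value_counts().to_dict()


def compute_snr(fg_median: float, bg_median: float, bg_sd: float) -> float:
    """Spot signal-to-noise ratio, (foreground - background) / background SD.

    Fallback for GenePix-style files that carry only foreground/background
    statistics; may be negative when the spot is dimmer than background.
    """
    if bg_sd <= 0:
        raise SignalError(f"background SD must be positive, got {bg_sd}")
    return (fg_median - bg_median) / bg_sd


def _check_duplicates(records: Sequence[SpotRecord]) -> None:
    seen: set[tuple] = set()
    for r in records:
        key = (r.subject_id, r.protein, r.peptide_index, r.replicate_ordinal)
        if key in seen:
            raise SignalError(f"duplicate spot record for {key}")
        seen.add(key)


def read_spot_table(source: str | Path, dialect: str = "plain", **kwargs) -> list[SpotRecord]:
    """Read spot-level measurements.

    ``dialect="plain"``: TSV/CSV with columns subject_id, region, protein,
    peptide_index, replicate, snr and optionally fg_median, bg_median,
    bg_sd. When an snr column is present it takes precedence over
    recomputation from foreground/background statistics.

    ``dialect="genepix"``: minimal GenePix-style tab-delimited records; see
    :func:`read_genepix_table` for the conventions and extra arguments.
    """
    if dialect == "plain":
        return _read_plain(source)
    if dialect == "genepix":
        return read_genepix_table(source, **kwargs)
    raise SignalError(f"unknown spot-table dialect {dialect!r}")


def _read_plain(source: str | Path) -> list[SpotRecord]:
    sep = "," if str(source).endswith(".csv") else "\t"
    df = pd.read_csv(source, sep=sep)
    missing = set(PLAIN_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise SignalError(f"spot table missing required columns: {sorted(missing)}")
    has_snr = "snr" in df.columns
    has_stats = {"fg_median", "bg_median", "bg_sd"} <= set(df.columns)
    if not has_snr and not has_stats:
        raise SignalError("spot table needs either an 'snr' column or "
                          "fg_median/bg_median/bg_sd statistics")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if has_snr and not pd.isna(d.get("snr")):
            snr = float(d["snr"])
        else:
            snr = compute_snr(float(d["fg_median"]), float(d["bg_median"]),
                              float(d["bg_sd"]))
        records.append(
            SpotRecord(
                subject_id=str(d["subject_id"]),
                region_label=str(d["region"]),
                protein=str(d["protein"]),
                peptide_index=int(d["peptide_index"]),
                replicate_ordinal=int(d["replicate"]),
                snr=snr,
                fg_median=float(d["fg_median"]) if has_stats else None,
                bg_median=float(d["bg_median"]) if has_stats else None,
                bg_sd=float(d["bg_sd"]) if has_stats else None,
            )
        )
    _check_duplicates(records)
    return records


def read_genepix_table(
    source: str | Path,
    subject_id: str,
    region_label: str,
) -> list[SpotRecord]:
    """Read a minimal GenePix-style results table for one subject's slide.

    Expected tab-delimited named columns: Block, Row, Column, Name, ID and
    either an SNR column ("SNR 532") or the statistics "F532 Median",
    "B532 Median", "B532 SD". Name encodes the spotted peptide as
    ``<protein>_<peptide_index>``; the replicate ordinal is the order of
    appearance of each Name. Rows whose "Flags" value is negative (spots
    flagged bad during scanning) are dropped with a logged count.
    """
    df = pd.read_csv(source, sep="\t")
    for col in ("Block", "Row", "Column", "Name", "ID"):
        if col not in df.columns:
            raise SignalError(f"genepix table missing required column: {col}")
    if "Flags" in df.columns:
        bad = df["Flags"] < 0
        if bad.any():
            logger.info("dropping %d flagged spots from %s", int(bad.sum()), source)
        df = df[~bad]
    has_snr = "SNR 532" in df.columns
    has_stats = {"F532 Median", "B532 Median", "B532 SD"} <= set(df.columns)
    if not has_snr and not has_stats:
        raise SignalError("genepix table needs 'SNR 532' or F532/B532 statistics")
    records = []
    replicate_counter: dict[str, int] = {}
    for d in df.to_dict("records"):
        name = str(d["Name"])
        if "_" not in name:
            raise SignalError(f"cannot parse peptide name {name!r}; expected "
                              "'<protein>_<peptide_index>'")
        protein, _, idx = name.rpartition("_")
        replicate_counter[name] = replicate_counter.get(name, 0) + 1
        if has_snr:
            snr = float(d["SNR 532"])
        else:
            snr = compute_snr(float(d["F532 Median"]), float(d["B532 Median"]),
                              float(d["B532 SD"]))
        records.append(
            SpotRecord(
                subject_id=subject_id,
                region_label=region_label,
                protein=protein,
                peptide_index=int(idx),
                replicate_ordinal=replicate_counter[name],
                snr=snr,
            )
        )
    _check_duplicates(records)
    return records


def aggregate_replicates(records: Sequence[SpotRecord]) -> BindingMatrix:
    """Collapse replicate spots to the median SNR per (subject, peptide).

    The median is taken over however many replicates survive (1-3 under
    the triplicate design, but any count is accepted); subject/peptide
    pairs with no surviving spots are left missing.
    """
    if not records:
        raise SignalError("no spot records to aggregate")
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "region": [r.region_label for r in records],
            "protein": [r.protein for r in records],
            "peptide_index": [r.peptide_index for r in records],
            "snr": [r.snr for r in records],
        }
    )
    regions = df.groupby("subject_id")["region"].first()
    conflicting = df.groupby("subject_id")["region"].nunique()
    if (conflicting > 1).any():
        bad = conflicting[conflicting > 1].index.tolist()
        raise SignalError(f"subjects with conflicting region labels: {bad}")
    values = {}
    for protein, sub in df.groupby("protein"):
        med = sub.groupby(["subject_id", "peptide_index"])["snr"].median().unstack()
        # keep every subject in the cohort, even if this protein was not probed
        med = med.reindex(regions.index)
        med.columns = med.columns.astype(int)
        values[str(protein)] = med.sort_index(axis=1)
    return BindingMatrix(values=values, regions=regions)


def frame_from_records(records: Sequence[SpotRecord]) -> pd.DataFrame:
    """Long-format spot DataFrame (plain-dialect column layout)."""
    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "region": r.region_label,
             "protein": r.protein, "peptide_index": r.peptide_index,
             "replicate": r.replicate_ordinal, "snr": r.snr}
            for r in records
        ]
    )


def write_spot_table(records: Sequence[SpotRecord], path: str | Path) -> None:
    frame_from_records(records).to_csv(path, sep="\t", index=False)


def read_isac_table(source: str | Path) -> list[IsacRecord]:
    """Read intact-protein ISAC measurements.

    Required columns: subject_id, region, allergen, isu_e. Negative ISU-E
    values are rejected; values outside the 0.3-100 operating range are
    flagged but retained.
    """
    df = pd.read_csv(source, sep="\t")
    missing = {"subject_id", "region", "allergen", "isu_e"} - set(df.columns)
    if missing:
        raise SignalError(f"ISAC table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        isu = float(row.isu_e)
        if isu < 0:
            raise SignalError(f"negative ISU-E value {isu} for subject {row.subject_id}")
        lo, hi = ISAC_OPERATING_RANGE
        records.append(
            IsacRecord(
                subject_id=str(row.subject_id),
                region_label=str(row.region),
                allergen=str(row.allergen),
                isu_e=isu,
                out_of_range=not (lo <= isu <= hi),
            )
        )
    return records


def write_isac_table(records: Iterable[IsacRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "region": r.region_label,
             "allergen": r.allergen, "isu_e": r.isu_e}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
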