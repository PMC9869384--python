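"""Secondary-structure segment annotation of epitope regions.

nsLTPs fold into four alpha-helices joined by short loops and a long
C-terminal coil. Segment boundaries are supplied as configuration (for
example derived externally from a crystal-structure template); the
package only intersects epitope intervals with those segments — it does
no modeling. Residues not covered by any supplied segment fall into the
implicit "other" segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calling import AnalysisConfig, EpitopeRegion, bin_intensity
from .tiling import PeptideTile

SEGMENT_LABELS = (
    "helix1", "helix2", "helix3", "helix4",
    "loop12", "loop23", "loop34", "cterm_coil", "other",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentAnnotation:
    """Non-overlapping labelled residue segments of one protein."""

    protein: str
    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        occupied: list[tuple[int, int]] = []
        for label, start, end in self.segments:
            if label not in SEGMENT_LABELS:
                raise AnnotationError(f"unknown segment label {label!r}")
            if start < 1 or end < start:
                raise AnnotationError(f"bad segment interval {start}-{end}")
            for s, e in occupied:
                if start <= e and s <= end:
                    raise AnnotationError(
                        f"segment {label} {start}-{end} overlaps another segment")
            occupied.append((start, end))


def read_annotation_tsv(path: str | Path) -> dict[str, SegmentAnnotation]:
    """Read per-protein segment annotations (protein, segment_label, start, end)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein", "segment_label", "start", "end"} - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
    out = {}
    for protein, sub in df.groupby("protein"):
        out[str(protein)] = SegmentAnnotation(
            protein=str(protein),
            segments=tuple(
                (str(r.segment_label), int(r.start), int(r.end))
                for r in sub.itertuples(index=False)
            ),
        )
    return out


def assign_segments(
    region: EpitopeRegion,
    annotation: SegmentAnnotation,
    protein_length: int | None = None,
) -> pd.DataFrame:
    """Overlap of each epitope interval with the annotated segments.

    Returns one row per (interval, segment) with the shared residue count
    and the fraction of the segment covered; residues outside every
    annotated segment are attributed to "other" (coverage fraction NaN).
    Segments with zero overlap are omitted. Residue conservation holds:
    per interval, the overlap lengths (including "other") sum to the
    interval length.
    """
    if protein_length is not None:
        for s, e in region.ranges:
            if e > protein_length or s < 1:
                raise AnnotationError(
                    f"region {s}-{e} outside protein of length {protein_length}")
    rows = []
    for start, end in region.ranges:
        assigned = 0
        for label, seg_start, seg_end in annotation.segments:
            ov = min(end, seg_end) - max(start, seg_start) + 1
            if ov > 0:
                assigned += ov
                rows.append(
                    {"protein": region.protein, "cohort": region.region_label,
                     "range_start": start, "range_end": end, "segment": label,
                     "overlap_length": ov,
                     "segment_coverage": round(ov / (seg_end - seg_start + 1), 3)}
                )
        leftover = (end - start + 1) - assigned
        if leftover > 0:
            rows.append(
                {"protein": region.protein, "cohort": region.region_label,
                 "range_start": start, "range_end": end, "segment": "other",
                 "overlap_length": leftover, "segment_coverage": float("nan")}
            )
    return pd.DataFrame(
        rows, columns=["protein", "cohort", "range_start", "range_end",
                       "segment", "overlap_length", "segment_coverage"]
    )


def segment_report(
    regions: Sequence[EpitopeRegion],
    annotation: SegmentAnnotation,
    tiles: Sequence[PeptideTile],
    median_snr_by_peptide: dict[int, float],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Combine segment overlaps with structure-display color classes.

    For every cohort and annotated segment overlapped by an epitope
    interval, lists the tiles covering the segment together with the
    color class of their cohort-median SNR ("pink" for 3 <= SNR < 5,
    "purple" for >= 5, "none" below positivity).
    """
    del config  # formatting conventions currently fixed
    by_index = {t.index: t for t in tiles}
    rows = []
    for region in regions:
        overlaps = assign_segments(region, annotation)
        for rec in overlaps.itertuples(index=False):
            seg_tiles = [
                by_index[i]
                for i in region.peptide_indices
                if by_index[i].start <= rec.range_end and by_index[i].end >= rec.range_start
            ]
            for t in seg_tiles:
                snr = median_snr_by_peptide.get(t.index)
                rows.append(
                    {"protein": region.protein, "cohort": region.region_label,
                     "segment": rec.segment, "peptide_index": t.index,
                     "median_snr": snr,
                     "color_class": bin_intensity(snr, "structure")
                     if snr is not None else "none"}
                )
    return pd.DataFrame(
        rows, columns=["protein", "cohort", "segment", "peptide_index",
                       "median_snr", "color_class"]
    ).drop_duplicates().reset_index(drop=True)
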