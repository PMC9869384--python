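"""End-to-end orchestration: from raw tables to report bundle.

``run_pipeline`` composes the stages deterministically — tiling and
validation, replicate aggregation, positivity calling, prevalence, major
peptides, epitope regions, regional Fisher/FDR comparison, intact-protein
comparison, cross-homolog conservation, and optional structure-segment
annotation — and returns everything as one :class:`ReportBundle` with a
provenance block (config snapshot, package version, input digests).
``render_report`` writes the bundle as TSV tables plus a short plain-text
summary, using the display conventions of the published tables (one-
decimal percentages; two-decimal adjusted p-values with "<0.001" and
">0.99" floors/ceilings).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .calling import (
    AnalysisConfig,
    EpitopeRegion,
    call_positivity,
    classify_major,
    major_tiles,
    merge_major_regions,
    summarize_prevalence,
)
from .signal import aggregate_replicates, read_isac_table, read_spot_table
from .similarity import global_align, identity_similarity_matrix, project_epitopes
from .stats import compare_isac, compare_regions
from .structure import read_annotation_tsv, segment_report
from .tiling import (
    ProteinRecord,
    read_fasta,
    read_tiles_tsv,
    tile_protein,
    validate_tiling,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """File inputs and analysis settings for a full run."""

    proteins_fasta: str | Path
    spots: str | Path
    tiles_tsv: str | Path | None = None
    isac: str | Path | None = None
    segments_tsv: str | Path | None = None
    tile_length: int = 15
    tile_offset: int = 5
    region_order: tuple[str, str] = ("USA", "Spain")
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    spot_dialect: str = "plain"


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus provenance."""

    tiles: pd.DataFrame
    prevalence: pd.DataFrame
    majors: pd.DataFrame
    regions: list[EpitopeRegion]
    comparison: pd.DataFrame
    isac_comparison: pd.DataFrame | None
    conservation: pd.DataFrame
    identity_matrix: pd.DataFrame
    segment_reports: pd.DataFrame | None
    provenance: dict


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _regions_frame(regions: Sequence[EpitopeRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein": r.protein, "cohort": r.region_label,
             "ranges": "; ".join(f"{s}-{e}" for s, e in r.ranges),
             "peptides": ",".join(map(str, r.peptide_indices)),
             "covered_residues": r.total_length()}
            for r in regions
        ]
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage; any stage error propagates with its stage name."""
    analysis = config.analysis

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(name, str(exc)) from exc

    for name, path in [("tiling", config.proteins_fasta), ("aggregate", config.spots)]:
        if not Path(path).exists():
            raise PipelineError(name, f"input file not found: {path}")

    proteins = stage("tiling", read_fasta, config.proteins_fasta)
    by_name: dict[str, ProteinRecord] = {p.allergen_name: p for p in proteins}

    if config.tiles_tsv is not None:
        all_tiles = stage("tiling", read_tiles_tsv, config.tiles_tsv)
        tiles_by_protein = {
            name: [t for t in all_tiles if t.protein == name] for name in by_name
        }
    else:
        tiles_by_protein = {
            name: stage("tiling", tile_protein, rec, config.tile_length,
                        config.tile_offset)
            for name, rec in by_name.items()
        }
    for name, tiles in tiles_by_protein.items():
        report = validate_tiling(tiles, by_name[name], offset=config.tile_offset)
        if not report.ok:
            raise PipelineError(
                "tiling",
                f"{name}: invalid tiling "
                f"(gaps={report.coverage_gaps}, mismatches={report.sequence_mismatches}, "
                f"off_grid={report.off_grid_starts})",
            )

    spots = stage("aggregate", read_spot_table, config.spots, config.spot_dialect)
    matrix = stage("aggregate", aggregate_replicates, spots)

    calls = stage("call", call_positivity, matrix, analysis)
    prevalence = stage("call", summarize_prevalence, calls, matrix.regions, analysis)
    majors = stage("call", classify_major, prevalence, analysis)

    regions: list[EpitopeRegion] = []
    for protein, tiles in tiles_by_protein.items():
        if protein not in calls:
            continue
        for cohort in config.region_order:
            selected = stage("call", major_tiles, prevalence, tiles, cohort, analysis)
            region = merge_major_regions(selected, protein=protein, region_label=cohort)
            regions.append(region)

    comparison = stage("compare", compare_regions, prevalence, analysis,
                       config.region_order)

    isac_comparison = None
    if config.isac is not None:
        isac_records = stage("isac", read_isac_table, config.isac)
        isac_comparison = stage("isac", compare_isac, isac_records, analysis,
                                config.region_order)

    conservation_rows = []
    protein_names = list(by_name)
    for src in protein_names:
        src_regions = [r for r in regions if r.protein == src]
        for dst in protein_names:
            if dst == src:
                continue
            aln = stage("conserve", global_align,
                        by_name[src].mature_sequence, by_name[dst].mature_sequence)
            for region in src_regions:
                links = stage("conserve", project_epitopes, aln, region, dst,
                              tiles_by_protein.get(dst, ()))
                for link in links:
                    conservation_rows.append(
                        {"source_protein": src, "cohort": region.region_label,
                         "source_range": f"{link.source_range[0]}-{link.source_range[1]}",
                         "target_protein": dst,
                         "target_range": (
                             f"{link.target_range[0]}-{link.target_range[1]}"
                             if link.target_range else ""),
                         "target_tiles": ",".join(map(str, link.target_tile_indices))}
                    )
    conservation = pd.DataFrame(
        conservation_rows,
        columns=["source_protein", "cohort", "source_range", "target_protein",
                 "target_range", "target_tiles"],
    )

    identity = stage("conserve", identity_similarity_matrix, proteins)

    seg_reports = None
    if config.segments_tsv is not None:
        annotations = stage("structure", read_annotation_tsv, config.segments_tsv)
        frames = []
        for protein, annotation in annotations.items():
            if protein not in calls:
                continue
            med = matrix.values[protein]
            for cohort in config.region_order:
                cohort_subjects = matrix.regions[matrix.regions == cohort].index
                cohort_median = med.loc[med.index.intersection(cohort_subjects)].median()
                snr_by_pep = {int(k): float(v) for k, v in cohort_median.items()}
                cohort_regions = [
                    r for r in regions
                    if r.protein == protein and r.region_label == cohort
                ]
                frames.append(
                    stage("structure", segment_report, cohort_regions, annotation,
                          tiles_by_protein[protein], snr_by_pep, analysis)
                )
        seg_reports = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )

    tiles_frame = pd.DataFrame(
        [
            {"protein": t.protein, "index": t.index, "start": t.start,
             "end": t.end, "sequence": t.sequence}
            for tiles in tiles_by_protein.values()
            for t in tiles
        ]
    )

    provenance = {
        "package_version": __version__,
        "analysis_config": analysis.__dict__.copy(),
        "region_order": list(config.region_order),
        "inputs": {
            "proteins_fasta": {"path": str(config.proteins_fasta),
                               "sha256_16": _digest(config.proteins_fasta)},
            "spots": {"path": str(config.spots), "sha256_16": _digest(config.spots)},
            **({"isac": {"path": str(config.isac), "sha256_16": _digest(config.isac)}}
               if config.isac else {}),
        },
    }
    return ReportBundle(
        tiles=tiles_frame, prevalence=prevalence, majors=majors, regions=regions,
        comparison=comparison, isac_comparison=isac_comparison,
        conservation=conservation, identity_matrix=identity,
        segment_reports=seg_reports, provenance=provenance,
    )


def format_percent(n_positive: int, n_total: int, decimals: int = 1) -> str:
    """Percent display matching the published tables ("96.4%", "60%", "100%")."""
    pct = round(100.0 * n_positive / n_total, decimals)
    if pct == int(pct):
        return f"{int(pct)}%"
    return f"{pct:.{decimals}f}%"


def render_report(bundle: ReportBundle, destination: str | Path) -> dict[str, Path]:
    """Write one TSV per table plus a plain-text summary; returns the paths."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, **kwargs):
        path = dest / f"{name}.tsv"
        df.to_csv(path, sep="\t", **kwargs)
        paths[name] = path

    write("tiles", bundle.tiles, index=False)
    write("prevalence", bundle.prevalence, index=False)
    write("majors", bundle.majors, index=False)
    write("epitope_regions", _regions_frame(bundle.regions), index=False)

    comparison = bundle.comparison.copy()
    region_cols = [c for c in comparison.columns if c.endswith("_positive")]
    for col in region_cols:
        total_col = col.replace("_positive", "_total")
        comparison[col.replace("_positive", "_display")] = [
            f"{a} ({format_percent(a, b)})"
            for a, b in zip(comparison[col], comparison[total_col])
        ]
    write("comparison", comparison, index=False)

    if bundle.isac_comparison is not None:
        write("isac_comparison", bundle.isac_comparison, index=False)
    write("conservation", bundle.conservation, index=False)
    write("identity_similarity", bundle.identity_matrix, index=True)
    if bundle.segment_reports is not None:
        write("segment_report", bundle.segment_reports, index=False)

    summary = dest / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("ltpmap report\n=============\n\n")
        fh.write(f"package version: {bundle.provenance['package_version']}\n")
        for key, info in bundle.provenance["inputs"].items():
            fh.write(f"input {key}: {info['path']} (sha256/16 {info['sha256_16']})\n")
        fh.write("\nepitope regions (major-tile unions):\n")
        for r in bundle.regions:
            ranges = ", ".join(f"{s}-{e}" for s, e in r.ranges) or "(none)"
            fh.write(f"  {r.protein} [{r.region_label}]: {ranges}\n")
        sig = bundle.comparison[bundle.comparison["significant"]]
        fh.write("\nsignificant regional differences (adjusted p < 0.05):\n")
        for rec in sig.itertuples(index=False):
            fh.write(f"  {rec.protein} peptide {rec.peptide_index}: "
                     f"adjusted p {rec.display}\n")
    paths["summary"] = summary
    return paths
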