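"""Protein records and overlapping peptide tilings.

The array design probes linear IgE epitopes with synthetic 15-mer peptides
that start every 5 residues of the mature protein, so consecutive tiles
overlap by 10 residues and the final tile may be truncated. Coordinates
are 1-based and inclusive on the mature sequence; the number of residues
removed as signal peptide is carried separately so precursor numbering
stays recoverable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Tiles shorter than this raise a warning from :func:`tile_protein`.
MIN_TILE_LENGTH = 8


class TilingError(ValueError):
    """Raised for inconsistent or invalid tilings."""


@dataclass(frozen=True)
class ProteinRecord:
    """A mature allergen sequence as present on the array.

    Parameters
    ----------
    allergen_name : str
        WHO/IUIS allergen name, e.g. ``"Ara h 9"``.
    isoform_label : str
        Isoform identifier, e.g. ``"Ara h 9.0201"``.
    mature_sequence : str
        One-letter amino-acid sequence of the mature protein (signal
        peptide removed). ``X`` is accepted only when ``allow_x`` is set.
    precursor_offset : int
        Number of N-terminal residues of the published precursor that are
        absent from the mature sequence (0 if none).
    allow_x : bool
        Permit ``X`` (unknown residue) in the sequence. Reference and
        fixture sequences may carry it; array proteins normally must not.
    """

    allergen_name: str
    isoform_label: str
    mature_sequence: str
    precursor_offset: int = 0
    allow_x: bool = False

    def __post_init__(self) -> None:
        if not self.mature_sequence:
            raise TilingError(f"{self.allergen_name}: empty mature sequence")
        if self.precursor_offset < 0:
            raise TilingError("precursor_offset must be >= 0")
        alphabet = STANDARD_AA | ({"X"} if self.allow_x else set())
        for pos, ch in enumerate(self.mature_sequence, start=1):
            if ch not in alphabet:
                raise TilingError(
                    f"{self.allergen_name}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.mature_sequence)


@dataclass(frozen=True)
class PeptideTile:
    """One synthesized peptide: a window of the mature protein.

    ``start``/``end`` are 1-based inclusive residue coordinates;
    ``index`` is the 1-based ordinal of the tile on its protein.
    """

    protein: str
    index: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise TilingError(
                f"tile {self.protein}#{self.index}: coordinates {self.start}-{self.end} "
                f"do not match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def tile_protein(
    protein: ProteinRecord,
    tile_length: int = 15,
    offset: int = 5,
    min_tile_length: int = MIN_TILE_LENGTH,
) -> list[PeptideTile]:
    """Generate the overlapping peptide tiling of a mature protein.

    Tiles start at residues 1, 1+offset, 1+2*offset, ... and each covers
    ``tile_length`` residues, truncated at the protein's C-terminus. For a
    sequence of length ``L > tile_length`` this yields
    ``ceil((L - tile_length)/offset) + 1`` tiles whose union covers every
    residue; a sequence no longer than one tile yields a single tile.

    A final tile shorter than ``min_tile_length`` triggers a warning (such
    peptides may be hard to synthesize or interpret) but is still returned.
    """
    if tile_length <= 0 or offset <= 0:
        raise TilingError("tile_length and offset must be positive")
    if tile_length <= offset:
        raise TilingError("tile_length must exceed offset for overlapping tiles")
    seq = protein.mature_sequence
    L = len(seq)
    if L <= tile_length:
        n_tiles = 1
    else:
        n_tiles = math.ceil((L - tile_length) / offset) + 1
    tiles = []
    for k in range(n_tiles):
        start = 1 + k * offset
        end = min(start + tile_length - 1, L)
        tiles.append(
            PeptideTile(
                protein=protein.allergen_name,
                index=k + 1,
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
            )
        )
    last = tiles[-1]
    if len(last) < min_tile_length:
        warnings.warn(
            f"{protein.allergen_name}: final tile #{last.index} is only "
            f"{len(last)} aa long",
            stacklevel=2,
        )
    return tiles


def reconstruct_sequence(tiles: Sequence[PeptideTile]) -> str:
    """Rebuild the unique mature sequence consistent with overlapping tiles.

    Tiles must be sorted by start coordinate, cover the sequence without
    gaps, and agree on every shared coordinate; the first conflicting or
    uncovered position is reported otherwise.
    """
    if not tiles:
        raise TilingError("no tiles to reconstruct from")
    length = max(t.end for t in tiles)
    residues: list[str | None] = [None] * length
    for t in tiles:
        for pos, ch in zip(range(t.start, t.end + 1), t.sequence):
            prev = residues[pos - 1]
            if prev is None:
                residues[pos - 1] = ch
            elif prev != ch:
                raise TilingError(
                    f"overlap conflict at residue {pos}: {prev!r} vs {ch!r} "
                    f"(tile {t.protein}#{t.index})"
                )
    for pos, ch in enumerate(residues, start=1):
        if ch is None:
            raise TilingError(f"coverage gap at residue {pos}")
    return "".join(residues)  # type: ignore[arg-type]


@dataclass
class TilingReport:
    """Diagnostics from :func:`validate_tiling`. ``ok`` when nothing was flagged."""

    protein: str
    n_tiles: int
    coverage_gaps: list[tuple[int, int]] = field(default_factory=list)
    sequence_mismatches: list[str] = field(default_factory=list)
    off_grid_starts: list[int] = field(default_factory=list)
    length_profile: dict[int, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (self.coverage_gaps or self.sequence_mismatches or self.off_grid_starts)


def validate_tiling(
    tiles: Sequence[PeptideTile],
    protein: ProteinRecord,
    offset: int = 5,
) -> TilingReport:
    """Check a tiling against its protein: sequence agreement, coverage, grid.

    Purely diagnostic; never raises for a bad tiling.
    """
    seq = protein.mature_sequence
    report = TilingReport(protein=protein.allergen_name, n_tiles=len(tiles))
    covered = [False] * len(seq)
    for t in sorted(tiles, key=lambda t: t.start):
        report.length_profile[len(t)] = report.length_profile.get(len(t), 0) + 1
        if (t.start - 1) % offset != 0:
            report.off_grid_starts.append(t.start)
        if t.end > len(seq) or seq[t.start - 1 : t.end] != t.sequence:
            report.sequence_mismatches.append(
                f"tile #{t.index} ({t.start}-{t.end}) does not match protein sequence"
            )
        for pos in range(t.start, min(t.end, len(seq)) + 1):
            covered[pos - 1] = True
    gap_start = None
    for pos, cov in enumerate(covered, start=1):
        if not cov and gap_start is None:
            gap_start = pos
        elif cov and gap_start is not None:
            report.coverage_gaps.append((gap_start, pos - 1))
            gap_start = None
    if gap_start is not None:
        report.coverage_gaps.append((gap_start, len(seq)))
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, allow_x: bool = False) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Header convention: ``>allergen|isoform|precursor_offset=N``; missing
    fields default to the allergen name and offset 0.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        name = parts[0].strip()
        isoform = parts[1].strip() if len(parts) > 1 else name
        offset = 0
        for p in parts[2:]:
            if p.strip().startswith("precursor_offset="):
                offset = int(p.strip().split("=", 1)[1])
        records.append(
            ProteinRecord(
                allergen_name=name,
                isoform_label=isoform,
                mature_sequence=str(rec.seq).upper(),
                precursor_offset=offset,
                allow_x=allow_x,
            )
        )
    if not records:
        raise TilingError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.mature_sequence),
            id=f"{r.allergen_name}|{r.isoform_label}|precursor_offset={r.precursor_offset}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def tiles_to_frame(tiles: Sequence[PeptideTile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein": t.protein, "index": t.index, "start": t.start,
             "end": t.end, "sequence": t.sequence}
            for t in tiles
        ]
    )


def write_tiles_tsv(tiles: Sequence[PeptideTile], path: str | Path) -> None:
    tiles_to_frame(tiles).to_csv(path, sep="\t", index=False)


def read_tiles_tsv(path: str | Path) -> list[PeptideTile]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "index", "start", "end", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise TilingError(f"tiles table missing columns: {sorted(missing)}")
    return [
        PeptideTile(
            protein=row.protein, index=int(row.index_), start=int(row.start),
            end=int(row.end), sequence=row.sequence,
        )
        for row in df.rename(columns={"index": "index_"}).itertuples(index=False)
    ]
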