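"""Ortholog selection and motif conservation scoring in alignments.

Functional SLiMs show island-like conservation: the motif persists across
orthologs even while the surrounding disordered sequence drifts.  Because
alignments of disordered regions are unreliable, conservation is scored
with a positional tolerance: an ortholog counts as conserved when the motif
regular expression matches its (ungapped) sequence and the match maps to an
alignment column within +/-50 columns of the human motif's column.

Ortholog choice follows the usual reciprocal-quality rules of a BLAST
screen: per species, the best-identity subject above 20% identity that
covers at least 60% of the human query.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO

from .motifs import MotifDefinition, scan_sequence


@dataclass(frozen=True)
class OrthologHitRecord:
    query_id: str
    subject_id: str
    species: str
    percent_identity: float
    coverage_fraction: float
    bitscore: float


def read_ortholog_hits(
    path: str | Path, query_length: int
) -> list[OrthologHitRecord]:
    """Read a tabular homology hit table (BLAST outfmt-6-like with headers).

    Expected columns: query, subject, species, pident, qstart, qend,
    bitscore.  Coverage is (aligned query span) / ``query_length``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for r in df.itertuples():
        span = int(r.qend) - int(r.qstart) + 1
        records.append(
            OrthologHitRecord(
                query_id=str(r.query),
                subject_id=str(r.subject),
                species=str(r.species),
                percent_identity=float(r.pident),
                coverage_fraction=span / query_length,
                bitscore=float(r.bitscore),
            )
        )
    return records


def select_orthologs(
    records: Sequence[OrthologHitRecord],
    min_identity: float = 20.0,
    min_coverage: float = 0.6,
) -> dict[str, str]:
    """Pick one subject per species: identity strictly above ``min_identity``
    and coverage at least ``min_coverage``; the highest-identity record wins,
    ties broken by higher bitscore, then lexicographically smallest subject id.
    """
    queries = {r.query_id for r in records}
    if len(queries) > 1:
        raise ValueError(f"records span multiple queries: {sorted(queries)}")
    best: dict[str, OrthologHitRecord] = {}
    for r in records:
        if not (r.percent_identity > min_identity and r.coverage_fraction >= min_coverage):
            continue
        cur = best.get(r.species)
        if cur is None or _beats(r, cur):
            best[r.species] = r
    return {sp: r.subject_id for sp, r in best.items()}


def _beats(a: OrthologHitRecord, b: OrthologHitRecord) -> bool:
    """Preference order: identity desc, bitscore desc, subject id asc."""
    if a.percent_identity != b.percent_identity:
        return a.percent_identity > b.percent_identity
    if a.bitscore != b.bitscore:
        return a.bitscore > b.bitscore
    return a.subject_id < b.subject_id


@dataclass
class AlignmentBlock:
    """A multiple sequence alignment with a designated human reference row.

    ``rows`` are (row_id, species, gapped sequence) triples of equal gapped
    length; ungapping the reference row must reproduce the human sequence.
    """

    rows: list[tuple[str, str, str]]
    reference_row: str

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"gapped rows have unequal lengths: {sorted(lengths)}")
        if self.reference_row not in {rid for rid, _, _ in self.rows}:
            raise ValueError(f"reference row {self.reference_row!r} absent")

    def row(self, row_id: str) -> str:
        for rid, _, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")


def read_alignment(
    path: str | Path, reference_row: str, fmt: str = "fasta"
) -> AlignmentBlock:
    """Read an aligned FASTA (``fmt='fasta'``) or Clustal (``fmt='clustal'``)
    file; row ids double as species labels."""
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, rec.id, str(rec.seq).upper()) for rec in aln]
    return AlignmentBlock(rows=rows, reference_row=reference_row)


def map_position_to_column(
    block: AlignmentBlock, row_id: str, ungapped_position: int
) -> int:
    """Alignment column (1-based) holding the row's ``ungapped_position``-th residue."""
    seq = block.row(row_id)
    count = 0
    for col, ch in enumerate(seq, start=1):
        if ch != "-":
            count += 1
            if count == ungapped_position:
                return col
    raise ValueError(
        f"position {ungapped_position} beyond ungapped length {count} "
        f"of row {row_id!r}"
    )


def map_column_to_position(block: AlignmentBlock, row_id: str, column: int) -> int | None:
    """Ungapped residue position at an alignment column (None on a gap)."""
    seq = block.row(row_id)
    if not 1 <= column <= len(seq):
        raise ValueError(f"column {column} outside alignment of width {len(seq)}")
    if seq[column - 1] == "-":
        return None
    return sum(1 for ch in seq[:column] if ch != "-")


@dataclass
class ConservationResult:
    core_start: int
    reference_column: int
    per_row: dict[str, tuple[bool, int | None]]
    conserved_fraction: float


def conservation_score(
    block: AlignmentBlock,
    definition: MotifDefinition,
    human_core_start: int,
    window: int = 50,
    space: str = "columns",
) -> ConservationResult:
    """Score motif conservation across the rows of an alignment block.

    The human row must contain a motif hit whose core starts at
    ``human_core_start`` (ungapped).  Each other row's ungapped sequence is
    scanned with ``definition``; the row is conserved iff some hit's
    core-start lies within ``+/-window`` of the reference position.  With
    ``space='columns'`` (default) the distance is measured between
    alignment columns, which absorbs indels; ``space='residues'`` measures
    it between ungapped ortholog positions after projecting the reference
    column onto the ortholog row.
    """
    if space not in ("columns", "residues"):
        raise ValueError(f"space must be 'columns' or 'residues', got {space!r}")
    ref = block.reference_row
    human_seq = block.ungapped(ref)
    ref_hits = {h.core_start for h in scan_sequence(human_seq, definition)}
    if human_core_start not in ref_hits:
        raise ValueError(
            f"reference row has no {definition.name!r} hit with core start "
            f"{human_core_start}"
        )
    ref_column = map_position_to_column(block, ref, human_core_start)

    per_row: dict[str, tuple[bool, int | None]] = {}
    n_conserved = 0
    n_rows = 0
    for row_id, _, _ in block.rows:
        if row_id == ref:
            continue
        n_rows += 1
        seq = block.ungapped(row_id)
        hits = scan_sequence(seq, definition)
        best: int | None = None
        for h in hits:
            if space == "columns":
                col = map_position_to_column(block, row_id, h.core_start)
                dist = abs(col - ref_column)
            else:
                anchor = _project_column(block, row_id, ref_column)
                dist = abs(h.core_start - anchor)
            if best is None or dist < best:
                best = dist
        conserved = best is not None and best <= window
        if conserved:
            n_conserved += 1
        per_row[row_id] = (conserved, best)
    fraction = n_conserved / n_rows if n_rows else 0.0
    return ConservationResult(
        core_start=human_core_start,
        reference_column=ref_column,
        per_row=per_row,
        conserved_fraction=fraction,
    )


def _project_column(block: AlignmentBlock, row_id: str, column: int) -> int:
    """Ungapped position in ``row_id`` at (or nearest before) ``column``."""
    pos = map_column_to_position(block, row_id, column)
    if pos is not None:
        return pos
    seq = block.row(row_id)
    before = sum(1 for ch in seq[: column - 1] if ch != "-")
    return max(before, 1)


def conservation_table(
    result: ConservationResult, motif_label: str
) -> pd.DataFrame:
    rows = [
        {
            "motif": motif_label,
            "species": row_id,
            "conserved": conserved,
            "column_distance": dist if dist is not None else ".",
            "conserved_fraction": result.conserved_fraction,
        }
        for row_id, (conserved, dist) in result.per_row.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["motif", "species", "conserved", "column_distance", "conserved_fraction"],
    )
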