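"""Proteome-wide motif scanning with a sequence-shuffle null model.

Short linear motif patterns are degenerate and occur by chance, especially
in proline/arginine-rich sequences.  This module scans a whole proteome for
a motif definition and, per protein, estimates how surprising the observed
match count is under random permutations of the same sequence (the shuffle
null preserves residue composition exactly).  It also applies the standard
hit-filtering annotations used in SLiM discovery: disorder over the motif
window, broad localization, and overlap with known interaction partners of
a protein family.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import (
    CORE_LENGTH,
    MotifDefinition,
    MotifHit,
    SequenceError,
    hits_to_rows,
    scan_sequence,
    validate_sequence,
)

HIT_COLUMNS = [
    "protein_id",
    "definition",
    "class",
    "core_start",
    "core_end",
    "window_seq",
    "position0",
    "reverse_candidate",
    "phospho_flank",
]


@dataclass
class ProteinRecord:
    """One proteome entry with optional per-residue and per-protein annotations."""

    protein_id: str
    sequence: str
    disorder_scores: Sequence[float] | None = None
    intracellular: bool | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.disorder_scores is not None and len(self.disorder_scores) != len(
            self.sequence
        ):
            raise ValueError(
                f"{self.protein_id}: disorder_scores length "
                f"{len(self.disorder_scores)} != sequence length "
                f"{len(self.sequence)}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(protein_id=rec.id, sequence=str(rec.seq).upper()))
    return records


def read_disorder_tsv(path: str | Path) -> dict[str, dict[int, float]]:
    """Read per-residue disorder scores: columns protein_id, position, score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, dict[int, float]] = {}
    for pid, sub in df.groupby("protein_id"):
        out[str(pid)] = dict(
            zip(sub["position"].astype(int), sub["score"].astype(float))
        )
    return out


def attach_disorder(
    records: Iterable[ProteinRecord], scores: Mapping[str, Mapping[int, float]]
) -> None:
    """Attach disorder score vectors (in place) where available."""
    for rec in records:
        per_pos = scores.get(rec.protein_id)
        if per_pos is None:
            continue
        vec = [float(per_pos.get(i, np.nan)) for i in range(1, len(rec.sequence) + 1)]
        rec.disorder_scores = vec


def read_localization_tsv(path: str | Path) -> dict[str, bool]:
    """Columns: protein_id, intracellular (true/false/1/0)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    truthy = {"true", "1", "yes", "t"}
    return {
        str(r.protein_id): str(r.intracellular).strip().lower() in truthy
        for r in df.itertuples()
    }


def read_partner_tsv(path: str | Path) -> set[frozenset[str]]:
    """Two-column TSV of interacting identifier pairs (unordered)."""
    pairs: set[frozenset[str]] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"partner table line has <2 columns: {line!r}")
        pairs.add(frozenset(parts[:2]) if parts[0] != parts[1] else frozenset([parts[0]]))
    return pairs


def read_mitab(path: str | Path) -> set[frozenset[str]]:
    """Extract interactor A/B identifiers from a PSI-MITAB file.

    Only the first two columns are used; 'prefix:accession' tokens are
    reduced to the accession.
    """
    pairs: set[frozenset[str]] = set()
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 2:
            continue
        ids = []
        for col in cols[:2]:
            token = col.split("|")[0].strip()
            ids.append(token.split(":", 1)[1] if ":" in token else token)
        if ids[0] and ids[1]:
            pairs.add(
                frozenset(ids) if ids[0] != ids[1] else frozenset([ids[0]])
            )
    return pairs


# ---------------------------------------------------------------------------
# proteome scan
# ---------------------------------------------------------------------------

def scan_proteome(
    records: Sequence[ProteinRecord], definition: MotifDefinition
) -> tuple[pd.DataFrame, int]:
    """Scan every record; return the hit table and the number of distinct
    proteins with at least one hit."""
    if not records:
        raise ValueError("empty proteome")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")
    rows: list[dict] = []
    proteins_with_hit = 0
    for rec in records:
        hits = scan_sequence(rec.sequence, definition, rec.protein_id)
        if hits:
            proteins_with_hit += 1
        rows.extend(hits_to_rows(hits))
    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return table, proteins_with_hit


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

@dataclass
class ShuffleNullResult:
    protein_id: str
    definition: str
    observed_count: int
    n_shuffles: int
    shuffled_counts: list[int]
    mean_shuffled: float
    sd_shuffled: float
    empirical_p: float
    seed: int


def derive_protein_seed(master_seed: int, protein_id: str) -> int:
    """Per-protein RNG substream seed, independent of proteome ordering.

    Hashes the protein id and folds the master seed in, so that fixing the
    master seed fixes every protein's shuffle stream bit-for-bit regardless
    of scan order or platform.
    """
    digest = hashlib.sha256(protein_id.encode()).digest()
    h = int.from_bytes(digest[:8], "big")
    return (h ^ (master_seed * 0x9E3779B97F4A7C15)) % (2**63)


def shuffle_null(
    record: ProteinRecord,
    definition: MotifDefinition,
    n_shuffles: int = 100,
    seed: int = 0,
) -> ShuffleNullResult:
    """Count motif matches in ``n_shuffles`` uniform permutations of the sequence.

    Each shuffle permutes the full sequence (residue composition preserved
    exactly) and is re-scanned with the same semantics as the observed scan.
    The empirical p-value uses the add-one estimator
    ``(1 + #{c >= observed}) / (n_shuffles + 1)`` so it is never zero.
    """
    seq = record.sequence
    if len(seq) < definition.window_length:
        raise ValueError(
            f"{record.protein_id}: sequence shorter than the motif window "
            f"({len(seq)} < {definition.window_length})"
        )
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    validate_sequence(seq)
    observed = len(scan_sequence(seq, definition, record.protein_id))
    rng = np.random.default_rng(derive_protein_seed(seed, record.protein_id))
    residues = np.frombuffer(seq.encode(), dtype="S1")
    counts: list[int] = []
    for _ in range(n_shuffles):
        shuffled = rng.permutation(residues)
        shuffled_seq = shuffled.tobytes().decode()
        assert sorted(shuffled_seq) == sorted(seq)  # composition preserved
        counts.append(len(scan_sequence(shuffled_seq, definition)))
    arr = np.asarray(counts)
    p = (1 + int((arr >= observed).sum())) / (n_shuffles + 1)
    return ShuffleNullResult(
        protein_id=record.protein_id,
        definition=definition.name,
        observed_count=observed,
        n_shuffles=n_shuffles,
        shuffled_counts=counts,
        mean_shuffled=float(arr.mean()),
        sd_shuffled=float(arr.std(ddof=1)) if n_shuffles > 1 else 0.0,
        empirical_p=p,
        seed=seed,
    )


def expected_shuffled_count(sequence: str, definition: MotifDefinition) -> float:
    """Exact expectation of the match count under a uniform permutation.

    Any ordered w-tuple of distinct sequence positions is an exchangeable
    sample without replacement from the residue multiset, so every window
    has the same match probability; by linearity the expected count is
    ``(L - w + 1) * P(window matches)``.  ``P`` is computed exactly by
    recursion over the positional classes with depleting residue counts.
    """
    w = definition.window_length
    L = len(sequence)
    if L < w:
        return 0.0
    counts: dict[str, int] = {}
    for ch in sequence:
        counts[ch] = counts.get(ch, 0) + 1

    classes: list[frozenset[str]] = list(definition.core_classes)
    if definition.requires_full_window:
        from .motifs import AMINO_ACIDS

        for excl in definition.flank_exclusions:
            classes.append(AMINO_ACIDS - excl)

    def prob(remaining: dict[str, int], total: int, depth: int) -> float:
        if depth == len(classes):
            return 1.0
        acc = 0.0
        for r in classes[depth]:
            c = remaining.get(r, 0)
            if c == 0:
                continue
            remaining[r] = c - 1
            acc += (c / total) * prob(remaining, total - 1, depth + 1)
            remaining[r] = c
        return acc

    return (L - w + 1) * prob(counts, L, 0)


# ---------------------------------------------------------------------------
# hit filters / annotation
# ---------------------------------------------------------------------------

@dataclass
class DisorderStatus:
    evaluable: bool
    mean_disorder: float | None
    passes: bool | None


def disorder_filter(
    hit: MotifHit, record: ProteinRecord, threshold: float = 0.5
) -> DisorderStatus:
    """Mean disorder over the hit window vs ``threshold`` (pass iff mean >= it).

    When the record carries no disorder scores, an explicit not-evaluable
    status is returned rather than a silent pass.
    """
    if record.disorder_scores is None:
        return DisorderStatus(evaluable=False, mean_disorder=None, passes=None)
    window = record.disorder_scores[hit.window_start - 1 : hit.window_end]
    mean = float(np.mean(window))
    return DisorderStatus(evaluable=True, mean_disorder=mean, passes=mean >= threshold)


@dataclass
class AnnotatedHit:
    hit: MotifHit
    mean_disorder_over_window: float | None = None
    passes_disorder: bool | None = None
    intracellular: bool | None = None
    partner_of: list[str] = field(default_factory=list)
    self_interaction: bool = False
    shuffle_p: float | None = None


def overlap_partners(
    hits: Sequence[MotifHit],
    partner_pairs: Iterable[frozenset[str]],
    family_ids: Sequence[str],
) -> list[AnnotatedHit]:
    """Annotate each hit with the family proteins its protein partners.

    ``partner_pairs`` is a set of unordered identifier pairs.  Hits in
    non-partner proteins are retained (empty ``partner_of``); a hit inside a
    family protein itself whose only support is a self-interaction pair is
    flagged ``self_interaction``.
    """
    pairs = set(partner_pairs)
    annotated = []
    for hit in hits:
        partner_of = []
        self_flag = False
        for fam in family_ids:
            if hit.protein_id == fam:
                if frozenset([fam]) in pairs:
                    self_flag = True
                continue
            if frozenset([fam, hit.protein_id]) in pairs:
                partner_of.append(fam)
        annotated.append(
            AnnotatedHit(hit=hit, partner_of=partner_of, self_interaction=self_flag)
        )
    return annotated


def null_summary_table(results: Sequence[ShuffleNullResult]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": r.protein_id,
            "definition": r.definition,
            "observed_count": r.observed_count,
            "n_shuffles": r.n_shuffles,
            "mean_shuffled": r.mean_shuffled,
            "sd_shuffled": r.sd_shuffled,
            "empirical_p": r.empirical_p,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "definition",
            "observed_count",
            "n_shuffles",
            "mean_shuffled",
            "sd_shuffled",
            "empirical_p",
        ],
    )
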