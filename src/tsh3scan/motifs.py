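"""Tandem-SH3-binding motif definitions, scanning and hit classification.

A tandem pair of SH3 domains (tSH3) can associate into a single composite
groove that binds one proline-rich peptide in a polyproline-II conformation
(the "superSH3" mode described for the p47phox/NCF1 organizer family).  The
binding preference of that groove is describable, ELM-style, as a positional
character-class regular expression over an 8-position frame:

    position 0   residue immediately preceding the core (context only;
                 an Arg here marks candidates for the reverse binding mode)
    positions 1-5  the PPII-forming core, e.g. [PAVIL]PPR[PR]
    positions 6-7  C-terminal flanks where acidic residues abolish binding

Three built-in definitions ship with the module:

    strong   [PAVIL]PPR[PR][^DE][^DE]   optimal tSH3 binders
    weak     [PAVIL]P[PTAV]R[RP][^DE][^DE]   relaxed 3rd/5th core position
    core     [PAVIL]PPR[PR]             the 5-residue core alone

The strong language is position-wise contained in the weak language, so
every strong match is also a weak match.  All coordinates are 1-based and
inclusive (UniProt style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in input sequences; 'X' is tolerated but never matches
#: any positional class.
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}

ACIDIC = frozenset("DE")
PHOSPHO_ACCEPTORS = frozenset("ST")

CORE_LENGTH = 5
WINDOW_LENGTH = 7  # core + two C-terminal flank positions


class MotifError(ValueError):
    """Raised on malformed motif definitions or contract violations."""


class SequenceError(ValueError):
    """Raised when an input sequence contains a non-amino-acid character."""


def _as_class(residues: Iterable[str], *, what: str) -> frozenset[str]:
    cls = frozenset(residues)
    if not cls <= AMINO_ACIDS:
        bad = "".join(sorted(cls - AMINO_ACIDS))
        raise MotifError(f"{what} contains non-standard residues: {bad!r}")
    return cls


@dataclass(frozen=True)
class MotifDefinition:
    """A named positional-character-class motif.

    ``core_classes`` lists, in order, the allowed residues at core positions
    1-5.  ``flank_exclusions`` lists the *forbidden* residues at positions
    6-7 (an empty set means the position is unconstrained).  When
    ``requires_full_window`` is true a match must have both flank positions
    inside the sequence; core-only definitions set it false.
    """

    name: str
    core_classes: tuple[frozenset[str], ...]
    flank_exclusions: tuple[frozenset[str], ...]
    requires_full_window: bool = True

    def __post_init__(self) -> None:
        if len(self.core_classes) != CORE_LENGTH:
            raise MotifError(
                f"definition {self.name!r}: expected {CORE_LENGTH} core "
                f"classes, got {len(self.core_classes)}"
            )
        for i, cls in enumerate(self.core_classes, start=1):
            if not cls:
                raise MotifError(
                    f"definition {self.name!r}: core position {i} is empty"
                )
            _as_class(cls, what=f"{self.name} core position {i}")
        if len(self.flank_exclusions) != 2:
            raise MotifError(
                f"definition {self.name!r}: expected 2 flank exclusions, "
                f"got {len(self.flank_exclusions)}"
            )
        for i, cls in enumerate(self.flank_exclusions, start=6):
            _as_class(cls, what=f"{self.name} flank position {i}")

    @property
    def window_length(self) -> int:
        return WINDOW_LENGTH if self.requires_full_window else CORE_LENGTH

    def core_matches(self, pentamer: str) -> bool:
        """True iff the 5-residue ``pentamer`` satisfies positions 1-5."""
        if len(pentamer) != CORE_LENGTH:
            return False
        return all(r in cls for r, cls in zip(pentamer, self.core_classes))

    def flank_allowed(self, position: int, residue: str | None) -> bool:
        """Whether ``residue`` is allowed at flank ``position`` (6 or 7).

        ``None`` (position beyond the sequence end) is allowed only when the
        definition does not require a full window.
        """
        if position not in (6, 7):
            raise MotifError(f"flank position must be 6 or 7, got {position}")
        if residue is None:
            return not self.requires_full_window
        # flank positions are the class [^exclusions]; 'X' satisfies no class
        return residue in AMINO_ACIDS and residue not in self.flank_exclusions[position - 6]

    def window_matches(self, window: str) -> bool:
        """True iff a 7-mer satisfies core classes and flank exclusions."""
        if len(window) != WINDOW_LENGTH:
            return False
        return self.core_matches(window[:CORE_LENGTH]) and all(
            self.flank_allowed(6 + i, window[CORE_LENGTH + i]) for i in range(2)
        )

    def contains(self, other: "MotifDefinition") -> bool:
        """Position-wise language containment: every ``other`` match matches self."""
        return all(
            o <= s for o, s in zip(other.core_classes, self.core_classes)
        ) and all(
            s <= o for s, o in zip(self.flank_exclusions, other.flank_exclusions)
        )


_PAVIL = frozenset("PAVIL")

STRONG = MotifDefinition(
    name="strong",
    core_classes=(_PAVIL, frozenset("P"), frozenset("P"), frozenset("R"), frozenset("PR")),
    flank_exclusions=(ACIDIC, ACIDIC),
    requires_full_window=True,
)

WEAK = MotifDefinition(
    name="weak",
    core_classes=(_PAVIL, frozenset("P"), frozenset("PTAV"), frozenset("R"), frozenset("RP")),
    flank_exclusions=(ACIDIC, ACIDIC),
    requires_full_window=True,
)

CORE = MotifDefinition(
    name="core",
    core_classes=STRONG.core_classes,
    flank_exclusions=(frozenset(), frozenset()),
    requires_full_window=False,
)

BUILTIN_DEFINITIONS: dict[str, MotifDefinition] = {
    d.name: d for d in (STRONG, WEAK, CORE)
}


def get_definition(name: str) -> MotifDefinition:
    try:
        return BUILTIN_DEFINITIONS[name]
    except KeyError:
        raise MotifError(
            f"unknown motif definition {name!r}; "
            f"built-ins: {sorted(BUILTIN_DEFINITIONS)}"
        ) from None


def load_definitions(path: str | Path) -> dict[str, MotifDefinition]:
    """Load motif definitions from a plain-text config.

    Each non-comment line holds 8 whitespace-separated fields: a name, five
    core class strings (allowed residues), and two flank exclusion strings
    (forbidden residues; ``.`` means unconstrained).  A definition whose two
    exclusions are both ``.`` is treated as core-only (no full-window
    requirement).
    """
    definitions: dict[str, MotifDefinition] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 8:
            raise MotifError(
                f"{path}:{lineno}: expected 8 fields "
                f"(name, 5 classes, 2 exclusions), got {len(fields)}"
            )
        name = fields[0]
        core = tuple(frozenset(f) for f in fields[1:6])
        excl = tuple(
            frozenset() if f == "." else frozenset(f) for f in fields[6:8]
        )
        definitions[name] = MotifDefinition(
            name=name,
            core_classes=core,
            flank_exclusions=excl,
            requires_full_window=any(excl),
        )
    return definitions


@dataclass(frozen=True)
class MotifHit:
    """One located motif match, in absolute 1-based inclusive coordinates."""

    protein_id: str
    definition: str
    core_start: int
    core_end: int
    window_start: int
    window_end: int
    matched_core: str
    flank_residues: str
    position0_residue: str | None
    class_label: str
    reverse_candidate: bool
    phospho_flank: bool

    def __post_init__(self) -> None:
        if self.core_end != self.core_start + CORE_LENGTH - 1:
            raise MotifError("core_end must equal core_start + 4")
        if self.class_label not in ("strong", "weak_only", "core_only"):
            raise MotifError(f"bad class label {self.class_label!r}")


def validate_sequence(sequence: str) -> None:
    """Reject any character outside the 20 standard residues plus 'X'."""
    for i, ch in enumerate(sequence, start=1):
        if ch not in SEQUENCE_ALPHABET:
            raise SequenceError(
                f"non-amino-acid character {ch!r} at position {i}"
            )


def classify_window(
    core: str,
    position0: str | None,
    flanks: str,
) -> tuple[str, bool, bool]:
    """Classify a matched window given its position-0-to-7 context.

    ``flanks`` holds whatever of positions 6-7 exists in the sequence
    (0-2 residues).  Returns ``(class_label, reverse_candidate,
    phospho_flank)``.

    A window is *strong* when all seven positions satisfy the strong
    definition, *weak_only* when it satisfies the weak 7-mer but not the
    strong one, and *core_only* when both 7-mer definitions fail (through a
    flank violation or a truncated window) but positions 1-5 still match the
    strong core.  A reverse-binding candidate additionally requires Arg at
    position 0 together with an acidic flank residue.
    """
    if not (STRONG.core_matches(core) or WEAK.core_matches(core)):
        raise MotifError(
            f"core {core!r} matches neither the strong nor the weak core"
        )
    if len(flanks) > 2:
        raise MotifError("at most two flank residues allowed")

    full = len(flanks) == 2
    flank_ok_strong = full and all(
        STRONG.flank_allowed(6 + i, flanks[i]) for i in range(2)
    )
    if STRONG.core_matches(core) and flank_ok_strong:
        label = "strong"
    elif WEAK.core_matches(core) and full and all(
        WEAK.flank_allowed(6 + i, flanks[i]) for i in range(2)
    ):
        label = "weak_only"
    elif STRONG.core_matches(core):
        label = "core_only"
    else:
        raise MotifError(
            f"window (core {core!r}, flanks {flanks!r}) fits neither 7-mer "
            "definition nor the strong core"
        )

    reverse_candidate = position0 == "R" and any(r in ACIDIC for r in flanks)
    phospho_flank = any(r in PHOSPHO_ACCEPTORS for r in flanks)
    return label, reverse_candidate, phospho_flank


def scan_sequence(
    sequence: str,
    definition: MotifDefinition,
    protein_id: str = "",
    anchor: int = 1,
) -> list[MotifHit]:
    """Scan one sequence for every (possibly overlapping) motif match.

    ``anchor`` is the absolute 1-based position of the first residue of
    ``sequence``; reported coordinates are anchor-based.  With a
    full-window definition, matches whose flank positions fall beyond the
    sequence end are not reported.
    """
    if anchor < 1:
        raise MotifError(f"anchor must be >= 1, got {anchor}")
    validate_sequence(sequence)
    hits: list[MotifHit] = []
    n = len(sequence)
    for i in range(n - CORE_LENGTH + 1):
        core = sequence[i : i + CORE_LENGTH]
        if not definition.core_matches(core):
            continue
        flanks = sequence[i + CORE_LENGTH : i + CORE_LENGTH + 2]
        if definition.requires_full_window:
            if len(flanks) < 2:
                continue
            if not all(
                definition.flank_allowed(6 + k, flanks[k]) for k in range(2)
            ):
                continue
        position0 = sequence[i - 1] if i >= 1 else None
        label, reverse, phospho = classify_window(core, position0, flanks)
        core_start = anchor + i
        hits.append(
            MotifHit(
                protein_id=protein_id,
                definition=definition.name,
                core_start=core_start,
                core_end=core_start + CORE_LENGTH - 1,
                window_start=core_start,
                window_end=core_start + CORE_LENGTH - 1 + len(flanks),
                matched_core=core,
                flank_residues=flanks,
                position0_residue=position0,
                class_label=label,
                reverse_candidate=reverse,
                phospho_flank=phospho,
            )
        )
    return hits


_PX_PAV_X_PR = re.compile(r"(?=P.[PAV].PR)")


def match_px_pav_x_pr(sequence: str, anchor: int = 1) -> list[int]:
    """Find all Px[PAV]xPR hexamers (the individual-CIN85-SH3 preference).

    Returns 1-based (anchor-adjusted) start positions of every, possibly
    overlapping, 6-residue match; used to annotate overlap between tSH3
    motifs and individual-SH3 binding sites.
    """
    validate_sequence(sequence)
    out = []
    for m in _PX_PAV_X_PR.finditer(sequence):
        window = sequence[m.start() : m.start() + 6]
        if "X" in window:  # '.' in the regex would accept the ambiguity code
            continue
        out.append(anchor + m.start())
    return out


def hits_to_rows(hits: Sequence[MotifHit], sequence: str | None = None) -> list[dict]:
    """Flatten hits for tabular output (TSV via pandas)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "protein_id": h.protein_id,
                "definition": h.definition,
                "class": h.class_label,
                "core_start": h.core_start,
                "core_end": h.core_end,
                "window_seq": h.matched_core + h.flank_residues,
                "position0": h.position0_residue or ".",
                "reverse_candidate": h.reverse_candidate,
                "phospho_flank": h.phospho_flank,
            }
        )
    return rows
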