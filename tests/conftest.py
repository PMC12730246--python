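"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's scanning code paths:
they test every window position directly against the positional residue
classes, so agreement with the scanner is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tsh3scan.motifs import CORE_LENGTH, MotifDefinition

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def oracle_core_starts(sequence: str, definition: MotifDefinition) -> list[int]:
    """All 1-based core starts, by testing every window position-by-position."""
    starts = []
    w = 7 if definition.requires_full_window else CORE_LENGTH
    for i in range(len(sequence) - w + 1):
        ok = all(
            sequence[i + j] in definition.core_classes[j] for j in range(CORE_LENGTH)
        )
        if ok and definition.requires_full_window:
            ok = all(
                sequence[i + CORE_LENGTH + k] in AA20
                and sequence[i + CORE_LENGTH + k] not in definition.flank_exclusions[k]
                for k in range(2)
            )
        if ok:
            starts.append(i + 1)
    return starts


def oracle_px_pav_x_pr(sequence: str) -> list[int]:
    """1-based starts of Px[PAV]xPR, window by window."""
    out = []
    for i in range(len(sequence) - 5):
        win = sequence[i : i + 6]
        if (
            win[0] == "P"
            and win[2] in "PAV"
            and win[4] == "P"
            and win[5] == "R"
            and "X" not in win
        ):
            out.append(i + 1)
    return out


def oracle_screen_tier(gww: tuple[bool, ...], linkers: tuple[int, ...],
                       max_linker: int = 60) -> str:
    """Highest screen tier by direct rule application."""
    if len(gww) < 2:
        return "none"
    tier = "a"
    for i in range(len(gww) - 1):
        if gww[i] and gww[i + 1]:
            tier = "b" if tier == "a" else tier
            if linkers[i] < max_linker:
                return "c"
    return tier


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


# --- printed peptide fixture: the validated/proposed tSH3-binding motifs ---

#: (peptide, first-residue position, expected class, reverse, phospho)
TABLE1_PEPTIDES = {
    "NCF1_AIR": ("RGAPPRRSS", 296, "strong", False, True),
    "CYBA": ("SNPPPRPPA", 153, "strong", False, False),
    "NOXO1_CT": ("PTVPTRPSP", 329, "weak_only", False, True),
    "TKS4_AIR": ("QRPPPRRDM", 344, "core_only", True, False),
    "SOS1": ("PPVPPRRRP", 1151, "strong", False, False),
    "NCF1_CT": ("PAVPPRPSA", 363, "strong", False, True),
    "TKS4_CT": ("PVVPPRRPP", 755, "strong", False, False),
    "TKS5_AIR": ("TRPPPRRES", 398, "core_only", True, True),
}

#: partner-protein motif windows printed with the proteome screen
PARTNER_MOTIFS = {
    "RELA": ("PPPRRIA", 326),
    "NCF2": ("PPPRPKT", 227),
    "ADAM19": ("PPPRPPP", 789),
}


@pytest.fixture
def table1_peptides():
    return TABLE1_PEPTIDES


@pytest.fixture
def partner_motifs():
    return PARTNER_MOTIFS


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
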