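"""Tandem SH3 domain identification and tandemization-signature screening.

Two consecutive SH3 domains on one chain can only associate into a
composite peptide-binding groove when the connecting linker is short
(< 60 residues) and both domains carry the sequence signatures of
tandemization:

* **GWW** — a Gly-Trp-Trp triplet in each domain; the Gly permits the
  close domain-domain packing (larger residues clash; Gly-to-Ser changes
  here cause chronic granulomatous disease) and the Trp residues form the
  peptide pockets and the inter-domain hydrogen bonds.
* **C-[DE][DE]** — two adjacent acidic residues in the C-terminal SH3 that
  salt-bridge the motif's invariant position-4 Arg.
* **N-PxxΦL** — a Pro-x-x-aromatic-Leu hydrophobic patch near the end of
  the N-terminal SH3 that contacts motif positions 3 and 5 (Φ in {F,W,Y};
  the relaxed variant also accepts Val at the last position, as seen in
  CIN85).

The screen tiers a proteome into (a) proteins with >= 2 SH3 domains,
(b) consecutive SH3 pairs with GWW in both domains, and (c) GWW pairs that
also pass the linker rule.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scanning import ProteinRecord

SH3_CLASS = "SH3"


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_class: str
    source_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: domain start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class SignatureFlags:
    gww_n: bool
    gww_n_position: int | None
    gww_c: bool
    gww_c_position: int | None
    c_double_negative: bool
    c_double_negative_positions: tuple[int, int] | None
    n_pxx_phi_l: bool
    n_pxx_phi_l_relaxed: bool

    def __post_init__(self) -> None:
        if self.n_pxx_phi_l and not self.n_pxx_phi_l_relaxed:
            raise ValueError("strict N-PxxPhiL implies the relaxed variant")


@dataclass(frozen=True)
class TandemPair:
    protein_id: str
    n_domain: DomainAnnotation
    c_domain: DomainAnnotation
    linker_start: int
    linker_end: int
    linker_length: int
    linker_net_charge: int
    is_tandem: bool
    signatures: SignatureFlags


_DEDE = re.compile(r"(?=[DE][DE])")
_PXXPHIL_STRICT = re.compile(r"P..[FWY]L")
_PXXPHIL_RELAXED = re.compile(r"P..[FWY][LV]")


def detect_signatures(
    n_domain_seq: str, c_domain_seq: str, tail_window: int = 15
) -> SignatureFlags:
    """Evaluate tandemization/motif-binding signatures on a domain pair.

    GWW is an exact substring search in each domain (first occurrence,
    1-based within the domain).  C-[DE][DE] is any adjacent acidic dimer in
    the C-domain.  N-PxxΦL is searched within the last ``tail_window``
    residues of the N-domain.
    """
    if not n_domain_seq or not c_domain_seq:
        raise ValueError("domain sequences must be non-empty")
    gn = n_domain_seq.find("GWW")
    gc = c_domain_seq.find("GWW")
    dd = _DEDE.search(c_domain_seq)
    tail_start = max(0, len(n_domain_seq) - tail_window)
    tail = n_domain_seq[tail_start:]
    strict = _PXXPHIL_STRICT.search(tail) is not None
    relaxed = strict or _PXXPHIL_RELAXED.search(tail) is not None
    return SignatureFlags(
        gww_n=gn >= 0,
        gww_n_position=gn + 1 if gn >= 0 else None,
        gww_c=gc >= 0,
        gww_c_position=gc + 1 if gc >= 0 else None,
        c_double_negative=dd is not None,
        c_double_negative_positions=(dd.start() + 1, dd.start() + 2) if dd else None,
        n_pxx_phi_l=strict,
        n_pxx_phi_l_relaxed=relaxed,
    )


def net_charge(sequence: str) -> int:
    """(#K + #R) - (#D + #E); His treated as neutral."""
    return (
        sequence.count("K")
        + sequence.count("R")
        - sequence.count("D")
        - sequence.count("E")
    )


def find_tandem_pairs(
    domains: Sequence[DomainAnnotation],
    sequence: str,
    max_linker: int = 60,
    tail_window: int = 15,
) -> list[TandemPair]:
    """Evaluate every consecutive pair of SH3-class domains on one protein.

    ``is_tandem`` holds iff the linker (residues strictly between the two
    domains) is shorter than ``max_linker`` (strict inequality).
    """
    proteins = {d.protein_id for d in domains}
    if len(proteins) > 1:
        raise ValueError(f"domains span multiple proteins: {sorted(proteins)}")
    ordered = sorted(domains, key=lambda d: d.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping domains {a.source_id} ({a.start}-{a.end}) and "
                f"{b.source_id} ({b.start}-{b.end})"
            )
    sh3s = [d for d in ordered if d.domain_class.upper() == SH3_CLASS]
    pairs = []
    for n_dom, c_dom in zip(sh3s, sh3s[1:]):
        linker_start = n_dom.end + 1
        linker_end = c_dom.start - 1
        linker_length = c_dom.start - n_dom.end - 1
        linker_seq = sequence[linker_start - 1 : linker_end]
        sig = detect_signatures(
            sequence[n_dom.start - 1 : n_dom.end],
            sequence[c_dom.start - 1 : c_dom.end],
            tail_window=tail_window,
        )
        pairs.append(
            TandemPair(
                protein_id=n_dom.protein_id,
                n_domain=n_dom,
                c_domain=c_dom,
                linker_start=linker_start,
                linker_end=linker_end,
                linker_length=linker_length,
                linker_net_charge=net_charge(linker_seq),
                is_tandem=linker_length < max_linker,
                signatures=sig,
            )
        )
    return pairs


@dataclass
class ScreenReport:
    """Tiered multi-SH3 screening result: (c) ⊆ (b) over pairs, and every
    protein in (b) appears in (a)."""

    multi_sh3_proteins: list[str]            # tier (a)
    gww_pairs: list[TandemPair]              # tier (b)
    tandem_gww_pairs: list[TandemPair]       # tier (c)
    all_pairs: list[TandemPair]


def screen_multi_sh3(
    records: Sequence[ProteinRecord],
    domain_table: Sequence[DomainAnnotation],
    max_linker: int = 60,
    tail_window: int = 15,
) -> ScreenReport:
    """Screen a proteome for candidate tandem-SH3 architectures."""
    by_id = {r.protein_id: r for r in records}
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for dom in domain_table:
        if dom.protein_id not in by_id:
            warnings.warn(
                f"domain table protein {dom.protein_id!r} absent from "
                "proteome; skipped",
                stacklevel=2,
            )
            continue
        by_protein.setdefault(dom.protein_id, []).append(dom)

    tier_a: list[str] = []
    all_pairs: list[TandemPair] = []
    for pid in sorted(by_protein):
        doms = by_protein[pid]
        sh3_count = sum(1 for d in doms if d.domain_class.upper() == SH3_CLASS)
        if sh3_count >= 2:
            tier_a.append(pid)
            all_pairs.extend(
                find_tandem_pairs(
                    doms, by_id[pid].sequence, max_linker=max_linker,
                    tail_window=tail_window,
                )
            )
    tier_b = [p for p in all_pairs if p.signatures.gww_n and p.signatures.gww_c]
    tier_c = [p for p in tier_b if p.is_tandem]
    return ScreenReport(
        multi_sh3_proteins=tier_a,
        gww_pairs=tier_b,
        tandem_gww_pairs=tier_c,
        all_pairs=all_pairs,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_domain_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read an InterPro-style domain table: protein_id, domain_class,
    source_id, start, end (tab-separated, '#' comments tolerated)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DomainAnnotation(
            protein_id=str(r.protein_id),
            domain_class=str(r.domain_class),
            source_id=str(r.source_id),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.itertuples()
    ]


def merge_domain_tables(
    primary: Iterable[DomainAnnotation], extra: Iterable[DomainAnnotation]
) -> list[DomainAnnotation]:
    """Merge a supplementary table into the primary annotations (used to
    repair missing domains, e.g. from UniProt when InterPro lacks one);
    exact duplicates are dropped."""
    merged = list(primary)
    seen = set(merged)
    for dom in extra:
        if dom not in seen:
            merged.append(dom)
            seen.add(dom)
    return merged


def pairs_table(pairs: Sequence[TandemPair]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": p.protein_id,
            "n_domain": f"{p.n_domain.start}-{p.n_domain.end}",
            "c_domain": f"{p.c_domain.start}-{p.c_domain.end}",
            "linker_length": p.linker_length,
            "linker_net_charge": p.linker_net_charge,
            "is_tandem": p.is_tandem,
            "gww_n": p.signatures.gww_n,
            "gww_c": p.signatures.gww_c,
            "c_double_negative": p.signatures.c_double_negative,
            "n_pxx_phi_l": p.signatures.n_pxx_phi_l,
            "n_pxx_phi_l_relaxed": p.signatures.n_pxx_phi_l_relaxed,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "n_domain", "c_domain", "linker_length",
            "linker_net_charge", "is_tandem", "gww_n", "gww_c",
            "c_double_negative", "n_pxx_phi_l", "n_pxx_phi_l_relaxed",
        ],
    )
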