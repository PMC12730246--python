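"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to a tSH3 motif screen are proteome-scale downloads (UniProt
sequences, InterPro domain tables, OMA orthologs, BioEmu ensembles).  The
generators here emulate each substrate at desk scale with a manifest that
records the planted truth, so that scanning, conservation scoring, tandem
screening and ensemble classification can all be tested exactly:

* proteomes with planted motif instances and Pro/Arg-rich decoy regions;
* ortholog families where the motif stays island-conserved over a
  drifting disordered background (with indels), except in chosen
  "kill-list" species where a core position is substituted away;
* SH3 domain architectures with controlled GWW / C-[DE][DE] / N-PxxΦL
  signatures and linker lengths;
* conformer ensembles with a controlled near-native fraction.

Synthetic "SH3 domains" are sequence mimics (~58 residues with planted
signature substrings), not folded domains, and the geometry fixtures use
abstract 3D point sets, so no download is ever required.  Ortholog
background mutations avoid Arg entirely: a motif match requires Arg at
core position 4, so no spurious motif can arise near the reference column
and the emitted conservation labels are exact by construction.  Every
generator is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .conservation import AlignmentBlock
from .ensembles import (
    DEFAULT_RMSD_THRESHOLD,
    ConformerSet,
    RegionSpec,
    rmsd_to_reference,
    superpose,
)
from .motifs import CORE_LENGTH, get_definition, scan_sequence
from .scanning import ProteinRecord
from .tandems import DomainAnnotation

#: approximate human proteome residue frequencies (order-insensitive)
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}

#: P/R-inflated composition used to stress the shuffle null with decoys
DECOY_AA_FREQS: dict[str, float] = {
    **{aa: 0.4 / 18 for aa in HUMAN_AA_FREQS if aa not in "PR"},
    "P": 0.40,
    "R": 0.20,
}


@dataclass
class SyntheticManifest:
    """Ground truth for one generated bundle; reproducible from its seed."""

    seed: int
    planted_motifs: list[tuple[str, str, int, str]] = field(default_factory=list)
    conservation_labels: dict[tuple[str, str], bool] = field(default_factory=dict)
    architecture_labels: dict[str, str] = field(default_factory=dict)
    ensemble_labels: dict[tuple[str, int], bool] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        lines = [f"seed={self.seed}"]
        for i, (pid, name, start, pep) in enumerate(self.planted_motifs):
            lines.append(f"planted.{i}={pid}|{name}|{start}|{pep}")
        for (family, species), label in sorted(self.conservation_labels.items()):
            lines.append(f"conservation.{family}.{species}={label}")
        for pid, tier in sorted(self.architecture_labels.items()):
            lines.append(f"architecture.{pid}={tier}")
        for (construct, idx), label in sorted(self.ensemble_labels.items()):
            lines.append(f"ensemble.{construct}.{idx}={label}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticManifest":
        manifest = cls(seed=0)
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or "=" not in line:
                continue
            key, value = line.split("=", 1)
            if key == "seed":
                manifest.seed = int(value)
            elif key.startswith("planted."):
                pid, name, start, pep = value.split("|")
                manifest.planted_motifs.append((pid, name, int(start), pep))
            elif key.startswith("conservation."):
                _, family, species = key.split(".", 2)
                manifest.conservation_labels[(family, species)] = value == "True"
            elif key.startswith("architecture."):
                manifest.architecture_labels[key.split(".", 1)[1]] = value
            elif key.startswith("ensemble."):
                body, idx = key[len("ensemble.") :].rsplit(".", 1)
                manifest.ensemble_labels[(body, int(idx))] = value == "True"
        return manifest


def _draw_background(rng: np.random.Generator, length: int, composition: Mapping[str, float]) -> list[str]:
    residues = sorted(composition)
    probs = np.array([composition[r] for r in residues], dtype=float)
    probs = probs / probs.sum()
    return list(rng.choice(residues, size=length, p=probs))


def _core_offset(peptide: str, definition_name: str) -> int:
    """0-based offset of the motif core within a planted peptide."""
    definition = get_definition(definition_name)
    hits = scan_sequence(peptide, definition)
    if not hits:
        raise ValueError(
            f"planted peptide {peptide!r} does not match definition "
            f"{definition_name!r}"
        )
    return hits[0].core_start - 1


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def gen_proteome(
    n_proteins: int = 100,
    mean_length: int = 400,
    sd_length: int = 100,
    composition: Mapping[str, float] | None = None,
    planted: Sequence[tuple[str, str, int, str]] = (),
    seed: int = 0,
) -> tuple[list[ProteinRecord], SyntheticManifest]:
    """Generate a synthetic proteome with planted motif instances.

    ``planted`` holds (protein_id, definition_name, core_start, peptide)
    tuples; the peptide (which may include position-0/flank context) is
    written into the protein so that its motif core begins at
    ``core_start``.  Background residues are drawn i.i.d. from
    ``composition`` (human-like frequencies by default).  Overlapping
    planted windows are an error.
    """
    composition = dict(composition or HUMAN_AA_FREQS)
    rng = np.random.default_rng(seed)
    min_length = 50
    by_protein: dict[str, list[tuple[int, int, str]]] = {}
    for pid, name, core_start, peptide in planted:
        offset = _core_offset(peptide, name)
        start = core_start - offset  # 1-based start of the peptide
        if start < 1:
            raise ValueError(f"planted peptide {peptide!r} extends before position 1")
        by_protein.setdefault(pid, []).append((start, start + len(peptide) - 1, peptide))
    for pid, spans in by_protein.items():
        spans.sort()
        for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{pid}: planted windows {s1}-{e1} and {s2}-{e2} overlap"
                )

    records = []
    planted_ids = sorted(by_protein)
    plain_needed = max(0, n_proteins - len(planted_ids))
    ids = planted_ids + [f"SYN{i:04d}" for i in range(1, plain_needed + 1)]
    for pid in ids:
        length = int(max(min_length, round(rng.normal(mean_length, sd_length))))
        spans = by_protein.get(pid, [])
        if spans:
            length = max(length, max(e for _, e, _ in spans))
        seq = _draw_background(rng, length, composition)
        for start, end, peptide in spans:
            seq[start - 1 : end] = list(peptide)
        records.append(ProteinRecord(protein_id=pid, sequence="".join(seq)))

    manifest = SyntheticManifest(seed=seed, planted_motifs=list(planted))
    return records, manifest


# ---------------------------------------------------------------------------
# ortholog families
# ---------------------------------------------------------------------------

#: substitution alphabet without Arg (and without Pro, to keep the drifting
#: background from building proline runs that complicate manual inspection)
_SUB_ALPHABET = "ACDEFGHIKLMNQSTVWY"


def gen_ortholog_family(
    human_sequence: str,
    core_start: int,
    definition_name: str = "strong",
    n_species: int = 10,
    sub_rate: float = 0.1,
    indel_rate: float = 0.02,
    kill_species: Sequence[str] = (),
    window: int = 50,
    family: str = "family1",
    seed: int = 0,
) -> tuple[AlignmentBlock, SyntheticManifest]:
    """Generate an aligned ortholog family with known conservation labels.

    The human row is reproduced verbatim.  Each ortholog mutates non-motif
    positions at ``sub_rate`` and applies indels at ``indel_rate`` (split
    between deletions and short insertions); the motif window (core plus
    flanks) is preserved except in ``kill_species``, where the invariant
    core Arg is substituted to Gly.  Because the alignment is emitted by
    construction (gap bookkeeping, no aligner), and background mutations
    never introduce Arg, the returned labels are exact.
    """
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    species = [f"sp{i:02d}" for i in range(1, n_species + 1)]
    unknown = sorted(set(kill_species) - set(species))
    if unknown:
        raise ValueError(f"kill-list species not generated: {unknown}")
    definition = get_definition(definition_name)
    hits = {h.core_start for h in scan_sequence(human_sequence, definition)}
    if core_start not in hits:
        raise ValueError(
            f"human sequence lacks a {definition_name!r} hit at {core_start}"
        )
    rng = np.random.default_rng(seed)
    L = len(human_sequence)
    protected = set(range(core_start - 1, min(core_start + CORE_LENGTH + 1, L)))
    kill_pos = core_start - 1 + 3  # 0-based index of the invariant core Arg

    # per-species edit scripts keyed on human positions
    row_chars: dict[str, list[str]] = {}
    insertions: dict[str, dict[int, str]] = {}
    for sp in species:
        chars = list(human_sequence)
        ins: dict[int, str] = {}
        for i in range(L):
            if i in protected:
                continue
            u = rng.random()
            if u < indel_rate / 2:
                chars[i] = "-"
            elif u < indel_rate / 2 + sub_rate:
                choices = [c for c in _SUB_ALPHABET if c != chars[i]]
                chars[i] = choices[rng.integers(len(choices))]
            if rng.random() < indel_rate / 2 and (i + 1) not in protected:
                k = int(rng.integers(1, 4))
                ins[i] = "".join(
                    _SUB_ALPHABET[rng.integers(len(_SUB_ALPHABET))] for _ in range(k)
                )
        if sp in kill_species:
            chars[kill_pos] = "G"
        # repair: remove any residual motif hit that could fake conservation
        # in a killed species (possible when the human background itself
        # contains other motif matches)
        if sp in kill_species:
            while True:
                ungapped = "".join(c for c in chars if c != "-")
                stray = scan_sequence(ungapped, definition)
                if not stray:
                    break
                # map ungapped core position back to the human-indexed list
                target = stray[0].core_start + 3  # the core Arg, 1-based ungapped
                count = 0
                for j, c in enumerate(chars):
                    if c != "-":
                        count += 1
                        if count == target:
                            chars[j] = "G"
                            break
        row_chars[sp] = chars
        insertions[sp] = ins

    # assemble columns: for each human position, optional insertion columns
    # (one block per inserting species) follow the position's column
    rows: dict[str, list[str]] = {"human": []}
    for sp in species:
        rows[sp] = []
    for i in range(L):
        rows["human"].append(human_sequence[i])
        for sp in species:
            rows[sp].append(row_chars[sp][i])
        for sp in species:
            inserted = insertions[sp].get(i)
            if inserted:
                rows["human"].extend("-" * len(inserted))
                for other in species:
                    rows[other].extend(inserted if other == sp else "-" * len(inserted))

    block = AlignmentBlock(
        rows=[("human", "human", "".join(rows["human"]))]
        + [(sp, sp, "".join(rows[sp])) for sp in species],
        reference_row="human",
    )
    manifest = SyntheticManifest(
        seed=seed,
        conservation_labels={
            (family, sp): sp not in set(kill_species) for sp in species
        },
    )
    return block, manifest


# ---------------------------------------------------------------------------
# domain architectures
# ---------------------------------------------------------------------------

#: background alphabet for synthetic domains: no P/W/G/D/E, so the only
#: GWW, [DE][DE] and PxxPhiL occurrences are the planted ones
_DOMAIN_ALPHABET = "ACFHIKLMNQRSTVY"
_LINKER_ALPHABET = "GSNQT"
DOMAIN_LENGTH = 58

_TAILS = {"strict": "PAAFL", "relaxed": "PAAYV", "none": None}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint for one synthetic multi-domain protein.

    Per-SH3-domain tuples: ``gww`` plants the Gly-Trp-Trp triplet,
    ``c_dd`` plants an adjacent acidic dimer, ``tail`` plants a strict or
    relaxed PxxΦL patch in the domain's last residues.
    """

    protein_id: str
    gww: tuple[bool, ...]
    linker_lengths: tuple[int, ...]
    c_dd: tuple[bool, ...] | None = None
    tail: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.gww)
        if n >= 1 and len(self.linker_lengths) != n - 1:
            raise ValueError("need one linker per consecutive domain pair")
        if self.c_dd is not None and len(self.c_dd) != n:
            raise ValueError("c_dd must match the domain count")
        if self.tail is not None and len(self.tail) != n:
            raise ValueError("tail must match the domain count")

    def expected_tier(self, max_linker: int = 60) -> str:
        """Highest screen tier this architecture reaches ('none'/'a'/'b'/'c')."""
        if len(self.gww) < 2:
            return "none"
        tier = "a"
        for i in range(len(self.gww) - 1):
            if self.gww[i] and self.gww[i + 1]:
                tier = "b" if tier == "a" else tier
                if self.linker_lengths[i] < max_linker:
                    return "c"
        return tier


def _render_domain(
    rng: np.random.Generator, gww: bool, c_dd: bool, tail: str
) -> str:
    chars = list(
        _DOMAIN_ALPHABET[i] for i in rng.integers(len(_DOMAIN_ALPHABET), size=DOMAIN_LENGTH)
    )
    if gww:
        chars[4:7] = "GWW"
    else:
        chars[4:7] = "SWW"  # tandem-incompetent variant (Gly-to-Ser)
    if c_dd:
        chars[20:22] = "DE"
    tail_seq = _TAILS[tail]
    if tail_seq:
        chars[-len(tail_seq) :] = tail_seq
    return "".join(chars)


def gen_domain_architectures(
    specs: Sequence[ArchitectureSpec], seed: int = 0
) -> tuple[list[ProteinRecord], list[DomainAnnotation], SyntheticManifest]:
    """Render architecture blueprints into sequences + a domain table.

    Returns protein records, InterPro-style domain annotations and a
    manifest mapping each protein to its expected screen tier.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    labels: dict[str, str] = {}
    for spec in specs:
        n = len(spec.gww)
        c_dd = spec.c_dd or tuple(False for _ in range(n))
        tails = spec.tail or tuple("none" for _ in range(n))
        parts: list[str] = []
        pos = 1
        leader = "".join(
            _LINKER_ALPHABET[i] for i in rng.integers(len(_LINKER_ALPHABET), size=20)
        )
        parts.append(leader)
        pos += len(leader)
        for d in range(n):
            dom_seq = _render_domain(rng, spec.gww[d], c_dd[d], tails[d])
            annotations.append(
                DomainAnnotation(
                    protein_id=spec.protein_id,
                    domain_class="SH3",
                    source_id=f"SYNSH3{d + 1}",
                    start=pos,
                    end=pos + len(dom_seq) - 1,
                )
            )
            parts.append(dom_seq)
            pos += len(dom_seq)
            if d < n - 1:
                linker = "".join(
                    _LINKER_ALPHABET[i]
                    for i in rng.integers(
                        len(_LINKER_ALPHABET), size=spec.linker_lengths[d]
                    )
                )
                parts.append(linker)
                pos += len(linker)
        trailer = "".join(
            _LINKER_ALPHABET[i] for i in rng.integers(len(_LINKER_ALPHABET), size=20)
        )
        parts.append(trailer)
        records.append(
            ProteinRecord(protein_id=spec.protein_id, sequence="".join(parts))
        )
        labels[spec.protein_id] = spec.expected_tier()
    manifest = SyntheticManifest(seed=seed, architecture_labels=labels)
    return records, annotations, manifest


# ---------------------------------------------------------------------------
# conformer ensembles
# ---------------------------------------------------------------------------

def make_reference_tandem(region: RegionSpec = RegionSpec()) -> dict[int, np.ndarray]:
    """Deterministic abstract CA trace for the reference region.

    Each residue range becomes a compact helical spiral; successive ranges
    are offset so the two 'domains' sit side by side like a tandem pair.
    """
    coords: dict[int, np.ndarray] = {}
    for block_idx, (start, end) in enumerate(region.ranges):
        origin = np.array([25.0 * block_idx, 0.0, 0.0])
        for k, resid in enumerate(range(start, end + 1)):
            angle = 0.6 * k
            coords[resid] = origin + np.array(
                [8.0 * np.cos(angle), 8.0 * np.sin(angle), 1.5 * k]
            )
    return coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_conformers(
    reference: Mapping[int, np.ndarray] | None = None,
    n_models: int = 30,
    near_native_fraction: float = 0.2,
    native_noise: float = 0.3,
    displacement: float = 25.0,
    region: RegionSpec = RegionSpec(),
    threshold: float = DEFAULT_RMSD_THRESHOLD,
    label: str = "construct",
    seed: int = 0,
) -> tuple[ConformerSet, SyntheticManifest]:
    """Generate an ensemble with a controlled near-native (tandem) fraction.

    Near-native models are rigid motions of the reference plus Gaussian
    coordinate noise (``native_noise`` Å, calibrated to stay well under the
    RMSD threshold).  Non-native models additionally displace the second
    residue block — the 'C-terminal domain' — by ``displacement`` Å in a
    random direction, breaking the tandem arrangement.  Model order is
    shuffled; the manifest records each model's intended tandem flag, which
    is checked against the realized RMSD during generation.
    """
    if not 0.0 <= near_native_fraction <= 1.0:
        raise ValueError("near_native_fraction must be in [0, 1]")
    reference = dict(reference) if reference is not None else make_reference_tandem(region)
    rng = np.random.default_rng(seed)
    resids = region.residue_ids()
    second_block = set(range(region.ranges[-1][0], region.ranges[-1][1] + 1))
    n_native = round(near_native_fraction * n_models)
    flags = np.array([True] * n_native + [False] * (n_models - n_native))
    rng.shuffle(flags)

    ref = np.array([reference[r] for r in resids])
    models: list[dict[int, np.ndarray]] = []
    for native in flags:
        coords = ref.copy()
        if not native:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for j, resid in enumerate(resids):
                if resid in second_block:
                    coords[j] = coords[j] + displacement * direction
        R = _random_rotation(rng)
        t = rng.normal(scale=10.0, size=3)
        coords = coords @ R.T + t
        if native_noise > 0:
            coords = coords + rng.normal(scale=native_noise, size=coords.shape)
        model = {resid: coords[j] for j, resid in enumerate(resids)}
        realized = superpose(
            np.array([model[r] for r in resids]), ref
        ).rmsd
        if native and realized >= threshold:
            raise RuntimeError(
                f"native model realized RMSD {realized:.2f} >= {threshold}; "
                "lower native_noise"
            )
        if not native and realized < threshold:
            raise RuntimeError(
                f"non-native model realized RMSD {realized:.2f} < {threshold}; "
                "raise displacement"
            )
        models.append(model)

    conformers = ConformerSet(label=label, models=models)
    manifest = SyntheticManifest(
        seed=seed,
        ensemble_labels={(label, i): bool(f) for i, f in enumerate(flags)},
    )
    return conformers, manifest
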