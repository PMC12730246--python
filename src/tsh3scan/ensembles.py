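"""RMSD-based classification of tandem-SH3 conformer ensembles.

A conformer of a linked two-SH3 construct counts as a correct tandem when
the alpha-carbon RMSD of its tandem region to a reference crystal
structure (after least-squares superposition) falls below 5 Å.  Ensembles
of two constructs (for example with and without the proline-rich peptide)
are compared by a two-sided Welch t-test on their raw RMSD distributions,
plus the fraction of tandem conformers at the threshold.  The reference
region defaults to the tandem-SH3 span of the NCF1-CYBA complex crystal
structure (residues 160-211 and 229-283).

Superposition is the classical Kabsch least-squares fit (proper rotation,
reflections corrected, no outlier-rejection cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_RMSD_THRESHOLD = 5.0  # Angstrom
DEFAULT_REGION_RANGES = ((160, 211), (229, 283))

#: relative tolerance on singular values below which the centered point
#: cloud is considered degenerate (collinear or coincident points)
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class RegionSpec:
    """Sorted, non-overlapping residue ranges selecting alpha-carbons."""

    ranges: tuple[tuple[int, int], ...] = DEFAULT_REGION_RANGES
    atom: str = "CA"

    def __post_init__(self) -> None:
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"range start {start} > end {end}")
        for (_, e1), (s2, _) in zip(self.ranges, self.ranges[1:]):
            if s2 <= e1:
                raise ValueError("region ranges must be sorted and non-overlapping")

    def residue_ids(self) -> list[int]:
        out = []
        for start, end in self.ranges:
            out.extend(range(start, end + 1))
        return out

    @classmethod
    def from_tokens(cls, tokens: Sequence[str]) -> "RegionSpec":
        """Parse 'start-end' (or 'chain:start-end'; the chain is ignored)."""
        ranges = []
        for tok in tokens:
            span = tok.split(":", 1)[-1]
            start, end = span.split("-")
            ranges.append((int(start), int(end)))
        return cls(ranges=tuple(sorted(ranges)))


@dataclass
class ConformerSet:
    """An ordered conformer ensemble: residue id -> CA coordinate per model."""

    label: str
    models: list[dict[int, np.ndarray]]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float
    degenerate: bool         # collinear/coincident points; solution still valid


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Least-squares (Kabsch) rigid superposition of ``mobile`` onto
    ``reference``.

    Points must be in one-to-one correspondence.  Returns the proper
    rotation R and translation t minimizing RMSD(R @ mobile + t,
    reference), with the minimized RMSD.  Collinear point sets are still
    solved but flagged degenerate.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point count mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 corresponding 3D points")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    Pc = P - p_mean
    Qc = Q - q_mean
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    sv = np.linalg.svd(Pc, compute_uv=False)
    degenerate = bool(sv[1] <= _DEGENERATE_RTOL * max(sv[0], 1.0))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, degenerate=degenerate)


def rmsd_to_reference(
    conformers: ConformerSet,
    reference: Mapping[int, np.ndarray],
    region: RegionSpec = RegionSpec(),
) -> list[float]:
    """Per-model minimized CA RMSD over the region's residues."""
    resids = region.residue_ids()
    missing_ref = [r for r in resids if r not in reference]
    if missing_ref:
        raise ValueError(f"reference lacks region residues {missing_ref[:5]}...")
    ref = np.array([reference[r] for r in resids], dtype=float)
    rmsds = []
    for idx, model in enumerate(conformers.models):
        missing = [r for r in resids if r not in model]
        if missing:
            raise ValueError(
                f"model {idx} of {conformers.label!r} lacks residues "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        mob = np.array([model[r] for r in resids], dtype=float)
        rmsds.append(superpose(mob, ref).rmsd)
    return rmsds


@dataclass
class EnsembleComparison:
    rmsds_a: list[float]
    rmsds_b: list[float]
    fraction_tandem_a: float
    fraction_tandem_b: float
    threshold: float
    t_statistic: float
    p_value: float


def fraction_tandem(rmsds: Sequence[float], threshold: float = DEFAULT_RMSD_THRESHOLD) -> float:
    """Fraction of conformers with RMSD strictly below the threshold."""
    arr = np.asarray(rmsds, dtype=float)
    return float((arr < threshold).mean())


def compare_ensembles(
    a: Sequence[float],
    b: Sequence[float],
    threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> EnsembleComparison:
    """Welch two-sample, two-sided t-test on raw RMSD lists plus tandem
    fractions at the threshold.

    Degenerate inputs: two zero-variance samples with equal means give
    t=0, p=1 by convention; with unequal means, t=+/-inf and p=0.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each RMSD list needs at least 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            t_stat, p = 0.0, 1.0
        else:
            t_stat = float(np.inf if np.mean(a) > np.mean(b) else -np.inf)
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return EnsembleComparison(
        rmsds_a=a,
        rmsds_b=b,
        fraction_tandem_a=fraction_tandem(a, threshold),
        fraction_tandem_b=fraction_tandem(b, threshold),
        threshold=threshold,
        t_statistic=t_stat,
        p_value=p,
    )


def gww_gly_distance(
    model: Mapping[int, np.ndarray], gly_position_n: int, gly_position_c: int
) -> float:
    """CA-CA Euclidean distance between the Gly residues of the two GWW
    triplets (small in intrachain tandems, large in interchain clustering)."""
    for resid in (gly_position_n, gly_position_c):
        if resid not in model:
            raise ValueError(f"residue {resid} missing from model")
    return float(
        np.linalg.norm(
            np.asarray(model[gly_position_n], dtype=float)
            - np.asarray(model[gly_position_c], dtype=float)
        )
    )


# ---------------------------------------------------------------------------
# multi-model PDB I/O
# ---------------------------------------------------------------------------

def read_multi_model_pdb(
    path: str | Path, label: str | None = None, chain: str | None = None
) -> ConformerSet:
    """Read a multi-model PDB (MODEL/ENDMDL records), extracting CA atoms."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or Path(path).stem, str(path))
    models = []
    for model in structure:
        coords: dict[int, np.ndarray] = {}
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for residue in ch:
                if "CA" in residue:
                    coords[residue.id[1]] = residue["CA"].coord.astype(float)
        models.append(coords)
    if not models:
        raise ValueError(f"no models found in {path}")
    return ConformerSet(label=label or Path(path).stem, models=models)


def write_multi_model_pdb(
    conformers: ConformerSet, path: str | Path, chain: str = "A"
) -> None:
    """Write CA-only models as a plain-text multi-model PDB file."""
    lines = []
    for m_idx, model in enumerate(conformers.models, start=1):
        lines.append(f"MODEL     {m_idx:4d}")
        serial = 1
        for resid in sorted(model):
            x, y, z = model[resid]
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain}{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
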