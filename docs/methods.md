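# Methods

This note documents the models and procedures tsh3scan implements, the
parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Motif model

The tSH3-binding motif is a deterministic positional character-class
pattern, not a probabilistic model: each core position (1–5) has an
allowed-residue set, and the two C-terminal flank positions (6–7) have
forbidden-residue sets. There is no scoring — a window either matches or
it does not. This mirrors how short linear motifs are curated in
ELM-style resources, and it is the right fidelity for a motif defined
from a handful of validated instances; a PSSM would suggest precision the
underlying data cannot support.

Scanning slides a window by one residue and reports **all** matches,
including overlapping ones. Coordinates are 1-based inclusive throughout
(UniProt convention). For the full-window definitions (`strong`, `weak`)
a match whose flank positions fall beyond the protein terminus is not
reported — plain 7-mer regular-expression semantics; the `core`
definition needs only positions 1–5. The ambiguity code `X` is accepted
in input but never satisfies any positional class, including the flank
classes `[^DE]` (conservative: an unknown residue cannot be shown to be
non-acidic).

Classification of a matched window is hierarchical: *strong* when all
seven positions satisfy the strict definition; *weak_only* when the
relaxed 7-mer matches but the strict one does not; *core_only* when both
7-mers fail (flank violation or truncation) but the strict 5-mer core
matches. Reverse-binding candidacy requires the **conjunction** of an Arg
at position 0 and an acidic flank residue — the two features co-occur in
both instances where the reverse orientation is predicted, and either
alone is common enough to be uninformative, so single features are
exposed as annotations (`position0`, flank residues) rather than as
candidacy. The `phospho_flank` flag fires on Ser *or* Thr at positions
6–7; Thr is included as the standard phospho-acceptor generalization of
the Ser-centred evidence and should be read as a deliberate extension.

## Shuffle null

For each protein the observed motif count is compared with counts in
`n_shuffles = 100` uniform random permutations of the full sequence,
which preserve residue composition exactly. The empirical p-value uses
the add-one estimator `(1 + #{c >= observed})/(n + 1)`, so the smallest
attainable value at 100 shuffles is 1/101 ≈ 0.0099 and p is never zero.
P-values are reported raw, with no multiple-testing correction — the
statistic is a per-protein composition diagnostic, not a family-wise
discovery test.

Per-protein RNG substreams are derived by hashing the protein identifier
(SHA-256) and folding in the master seed, so results are independent of
proteome ordering and stable across platforms.

`expected_shuffled_count` computes the *exact* expectation of the count
under a uniform permutation: any ordered w-tuple of positions is an
exchangeable sample without replacement from the residue multiset, so
every window has the same match probability and the expectation is
`(L − w + 1) · P(window matches)`, with `P` evaluated by recursion over
the positional classes with depleting residue counts. This closed form is
the oracle the simulation is tested against.

## Hit filters

Disorder is aggregated as the **mean** predictor score over the 7-residue
window, passed at the conventional 0.5 cut; the choice of aggregation
rule and threshold is ours (mean-over-window is the least surprising
default and the threshold is configurable). Missing scores yield an
explicit not-evaluable status, never a silent pass, and the filter is
exposed as an annotation column rather than a hard drop, so both usages
are available. Localization and interaction-partner lists are consumed as
file inputs (TSV, or PSI-MITAB for partners); proteins without
localization annotation are kept and flagged unknown. Self-interactions
are reported but marked, so downstream tables can exclude them.

## Conservation

Ortholog selection keeps, per species, hits with identity strictly above
20% and query coverage of at least 60%, then takes the highest identity
(ties: higher bitscore, then lexicographically smallest subject id — an
arbitrary but deterministic final tie-break).

The ±50-position tolerance for motif recovery in orthologs is measured in
**alignment columns** between core-start columns. Column space is the
interpretation that absorbs indels, which is the stated motivation for
tolerating deviation at all (disordered regions align poorly); measuring
in ortholog residue space is available behind `space="residues"` for
comparison. The boundary is inclusive: a hit exactly 50 columns away is
conserved, 51 is not. The conserved fraction is computed over
non-reference rows. Alignments themselves are external inputs (aligned
FASTA or Clustal); the package never aligns.

## Tandem screen

Two consecutive SH3 domains are a tandem when the linker between them
(residues strictly between the annotated domain boundaries) is **shorter
than 60 residues** — a strict inequality, so linker 59 qualifies and 60
does not. Linker net charge is (#K + #R) − (#D + #E) with His neutral.
Domain coordinates are taken as annotated, with no trimming; a
supplementary domain table can be merged to repair missing annotations.

Signature placement involves two approximations, both configurable and
both reported with positions so stricter locality can be imposed
downstream: the C-[DE][DE] acidic pair is searched over the whole
C-terminal domain (the structural evidence localizes it only in alignment
space), and the N-PxxΦL patch is searched in the last `tail_window = 15`
residues of the N-terminal domain (enough to cover the post-GWW tail).
Φ is {F, W, Y}; His is excluded. The relaxed patch variant allows Val at
the final position, as observed in CIN85.

The screen tiers nest by construction: (a) proteins with ≥ 2 SH3 domains
⊇ (b) consecutive pairs with GWW in both domains ⊇ (c) pairs also passing
the linker rule.

## Ensemble geometry

Superposition is the closed-form Kabsch least-squares fit (SVD of the
cross-covariance, reflection corrected to a proper rotation), with no
outlier-rejection cycles — all region alpha-carbons weigh equally, which
matches superposing with rejection disabled. Residue correspondence is by
residue number within the region specification; no sequence alignment is
attempted. Collinear point sets are still solved (the minimizer is
well-defined) but flagged degenerate because the in-plane rotation
component is arbitrary. The default region (160–211 plus 229–283) and
threshold (5 Å) are configuration values.

The ensemble comparison is a **Welch** (unequal-variance), two-sided
t-test on the raw RMSD lists. The t-test variant was an open choice;
Welch is the conservative default since there is no reason to assume
equal variances between, say, peptide-bound and apo ensembles. Degenerate
inputs: two zero-variance samples with equal means give t = 0, p = 1;
with unequal means, t = ±∞ and p = 0.

## Synthetic generators

The generators produce the study substrates at desk scale with exact
ground truth; their defaults are fixed study conditions, not tuning
knobs.

* **Proteome**: 100 proteins, lengths ~Normal(400, 100) clipped at 50,
  residues i.i.d. from human-like frequencies; planted peptides overwrite
  the background so the motif core lands on the stated coordinate; a
  Pro/Arg-inflated composition is provided to stress the shuffle null
  with decoys. What this does **not** emulate: real position-dependent
  composition, repeats, or domain structure — so passing tests show
  correctness of the machinery, not proteome-scale discovery
  performance, and the published proteome-wide hit count is not
  reproducible without the actual proteome release.
* **Ortholog families**: 10 species, substitution rate 0.1, indel rate
  0.02 (deletions and 1–3-residue insertions split evenly), motif window
  exempt; kill-list species get the invariant core Arg substituted to
  Gly. Background substitutions draw from an alphabet **without Arg**, so
  no spurious motif (which requires Arg at core position 4) can appear; a
  repair pass additionally removes any motif inherited from the human
  background in killed species. This is what makes the emitted labels
  exact. The evolutionary model is i.i.d. per site — no rate
  heterogeneity, no phylogeny.
* **Architectures**: domains are 58-residue sequence mimics over an
  alphabet excluding P/W/G/D/E, so the only GWW, acidic-pair and PxxΦL
  occurrences are the planted ones and tier labels are exact; they are
  not folded domains.
* **Ensembles**: 30 models per construct (the sample size used for
  generated ensembles). Near-native models are random rigid motions of an
  abstract two-block reference trace plus 0.3 Å Gaussian noise;
  non-native models displace the second block by 25 Å before the rigid
  motion. Realized RMSDs are checked against the intended labels at
  generation time, so a planted fraction of 0.2 yields exactly 6/30
  tandem conformers. These are abstract point sets: nothing about real
  conformational sampling is emulated, only the downstream
  classification arithmetic.

Every generator is bit-reproducible from its seed, and every bundle
carries a flat-text manifest describing the planted truth.

## Problem sizes and determinism

The test suite and the acceptance script run everything at small scale
(proteomes of tens of proteins, 10-species families, 30-model ensembles,
10^4-shuffle oracles on ~26-residue sequences); these sizes were chosen
as sufficient for exact or 3-standard-error checks of each component. One
master seed governs all stochastic stages; TSV outputs use fixed column
orders, a fixed float format and `.` for missing values (docs/formats.md),
so identical inputs reproduce byte-identical files.

## Known limitations

* The motif model is binary; affinity is not predicted, and the
  experimentally measured dissociation constants of validated instances
  are inputs for interpretation only.
* No reverse-motif regular expression is defined — the two known
  reverse-predicted instances are too homologous to generalize from — so
  only the candidacy flag is exposed.
* Disorder prediction, BLAST, multiple alignment and ensemble generation
  are all external: the package consumes their outputs as files.
* Whether proteome scans should count motifs truncated at protein termini
  is unknowable from the published definitions; we exclude them for the
  full-window definitions (see above) and note that terminal cores are
  still visible through the `core` definition.
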