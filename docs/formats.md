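# File formats

All tabular files are tab-separated with a header row, `#`-prefixed
comment lines tolerated on input, fixed column orders on output, floats
printed with `%.6g`, and `.` for missing values.

## Inputs

**Proteome** — FASTA; record ids are protein identifiers; sequences use
the 20 standard residues plus `X`.

**Disorder scores** — TSV: `protein_id  position  score`
(1-based position, score in [0, 1]).

**Localization** — TSV: `protein_id  intracellular`
(true/false/1/0/yes/no).

**Partners** — two-column TSV of interacting identifiers (unordered
pairs), or PSI-MITAB (the first two columns are parsed;
`prefix:accession` tokens are reduced to the accession).

**Domain annotations** — InterPro-style TSV:
`protein_id  domain_class  source_id  start  end` (1-based inclusive).

**Homology hits** — BLAST-outfmt-6-like TSV with a header:
`query  subject  species  pident  qstart  qend  bitscore`.

**Alignments** — aligned FASTA or Clustal; row ids double as species
labels.

**Conformer ensembles** — multi-model PDB (`MODEL`/`ENDMDL`); only
alpha-carbons are read.

**Motif definition config** — plain text, 8 whitespace-separated fields
per line: name, five core class strings, two flank exclusion strings
(`.` = unconstrained). A definition with both exclusions `.` is treated
as core-only (no full-window requirement).

## Outputs

**Hits** (`scan`): `protein_id  definition  class  core_start  core_end
window_seq  position0  reverse_candidate  phospho_flank`.

**Null summary** (`null`): `protein_id  definition  observed_count
n_shuffles  mean_shuffled  sd_shuffled  empirical_p`.

**Conservation** (`conserve`): `motif  species  conserved
column_distance  conserved_fraction`.

**Tandem screen** (`tandem`): per-tier TSVs (`.pairs`, `.gww`, `.tandem`,
`.multi_sh3`) with `protein_id  n_domain  c_domain  linker_length
linker_net_charge  is_tandem  gww_n  gww_c  c_double_negative
n_pxx_phi_l  n_pxx_phi_l_relaxed`.

**Ensemble** (`ensemble`): `construct  model  rmsd  tandem`.

**Report** (`report`): ranked hit table joining scan, null, disorder,
localization and partner columns; sorted by empirical p, then protein id,
then position.

**Manifest** (`synth`): flat `key=value` text recording the planted
ground truth (planted motifs, conservation labels, architecture tiers,
ensemble flags) and the seed.
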