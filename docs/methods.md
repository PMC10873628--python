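# Methods

This note documents the models, conventions, and numerical choices behind
curtainkit, and what the synthetic fixtures do and do not establish about
real data.

## Coordinate and scale conventions

* All residue and site coordinates are **1-based, inclusive**, everywhere.
* Volcano space is x = log2 fold change, y = −log10 significance. Scales of
  input columns are **declared** in the column map (`linear` vs `log2` fold
  change, `raw_p` vs `neglog10` significance), never inferred from data.
* Rows whose transform is undefined (FC ≤ 0 on a linear scale; p ≤ 0 or
  p > 1 on a raw-p scale; negative values on a −log10 scale) are **dropped
  and counted**, not clamped: a clamped point would sit at a fabricated
  position on the volcano. The read report satisfies
  dropped + retained = rows read, always.
* Intensity 0 in a quantitation matrix means *not detected* and becomes
  missing (NaN) before any log or correlation step. Duplicate feature ids
  keep the first occurrence with a logged warning (deterministic and
  order-stable).
* Multi-accession protein groups (`P1;P2`) keep the full group string as
  the feature id; the first accession is the representative for sequence
  and annotation lookup.

## Volcano classification

*Significant* ⇔ y > `sig_cutoff`; *changed* ⇔ |x| > `fc_cutoff`. Both
comparisons are **strict**: the dotted cutoff lines are boundaries, and a
point exactly on a line falls in the less-extreme class, which makes
classification deterministic and monotone in both cutoffs. The default
cutoffs (0.6 log2 units ≈ 1.5-fold; 1.301 ≈ p < 0.05) are labeled presets;
every API takes the cutoffs explicitly.

Class-I PTM sites are those with localization probability **strictly
greater than 0.75**; the threshold is a parameter of `filter_class1`.

Replicate summaries report the sample standard deviation (n−1) and
SEM = SD/√n over non-missing replicates. For n = 1 both are reported as 0
with an `insufficient_replicates` flag rather than raising, so
single-replicate pilot data still renders.

## QC statistics

Profile plots rank each sample's non-missing log2 intensities in
descending order; the plotted multiset equals the source multiset (the
ranking is a permutation). The correlation matrix defaults to **Pearson on
log2 intensities with pairwise-complete observations**: raw MS intensities
span orders of magnitude, and a handful of abundant proteins would
dominate r on the raw scale. Raw-scale and Spearman variants are
selectable. A sample pair sharing fewer than 3 features has no meaningful
coefficient and is reported as NaN — a distinct undefined marker, never 0.
The diagonal is 1 by definition.

## PTM harmonization

The localization-probability grammar is residue letters with `(p)`
immediately after a modified residue (`AAS(0.98)PT(0.02)K`); square-bracket
variants are normalized to this grammar before parsing. Each engine
converter targets one representative export layout, encoded in an
overridable column-preset dataclass:

* **MaxQuant**: sites already carry protein-level positions; the
  `multiplicity` parameter (default 1) selects which `___1/___2/___3`
  intensity-column family to read.
* **MS-Fragger**: protein position = reported peptide start + in-peptide
  position − 1; the peptide must match the protein at that start.
* **Spectronaut**: no protein position at all; the stripped peptide is
  located by exact substring search. Multiple occurrences use the first
  and set an `ambiguous` flag that downstream consumers must surface.
  Combined multi-modification files are split per modification label.
* **DIA-NN**: quantities and probabilities arrive in separate files and
  are inner-joined on the precursor key; unmatched keys are reported,
  never imputed; zero overlap or a protein-group conflict on a shared key
  is an error.

Every converter cross-checks peptide[pos] = residue and, when the protein
sequence is available, protein[pos] = residue; a failing record is flagged
invalid and excluded from downstream analysis by default, never silently
kept or dropped.

## Isoform alignment and remapping

Exactly two sequences are compared per protein, so the remapper uses
pairwise global alignment (Needleman–Wunsch with Gotoh affine gaps) rather
than a multiple-alignment engine. Scoring: BLOSUM62, gap open −10 (first
gap residue), gap extend −0.5 (each further residue); a simple
match/mismatch scheme is available. Letters outside the matrix alphabet
(e.g. U) score as X.

Determinism is part of the contract: among co-optimal alignments the
implementation returns the one whose move sequence is lexicographically
first under **diagonal < up < left** reading from the N-terminus
("up" consumes an experimental residue opposite a gap). It computes suffix
score tables for the three gap states and walks forward greedily, taking
the most-preferred move that still achieves the optimum; the test suite
checks it against an independently coded memoized recursion (scores and
tracebacks) and against Biopython's `PairwiseAligner` (scores). All gap and
substitution scores are integers or halves, exactly representable in
floating point, so score comparisons are exact.

Remapping through the monotone position map either yields the canonical
residue number or `UNALIGNED` (experimental residue opposite a gap); both
residues are retained for mismatch auditing. Database comparison classes
each canonical position as BOTH / EXPERIMENT_ONLY / DATABASE_ONLY, with a
user-selected position overriding to SELECTED and an S_C significance
class setting the asterisk flag. Coincidence requires position **and**
modification type; a coinciding entry whose residue letter disagrees after
remapping is demoted to EXPERIMENT_ONLY with `residue_conflict` set — the
four classes always partition the union of positions.

Motif windows are ±7 residues (15-mer, the convention of the major
kinase-substrate resources) padded with `_` past the sequence ends; the
position-frequency matrix has 21 rows (20 residues + pad) and column sums
equal to the window count.

## Session documents

JSON, schema_version "1.0", UUID4 session ids. Serialization uses sorted
keys and embedded payloads by default, so documents are diffable and
self-contained; NaN is encoded as null. Loading an unsupported version
refuses outright — a silent partial load would corrupt a shared analysis.
Unknown top-level keys round-trip verbatim, so documents from a newer
writer survive a load/save cycle here.

## Synthetic fixtures

`gen_proteome` emulates a small label-free experiment: per-feature log2
intensities are baseline (uniform 22–30) + condition effect + Gaussian
noise, with an optional missing-at-random mask. Defaults — 500 features,
2 conditions × 4 replicates, 10% DE, effect 3 log2 units, noise 0.2 log2
units — describe a strong, clean contrast (e.g. targeted protein
degradation). The accompanying differential table comes from a plain
equal-variance t-test per feature; this is generator plumbing standing in
for the external differential-analysis file a real workflow would import —
the toolkit itself never computes differential statistics.

`gen_ptm` plants S/T/Y sites in random protein sequences (60–120 residues)
and renders one truth table into all four engine dialects using exactly the
converters' column presets (generator and parser are co-specified).
Canonical isoforms differ from experimental sequences by N-terminal offsets
drawn from (0, 0, 3, 11) by default, so canonical position = experimental
position + offset in closed form. Peptides are 15-residue windows around
each site; a peptide occurring more than once in its protein is re-drawn
out of the fixture to keep placement unambiguous.

What passing fixture tests do **not** show about real data: real exports
vary column headers across versions (presets are configurable but cover
one layout each); real localization probabilities are not uniform; real
isoform differences include internal splice events, not only N-terminal
offsets (the aligner handles them, the generator's truth table does not
exercise them); and real missingness is intensity-dependent, not at
random.

## Problem sizes

The default test suite and the acceptance script run in seconds: 500 × 8
proteome matrices, ~24 planted PTM sites across 8 proteins, 1,000 random
alignment pairs of length ≤ 12 plus offset constructions of length ~80–150,
and 50–100 randomized session round trips. These sizes were chosen to make
the contracts (partition, closure, oracle equality, determinism) fully
checkable while keeping the suite fast to iterate on.

## Known limitations

* No rescoring/re-localization of PTM sites; probabilities are taken as
  given. No spectra or mzML handling.
* Differential statistics (p-values, FDR) are consumed, not computed.
* The shipped annotation provider is offline/fixture-based; live lookups
  are an interface, not an implementation.
* Sessions are not byte-compatible with any other tool's storage format.
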