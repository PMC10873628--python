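# curtainkit

A headless Python toolkit for exploring differential proteomics and
post-translational modification (PTM) data the way interactive volcano-plot
tools do — but as a library and CLI you can script, test, and run offline.

It is aimed at MS bioinformaticians who receive search-engine output
(MaxQuant, MS-Fragger, Spectronaut, DIA-NN) plus a differential-analysis
table (Perseus/MSstats-style) and want to:

* import those tables with an **explicit column map** (no header guessing),
  transforming values into volcano space: x = log2 fold change,
  y = −log10 significance;
* **classify** every feature into the four volcano classes defined by a
  fold-change cutoff and a significance cutoff, manage named selection
  sets, and build plot-ready figure data (JSON or SVG);
* run **QC**: per-sample ranked log2-intensity profile plots and the global
  sample × sample correlation matrix (Pearson on log2 intensities,
  pairwise-complete);
* **harmonize PTM sites** from four engine dialects into one canonical site
  table, including parsing in-line localization-probability strings like
  `AAS(0.98)PT(0.02)K` and reconstructing protein residue numbers for
  engines that only report peptide-level positions;
* **remap PTM residue numbers across splice variants** by global sequence
  alignment, compare experimental sites against reference/custom PTM
  databases, and extract ±7-residue motif windows for logo/kinase tools;
* persist everything as a **round-trippable JSON session**.

## The core algorithms

**Volcano classification.** A feature at (x, y) is *significant* iff
y > `sig_cutoff` and *changed* iff |x| > `fc_cutoff` (strict comparisons, so
points exactly on a dotted cutoff line fall in the less-extreme class). The
conjunction yields the four classes S_C, S_NC, NS_C, NS_NC, which partition
any table. Class-I PTM sites are those with localization probability
strictly greater than 0.75.

**Isoform remapping.** Experimental and canonical isoform sequences are
aligned with a global Needleman–Wunsch / Gotoh affine-gap aligner
(BLOSUM62; gap open −10, gap extend −0.5). Among co-optimal alignments the
traceback is deterministic: the alignment whose move sequence is
lexicographically first under diagonal < up < left, reading from the
N-terminus. Site numbers are carried through the resulting monotone
position map; a residue aligned to a gap is reported `UNALIGNED`, never
guessed.

## Worked example

All inputs can be simulated with known ground truth — no downloads:

```python
from curtainkit.synthetic_fixtures import ProteomeSimParams, gen_proteome
from curtainkit.diffexp import CutoffConfig, classify_table
from curtainkit.qc_stats import correlation_matrix, mean_replicate_correlation

fx = gen_proteome(ProteomeSimParams(seed=1))   # 500 features, 2x4 samples
cut = CutoffConfig()                           # |log2 FC| > 0.6, y > 1.301
print(classify_table(fx.differential, cut).value_counts().to_string())
cm = correlation_matrix(fx.matrix)
print("mean replicate correlation:",
      round(mean_replicate_correlation(cm, fx.matrix), 4))
```

prints

```
SignificanceClass.NS_NC    430
SignificanceClass.S_C       50
SignificanceClass.S_NC      20
mean replicate correlation: 0.9929
```

— the 50 features the generator made differentially expressed land in S_C
(significant and changed), the replicate noise level of 0.2 log2 units
yields ~0.99 within-condition correlation, and nothing falls in NS_C at
this effect size. Remapping a site across an N-terminal splice difference:

```python
from curtainkit.ptm_map import align_isoforms, remap_site
amap = align_isoforms("MKSASKLLDEQR", "GPW" + "MKSASKLLDEQR")
print(remap_site(amap, 5))   # -> 8 : experimental Ser5 is canonical Ser8
```

The same pipeline is available from the shell:

```sh
curtainkit simulate proteome --seed 1 --out sim/
curtainkit import --diff sim/differential.tsv --raw sim/raw_matrix.tsv \
    --colmap colmap.json --annot annot.json --out session.json
curtainkit qc --session session.json --out qc.json
curtainkit volcano --session session.json --out volcano.svg
```

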