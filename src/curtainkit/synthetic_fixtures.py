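"""Synthetic proteome and PTM fixtures with known ground truth.

Every input dialect the toolkit reads can be generated here from one
underlying truth table, so the whole pipeline is testable offline with no
deposited data. Two generators:

* :func:`gen_proteome` — a label-free style experiment: per-feature log2
  intensities are baseline + condition effect (for the differentially
  expressed fraction) + Gaussian noise, with an optional missing-at-random
  mask. A plain two-sample t-test per feature produces the accompanying
  differential table (generator plumbing standing in for the Perseus/MSstats
  output a real analysis would consume — the toolkit itself never computes
  differential statistics). Truth labels record which features are DE and
  in which direction.

  Defaults mirror a small but realistic designed experiment: 500 features,
  2 conditions x 4 replicates, 10% DE at 3 log2 units effect, 0.2 log2
  units replicate noise — an effect/noise regime typical of a strong
  targeted-degradation contrast.

* :func:`gen_ptm` — random protein sequences with planted S/T/Y sites, each
  carrying a localization probability and per-sample intensities; the same
  site set is rendered into all four engine dialects (MaxQuant, MS-Fragger,
  Spectronaut, DIA-NN) exactly as the converters' column presets expect.
  Canonical isoforms differ from the experimental sequences by drawn
  N-terminal offsets (extension for positive, deletion for negative), so
  residue remapping has closed-form known answers:
  canonical = experimental + offset.

All randomness flows from a single integer seed; identical parameters and
seed reproduce files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .formats_io import (DifferentialTable, RawQuantMatrix, SampleAnnotation,
                         SequenceSet, write_fasta)
from .ptm_harmonize import (DiannColumns, MaxQuantColumns, MSFraggerColumns,
                            SpectronautColumns)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSimParams:
    n_features: int = 500
    n_conditions: int = 2
    n_replicates: int = 4
    de_fraction: float = 0.1
    effect_size: float = 3.0      # log2 units
    noise_sd: float = 0.2         # log2 units
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValidationError(
                "at least 2 replicates are needed for the fixture t-test")
        if self.n_conditions < 2:
            raise ValidationError("at least 2 conditions are required")


@dataclass
class ProteomeFixture:
    matrix: RawQuantMatrix
    differential: DifferentialTable
    truth: pd.DataFrame     # feature_id, gene, is_de, direction


def gen_proteome(params: ProteomeSimParams) -> ProteomeFixture:
    """Simulate a quantified proteome plus its differential table.

    The differential comparison is condition 2 vs condition 1 (log2 fold
    change = mean difference of log2 intensities; significance from an
    equal-variance two-sample t-test). DE features receive the effect in
    condition 2 only, with random sign.
    """
    rng = np.random.default_rng(params.seed)
    nf, nc, nr = params.n_features, params.n_conditions, params.n_replicates

    feature_ids = [f"PROT{i:04d}" for i in range(nf)]
    genes = [f"GENE{i:04d}" for i in range(nf)]
    conditions = [f"cond{c + 1}" for c in range(nc)]
    annotations = [
        SampleAnnotation(sample_name=f"{cond}_r{r + 1}", condition=cond,
                         replicate=r + 1, display_order=c * nr + r)
        for c, cond in enumerate(conditions) for r in range(nr)]

    baseline = rng.uniform(22.0, 30.0, size=nf)
    n_de = int(round(params.de_fraction * nf))
    de_idx = rng.choice(nf, size=n_de, replace=False)
    direction = np.zeros(nf, dtype=int)
    direction[de_idx] = rng.choice([-1, 1], size=n_de)

    log2 = np.empty((nf, nc * nr))
    for c in range(nc):
        cols = slice(c * nr, (c + 1) * nr)
        effect = (direction * params.effect_size) if c == 1 else 0.0
        log2[:, cols] = (baseline + effect)[:, None] \
            + rng.normal(0.0, params.noise_sd, size=(nf, nr))

    intensities = np.power(2.0, log2)
    if params.missing_rate > 0:
        mask = rng.random(intensities.shape) < params.missing_rate
        intensities[mask] = np.nan

    df = pd.DataFrame(intensities, index=pd.Index(feature_ids,
                                                  name="feature_id"),
                      columns=[a.sample_name for a in annotations])
    matrix = RawQuantMatrix(intensities=df, samples=annotations)

    # fixture-internal differential statistics (cond2 vs cond1)
    a_cols = [a.sample_name for a in annotations if a.condition == "cond1"]
    b_cols = [a.sample_name for a in annotations if a.condition == "cond2"]
    log2_obs = np.log2(df)
    rows = []
    for i, fid in enumerate(feature_ids):
        va = log2_obs.loc[fid, a_cols].dropna().to_numpy()
        vb = log2_obs.loc[fid, b_cols].dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue
        t, p = stats.ttest_ind(vb, va, equal_var=True)
        rows.append({"primary_id": fid, "gene": genes[i],
                     "log2_fc": float(np.mean(vb) - np.mean(va)),
                     "neglog10_sig": float(-np.log10(p)),
                     "comparison": "cond2_vs_cond1"})
    differential = DifferentialTable(data=pd.DataFrame(rows))

    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "gene": genes,
        "is_de": direction != 0,
        "direction": direction,
    })
    return ProteomeFixture(matrix=matrix, differential=differential,
                           truth=truth)


# ---------------------------------------------------------------------------
# PTM generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTMSimParams:
    n_proteins: int = 8
    sites_per_protein: int = 3
    probability_range: tuple[float, float] = (0.4, 1.0)
    offset_choices: tuple[int, ...] = (0, 0, 3, 11)
    n_samples: int = 4
    min_length: int = 60
    max_length: int = 120
    modification: str = "Phospho"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.probability_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("probability_range must lie within [0, 1]")
        if self.min_length < 30 or self.max_length < self.min_length:
            raise ValidationError("sequence length bounds are implausible")


@dataclass
class PTMFixture:
    """One planted site set plus its four dialect renderings.

    ``truth`` columns: accession, position (experimental protein numbering),
    position_in_peptide, peptide, residue, probability, offset,
    canonical_position (experimental position + offset; <1 means the residue
    was deleted from the canonical isoform), modification, and one
    ``Intensity <sample>`` column per sample.
    """

    truth: pd.DataFrame
    exp_sequences: SequenceSet
    canonical_sequences: SequenceSet
    maxquant: pd.DataFrame
    msfragger: pd.DataFrame
    spectronaut: pd.DataFrame
    diann_quant: pd.DataFrame
    diann_prob: pd.DataFrame
    sample_names: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every rendering (TSV/FASTA) byte-deterministically."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        frames = {"truth": self.truth, "maxquant": self.maxquant,
                  "msfragger": self.msfragger,
                  "spectronaut": self.spectronaut,
                  "diann_quant": self.diann_quant,
                  "diann_prob": self.diann_prob}
        for name, frame in frames.items():
            p = out / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.4f")
            paths[name] = p
        for name, seqs in (("experimental", self.exp_sequences),
                           ("canonical", self.canonical_sequences)):
            p = out / f"{name}.fasta"
            write_fasta(seqs, p)
            paths[name] = p
        return paths


def _annotate_peptide(peptide: str, pos_in_pep: int, prob: float) -> str:
    """Render the probability-string grammar for a single-site peptide."""
    return (peptide[:pos_in_pep] + f"({prob:.4f})" + peptide[pos_in_pep:])


def gen_ptm(params: PTMSimParams) -> PTMFixture:
    """Plant PTM sites in random proteins and render all four dialects."""
    rng = np.random.default_rng(params.seed)
    aas = np.array(list(AMINO_ACIDS))
    sample_names = [f"S{i + 1}" for i in range(params.n_samples)]

    exp_seqs = SequenceSet()
    canon_seqs = SequenceSet()
    truth_rows = []
    for pi in range(params.n_proteins):
        acc = f"SIM{pi:03d}"
        length = int(rng.integers(params.min_length, params.max_length + 1))
        seq = list(rng.choice(aas, size=length))
        n_sites = params.sites_per_protein
        positions = sorted(
            int(p) + 10
            for p in rng.choice(length - 20, size=n_sites, replace=False))
        for pos in positions:          # 1-based positions in [11, length-10]
            seq[pos - 1] = str(rng.choice(list("STY")))
        exp_seq = "".join(seq)

        offset = int(rng.choice(params.offset_choices))
        if offset >= 0:
            prefix = "".join(rng.choice(aas, size=offset)) if offset else ""
            canon_seq = prefix + exp_seq
        else:
            canon_seq = exp_seq[-offset:]
        exp_seqs[acc] = exp_seq
        canon_seqs[acc] = canon_seq

        for pos in positions:
            start = max(1, pos - 7)
            end = min(length, pos + 7)
            peptide = exp_seq[start - 1:end]
            # keep fixtures unambiguous: the peptide must occur exactly once
            if exp_seq.count(peptide) != 1:
                continue
            lo, hi = params.probability_range
            prob = round(float(rng.uniform(lo, hi)), 4)
            quant = np.round(rng.lognormal(mean=18.0, sigma=1.0,
                                           size=params.n_samples), 1)
            row = {
                "accession": acc,
                "position": pos,
                "position_in_peptide": pos - start + 1,
                "peptide": peptide,
                "peptide_start": start,
                "residue": exp_seq[pos - 1],
                "probability": prob,
                "offset": offset,
                "canonical_position": pos + offset,
                "modification": params.modification,
            }
            for s, q in zip(sample_names, quant):
                row[f"Intensity {s}"] = float(q)
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)

    mq_cols = MaxQuantColumns()
    mf_cols = MSFraggerColumns()
    sn_cols = SpectronautColumns()
    dn_cols = DiannColumns()

    mq_rows, mf_rows, sn_rows, dq_rows, dp_rows = [], [], [], [], []
    for _, r in truth.iterrows():
        annotated = _annotate_peptide(r["peptide"],
                                      int(r["position_in_peptide"]),
                                      float(r["probability"]))
        quant = {s: r[f"Intensity {s}"] for s in sample_names}

        mq = {mq_cols.protein: r["accession"],
              mq_cols.position: int(r["position"]),
              mq_cols.amino_acid: r["residue"],
              mq_cols.position_in_peptide: int(r["position_in_peptide"]),
              mq_cols.localization_prob: float(r["probability"]),
              mq_cols.probability_string: annotated}
        for mult in (1, 2, 3):
            # only the singly-modified family carries the truth quantities;
            # higher multiplicities get distinct values so a wrong column
            # pick cannot pass unnoticed
            for s in sample_names:
                v = quant[s] if mult == 1 else round(quant[s] / (10 * mult), 1)
                mq[f"{mq_cols.intensity_prefix}{s}___{mult}"] = v
        mq_rows.append(mq)

        mf = {mf_cols.protein: r["accession"],
              mf_cols.modified_peptide: annotated,
              mf_cols.peptide_start: int(r["peptide_start"])}
        mf.update({f"{mf_cols.intensity_prefix}{s}": quant[s]
                   for s in sample_names})
        mf_rows.append(mf)

        sn = {sn_cols.protein: r["accession"],
              sn_cols.modified_peptide: annotated,
              sn_cols.modification: r["modification"]}
        sn.update({f"{sn_cols.intensity_prefix}{s}": quant[s]
                   for s in sample_names})
        sn_rows.append(sn)

        key = f"{r['accession']}_{int(r['position'])}"
        dq = {dn_cols.key: key, dn_cols.protein: r["accession"],
              dn_cols.peptide_start: int(r["peptide_start"])}
        dq.update({f"{dn_cols.intensity_prefix}{s}": quant[s]
                   for s in sample_names})
        dq_rows.append(dq)
        dp_rows.append({dn_cols.key: key, dn_cols.protein: r["accession"],
                        dn_cols.modified_sequence: annotated})

    return PTMFixture(
        truth=truth,
        exp_sequences=exp_seqs,
        canonical_sequences=canon_seqs,
        maxquant=pd.DataFrame(mq_rows),
        msfragger=pd.DataFrame(mf_rows),
        spectronaut=pd.DataFrame(sn_rows),
        diann_quant=pd.DataFrame(dq_rows),
        diann_prob=pd.DataFrame(dp_rows),
        sample_names=sample_names,
    )


def write_proteome(fixture: ProteomeFixture, out_dir: str | Path,
                   ) -> dict[str, Path]:
    """Write a proteome fixture as the TSV pair the import step consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw_path = out / "raw_matrix.tsv"
    raw = fixture.matrix.intensities.fillna(0.0)
    raw.to_csv(raw_path, sep="\t", float_format="%.6f")
    diff_path = out / "differential.tsv"
    fixture.differential.data.to_csv(diff_path, sep="\t", index=False,
                                     float_format="%.10g")
    truth_path = out / "truth.tsv"
    fixture.truth.to_csv(truth_path, sep="\t", index=False)
    return {"raw": raw_path, "differential": diff_path, "truth": truth_path}
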