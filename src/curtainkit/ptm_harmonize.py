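"""Harmonize PTM site output from four search engines into one site table.

MaxQuant site tables already carry the protein-level residue number of each
modified site; MS-Fragger, Spectronaut, and DIA-NN exports describe the site
only within the modified peptide, so the residue number within the protein
has to be reconstructed (from a reported peptide start, or by locating the
stripped peptide in the protein sequence). Each converter emits the same
:class:`PTMSiteRecord`, so downstream volcano classification, isoform
remapping, and database comparison are engine-agnostic.

Localization probabilities are annotated in-line in the modified-peptide
string using a single grammar: residue letters with ``(p)`` immediately after
a modified residue, e.g. ``AAS(0.98)PT(0.02)K``. Engine exports that use
square brackets are normalized to this grammar before parsing.

Column presets cover one representative export layout per engine; real-world
exports vary by version, so every preset is a dataclass whose column names
can be overridden.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, MergeError, ValidationError
from .formats_io import SequenceSet, representative_accession

# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class PTMSiteRecord:
    """One modification site, harmonized across engines.

    Positions are 1-based: ``position_in_peptide`` indexes the stripped
    peptide, ``position_in_protein`` the engine's protein sequence. ``valid``
    is cleared when a residue cross-check against the peptide or protein
    sequence fails; ``ambiguous`` is set when the peptide occurs more than
    once in the protein and the first occurrence was used.
    """

    accession: str
    peptide: str
    position_in_peptide: int
    position_in_protein: int
    residue: str
    localization_probability: float
    modification: str = "Phospho"
    quant: dict = field(default_factory=dict)
    protein_group: str | None = None
    ambiguous: bool = False
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValidationError(
                "localization probability must lie in [0, 1], got "
                f"{self.localization_probability}")

    def flag_invalid(self, reason: str) -> None:
        self.valid = False
        self.invalid_reason = reason


def valid_records(records: Iterable[PTMSiteRecord]) -> list[PTMSiteRecord]:
    return [r for r in records if r.valid]


def split_by_modification(
        records: Iterable[PTMSiteRecord]) -> dict[str, list[PTMSiteRecord]]:
    """Split a combined-export record list into per-modification lists."""
    out: dict[str, list[PTMSiteRecord]] = {}
    for r in records:
        out.setdefault(r.modification, []).append(r)
    return out


# ---------------------------------------------------------------------------
# probability-string grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityAnnotation:
    """Site probabilities read off an annotated peptide string."""

    peptide: str                                  # stripped sequence
    sites: tuple[tuple[int, str, float], ...]     # (1-based pos, residue, p)


_BRACKET_RE = re.compile(r"\[([0-9.eE+-]+)\]")


def normalize_probability_string(s: str) -> str:
    """Rewrite square-bracket probability annotations to the ``(p)`` grammar."""
    return _BRACKET_RE.sub(r"(\1)", s)


def parse_probability_string(s: str) -> ProbabilityAnnotation:
    """Parse ``AAS(0.98)PT(0.02)K`` into a stripped peptide plus sites.

    A ``(p)`` group annotates the residue letter immediately before it;
    positions refer to the stripped peptide and are strictly increasing by
    construction.
    """
    s = normalize_probability_string(s)
    peptide: list[str] = []
    sites: list[tuple[int, str, float]] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch.isalpha():
            peptide.append(ch.upper())
            i += 1
        elif ch == "(":
            if not peptide:
                raise ValidationError(
                    f"probability annotation before any residue in {s!r}")
            end = s.find(")", i)
            if end == -1:
                raise ValidationError(f"unbalanced parentheses in {s!r}")
            try:
                p = float(s[i + 1:end])
            except ValueError as exc:
                raise ValidationError(
                    f"unparseable probability {s[i + 1:end]!r} in {s!r}"
                ) from exc
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"probability {p} outside [0, 1] in {s!r}")
            sites.append((len(peptide), peptide[-1], p))
            i = end + 1
        else:
            raise ValidationError(f"unexpected character {ch!r} in {s!r}")
    return ProbabilityAnnotation(peptide="".join(peptide), sites=tuple(sites))


# ---------------------------------------------------------------------------
# column presets (one representative export layout per engine)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaxQuantColumns:
    protein: str = "Protein"
    position: str = "Position"
    amino_acid: str = "Amino acid"
    position_in_peptide: str = "Position in peptide"
    localization_prob: str = "Localization prob"
    probability_string: str = "Localization probabilities"
    intensity_prefix: str = "Intensity "


@dataclass(frozen=True)
class MSFraggerColumns:
    protein: str = "Protein ID"
    modified_peptide: str = "Modified Peptide"
    peptide_start: str = "Protein Start"
    intensity_prefix: str = "Intensity "


@dataclass(frozen=True)
class SpectronautColumns:
    protein: str = "PG.ProteinAccessions"
    modified_peptide: str = "EG.ModifiedPeptide"
    modification: str = "PTM.ModificationTitle"
    intensity_prefix: str = "Intensity "


@dataclass(frozen=True)
class DiannColumns:
    key: str = "Precursor.Id"
    protein: str = "Protein.Group"
    peptide_start: str = "Peptide.Start"
    modified_sequence: str = "Modified.Sequence"
    intensity_prefix: str = "Intensity "


def _load(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table, sep="\t")


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what}: missing columns {missing}")


def _intensity_columns(df: pd.DataFrame, prefix: str,
                       suffix: str = "") -> dict[str, str]:
    """Map sample name -> column for intensity columns with given affixes."""
    out = {}
    for c in df.columns:
        if c.startswith(prefix) and c.endswith(suffix):
            sample = c[len(prefix):len(c) - len(suffix) or None]
            out[sample] = c
    return out


def _cross_check(rec: PTMSiteRecord, sequences: SequenceSet | None) -> None:
    """Enforce peptide[pos]=residue and, when known, protein[pos]=residue."""
    pos = rec.position_in_peptide
    if not (1 <= pos <= len(rec.peptide)) or rec.peptide[pos - 1] != rec.residue:
        rec.flag_invalid("peptide residue mismatch")
        return
    if sequences is not None and rec.accession in sequences:
        prot = sequences[rec.accession]
        ppos = rec.position_in_protein
        if not (1 <= ppos <= len(prot)) or prot[ppos - 1] != rec.residue:
            rec.flag_invalid("protein residue mismatch")


# ---------------------------------------------------------------------------
# converters
# ---------------------------------------------------------------------------

def convert_maxquant(site_table: pd.DataFrame | str | Path,
                     multiplicity: int = 1,
                     modification: str = "Phospho",
                     columns: MaxQuantColumns = MaxQuantColumns(),
                     sequences: SequenceSet | None = None,
                     ) -> list[PTMSiteRecord]:
    """Convert a MaxQuant-style sites table (one row per site).

    ``multiplicity`` selects which ``___1/___2/___3`` intensity-column family
    to use (MaxQuant reports singly/doubly/triply modified peptide evidence
    separately; default 1). Low-probability sites are retained — class-I
    filtering is a separate, explicit step (:func:`filter_class1`).
    """
    if multiplicity not in (1, 2, 3):
        raise ConfigurationError("multiplicity must be 1, 2 or 3")
    df = _load(site_table)
    _require(df, [columns.protein, columns.position, columns.amino_acid,
                  columns.position_in_peptide, columns.localization_prob,
                  columns.probability_string], "MaxQuant site table")
    quant_cols = _intensity_columns(df, columns.intensity_prefix,
                                    f"___{multiplicity}")
    records = []
    for _, row in df.iterrows():
        ann = parse_probability_string(str(row[columns.probability_string]))
        group = str(row[columns.protein])
        rec = PTMSiteRecord(
            accession=representative_accession(group),
            peptide=ann.peptide,
            position_in_peptide=int(row[columns.position_in_peptide]),
            position_in_protein=int(row[columns.position]),
            residue=str(row[columns.amino_acid]).upper(),
            localization_probability=float(row[columns.localization_prob]),
            modification=modification,
            quant={s: float(row[c]) for s, c in quant_cols.items()},
            protein_group=group,
        )
        _cross_check(rec, sequences)
        records.append(rec)
    return records


def convert_msfragger(site_table: pd.DataFrame | str | Path,
                      sequences: SequenceSet,
                      modification: str = "Phospho",
                      columns: MSFraggerColumns = MSFraggerColumns(),
                      ) -> list[PTMSiteRecord]:
    """Convert an MS-Fragger-style PTM report.

    The export names the site only within the modified peptide; the protein
    residue number is reconstructed as ``peptide_start + in-peptide position
    - 1`` and cross-checked against the protein sequence. A record whose
    peptide does not match the protein at the reported start, or whose
    residue disagrees with the sequence, is flagged invalid, never silently
    kept.
    """
    df = _load(site_table)
    _require(df, [columns.protein, columns.modified_peptide,
                  columns.peptide_start], "MS-Fragger site table")
    quant_cols = _intensity_columns(df, columns.intensity_prefix)
    records = []
    for _, row in df.iterrows():
        ann = parse_probability_string(str(row[columns.modified_peptide]))
        group = str(row[columns.protein])
        acc = representative_accession(group)
        start = int(row[columns.peptide_start])
        quant = {s: float(row[c]) for s, c in quant_cols.items()}
        placed = (acc in sequences
                  and sequences[acc].find(ann.peptide, start - 1) == start - 1)
        for pos_pep, residue, prob in ann.sites:
            rec = PTMSiteRecord(
                accession=acc, peptide=ann.peptide,
                position_in_peptide=pos_pep,
                position_in_protein=start + pos_pep - 1,
                residue=residue, localization_probability=prob,
                modification=modification, quant=dict(quant),
                protein_group=group,
            )
            if not placed:
                rec.flag_invalid("peptide not found at reported start")
            else:
                _cross_check(rec, sequences)
            records.append(rec)
    return records


def convert_spectronaut(report: pd.DataFrame | str | Path,
                        sequences: SequenceSet,
                        columns: SpectronautColumns = SpectronautColumns(),
                        ) -> list[PTMSiteRecord]:
    """Convert a Spectronaut-style combined PTM report.

    The export gives the modified peptide with no protein residue number at
    all, so the stripped peptide is located in the protein by exact substring
    search. When it occurs more than once, the first occurrence is used and
    the record is marked ``ambiguous`` — downstream consumers must surface
    that flag. One combined file may mix modification types (e.g. Phospho and
    GlyGly rows); each record carries its row's modification label, and
    :func:`split_by_modification` separates them.
    """
    df = _load(report)
    _require(df, [columns.protein, columns.modified_peptide,
                  columns.modification], "Spectronaut report")
    quant_cols = _intensity_columns(df, columns.intensity_prefix)
    records = []
    for _, row in df.iterrows():
        ann = parse_probability_string(str(row[columns.modified_peptide]))
        group = str(row[columns.protein])
        acc = representative_accession(group)
        quant = {s: float(row[c]) for s, c in quant_cols.items()}
        seq = sequences.get(acc)
        occurrences = []
        if seq:
            k = seq.find(ann.peptide)
            while k != -1:
                occurrences.append(k)
                k = seq.find(ann.peptide, k + 1)
        for pos_pep, residue, prob in ann.sites:
            rec = PTMSiteRecord(
                accession=acc, peptide=ann.peptide,
                position_in_peptide=pos_pep,
                position_in_protein=(occurrences[0] + pos_pep
                                     if occurrences else 0),
                residue=residue, localization_probability=prob,
                modification=str(row[columns.modification]),
                quant=dict(quant), protein_group=group,
                ambiguous=len(occurrences) > 1,
            )
            if not occurrences:
                rec.flag_invalid("peptide not found in protein sequence")
            else:
                _cross_check(rec, sequences)
            records.append(rec)
    return records


@dataclass
class DiannMergeReport:
    """Keys present in only one of the two DIA-NN files (inner join drops
    them; they are reported, never imputed)."""

    unmatched_quant: list[str] = field(default_factory=list)
    unmatched_prob: list[str] = field(default_factory=list)


def convert_diann(quant_report: pd.DataFrame | str | Path,
                  prob_file: pd.DataFrame | str | Path,
                  modification: str = "Phospho",
                  columns: DiannColumns = DiannColumns(),
                  sequences: SequenceSet | None = None,
                  ) -> tuple[list[PTMSiteRecord], DiannMergeReport]:
    """Convert a DIA-NN-style export pair.

    DIA-NN ships quantities and site probabilities in separate files sharing
    a precursor key; they are inner-joined on that key. Zero overlapping keys
    is an error; a key whose protein group differs between the two files is
    an error (the merge would silently mis-assign sites).
    """
    qdf = _load(quant_report)
    pdf = _load(prob_file)
    _require(qdf, [columns.key, columns.protein, columns.peptide_start],
             "DIA-NN quant report")
    _require(pdf, [columns.key, columns.protein, columns.modified_sequence],
             "DIA-NN probability file")
    quant_cols = _intensity_columns(qdf, columns.intensity_prefix)

    qkeys = set(qdf[columns.key])
    pkeys = set(pdf[columns.key])
    shared = qkeys & pkeys
    if not shared:
        raise MergeError("DIA-NN quant and probability files share no keys")
    report = DiannMergeReport(
        unmatched_quant=sorted(qkeys - pkeys),
        unmatched_prob=sorted(pkeys - qkeys),
    )
    merged = qdf.merge(pdf, on=columns.key, how="inner",
                       suffixes=("", "__prob"))
    prot_prob = columns.protein + "__prob"
    conflicts = merged[merged[columns.protein] != merged[prot_prob]]
    if len(conflicts):
        keys = list(conflicts[columns.key])[:5]
        raise MergeError(
            f"conflicting protein accession between files for keys {keys}")

    records = []
    for _, row in merged.iterrows():
        ann = parse_probability_string(str(row[columns.modified_sequence]))
        group = str(row[columns.protein])
        acc = representative_accession(group)
        start = int(row[columns.peptide_start])
        quant = {s: float(row[c]) for s, c in quant_cols.items()}
        for pos_pep, residue, prob in ann.sites:
            rec = PTMSiteRecord(
                accession=acc, peptide=ann.peptide,
                position_in_peptide=pos_pep,
                position_in_protein=start + pos_pep - 1,
                residue=residue, localization_probability=prob,
                modification=modification, quant=dict(quant),
                protein_group=group,
            )
            _cross_check(rec, sequences)
            records.append(rec)
    return records, report


# ---------------------------------------------------------------------------
# class-I filter
# ---------------------------------------------------------------------------

def filter_class1(records: Iterable[PTMSiteRecord],
                  threshold: float = 0.75) -> list[PTMSiteRecord]:
    """Retain class-I (high-confidence) sites.

    A site qualifies when its localization probability is strictly greater
    than ``threshold`` (default 0.75, the conventional class-I cut)."""
    return [r for r in records if r.localization_probability > threshold]


# ---------------------------------------------------------------------------
# canonical TSV rendering of harmonized records
# ---------------------------------------------------------------------------

SITE_TSV_COLUMNS = ("accession", "peptide", "position_in_peptide",
                    "position_in_protein", "residue",
                    "localization_probability", "modification",
                    "ambiguous", "valid")


def records_to_frame(records: Iterable[PTMSiteRecord]) -> pd.DataFrame:
    records = list(records)
    rows = []
    sample_names: list[str] = []
    for r in records:
        for s in r.quant:
            if s not in sample_names:
                sample_names.append(s)
    for r in records:
        row = {
            "accession": r.accession, "peptide": r.peptide,
            "position_in_peptide": r.position_in_peptide,
            "position_in_protein": r.position_in_protein,
            "residue": r.residue,
            "localization_probability": r.localization_probability,
            "modification": r.modification,
            "ambiguous": r.ambiguous, "valid": r.valid,
        }
        for s in sample_names:
            row[f"Intensity {s}"] = r.quant.get(s)
        rows.append(row)
    cols = list(SITE_TSV_COLUMNS) + [f"Intensity {s}" for s in sample_names]
    return pd.DataFrame(rows, columns=cols)


def write_sites_tsv(records: Iterable[PTMSiteRecord],
                    path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[PTMSiteRecord]:
    df = pd.read_csv(path, sep="\t")
    _require(df, SITE_TSV_COLUMNS, "harmonized site table")
    prefix = "Intensity "
    quant_cols = {c[len(prefix):]: c for c in df.columns
                  if c.startswith(prefix)}
    out = []
    for _, row in df.iterrows():
        out.append(PTMSiteRecord(
            accession=str(row["accession"]), peptide=str(row["peptide"]),
            position_in_peptide=int(row["position_in_peptide"]),
            position_in_protein=int(row["position_in_protein"]),
            residue=str(row["residue"]),
            localization_probability=float(row["localization_probability"]),
            modification=str(row["modification"]),
            quant={s: float(row[c]) for s, c in quant_cols.items()
                   if pd.notna(row[c])},
            ambiguous=bool(row["ambiguous"]), valid=bool(row["valid"]),
        ))
    return out
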