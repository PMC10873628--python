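"""Readers and writers for every external table the toolkit touches.

All tabular inputs are UTF-8 tab-delimited text with a header row. Column
semantics are never guessed: an explicit :class:`ColumnMap` (the equivalent of
the interactive column-selection step in volcano tools) declares which column
holds what and on which scale, and the readers transform values into plot
space (log2 fold change on x, -log10 significance on y).

Conventions fixed here and used throughout the package:

* residue and site coordinates are 1-based and inclusive;
* an intensity of 0 in a quantitation matrix means "not detected" and is
  converted to missing before any log or correlation step;
* multi-accession protein groups ("P1;P2") keep the full group string as the
  feature id while the first accession acts as the representative for
  sequence/annotation lookup.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Residue alphabet accepted in sequence inputs: the 20 standard amino acids
#: plus ambiguity/rare codes.
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMap:
    """Declares which columns of a differential table hold what.

    Scales are declared, never inferred: ``fc_scale`` is ``"log2"`` or
    ``"linear"``; ``sig_scale`` is ``"neglog10"`` or ``"raw_p"``.
    """

    primary_id_col: str
    fc_col: str
    sig_col: str
    fc_scale: str = "log2"
    sig_scale: str = "neglog10"
    gene_col: str | None = None
    comparison_label: str = "comparison 1"

    def __post_init__(self) -> None:
        if self.fc_col == self.sig_col:
            raise ConfigurationError(
                "fc_col and sig_col must name different columns"
            )
        if self.fc_scale not in ("log2", "linear"):
            raise ConfigurationError(f"unknown fc_scale {self.fc_scale!r}")
        if self.sig_scale not in ("neglog10", "raw_p"):
            raise ConfigurationError(f"unknown sig_scale {self.sig_scale!r}")

    def to_dict(self) -> dict:
        return {
            "primary_id_col": self.primary_id_col,
            "fc_col": self.fc_col,
            "sig_col": self.sig_col,
            "fc_scale": self.fc_scale,
            "sig_scale": self.sig_scale,
            "gene_col": self.gene_col,
            "comparison_label": self.comparison_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMap":
        return cls(**{k: d[k] for k in (
            "primary_id_col", "fc_col", "sig_col", "fc_scale", "sig_scale",
            "gene_col", "comparison_label") if k in d})


@dataclass(frozen=True)
class SampleAnnotation:
    """Assignment of one matrix column to a condition/replicate slot."""

    sample_name: str
    condition: str
    replicate: int
    display_order: int = 0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate}"
            )

    def to_dict(self) -> dict:
        return {
            "sample_name": self.sample_name,
            "condition": self.condition,
            "replicate": self.replicate,
            "display_order": self.display_order,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleAnnotation":
        return cls(sample_name=d["sample_name"], condition=d["condition"],
                   replicate=int(d["replicate"]),
                   display_order=int(d.get("display_order", 0)))


def validate_annotations(annotations: Iterable[SampleAnnotation]) -> None:
    """(condition, replicate) pairs must be unique across annotations."""
    seen: Counter = Counter((a.condition, a.replicate) for a in annotations)
    dupes = [k for k, n in seen.items() if n > 1]
    if dupes:
        raise ValidationError(
            f"duplicate (condition, replicate) assignments: {dupes}"
        )


@dataclass
class ReadReport:
    """Bookkeeping for a read: every source row is retained or counted here."""

    rows_read: int = 0
    rows_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    def drop(self, reason: str, n: int = 1) -> None:
        self.rows_dropped += n
        self.drop_reasons[reason] += n


@dataclass
class DifferentialTable:
    """One row per feature in volcano space.

    ``data`` columns: ``primary_id``, ``gene``, ``log2_fc``, ``neglog10_sig``,
    ``comparison``. ``primary_id`` is unique within a comparison.
    """

    data: pd.DataFrame
    report: ReadReport = field(default_factory=ReadReport)

    @property
    def ids(self) -> list[str]:
        return list(self.data["primary_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RawQuantMatrix:
    """Feature x sample intensity matrix; NaN marks a missing value."""

    intensities: pd.DataFrame          # index: feature ids, columns: samples
    samples: list[SampleAnnotation]

    def __post_init__(self) -> None:
        validate_annotations(self.samples)
        names = [a.sample_name for a in self.samples]
        if list(self.intensities.columns) != names:
            raise ValidationError(
                "matrix columns do not match sample annotations in order"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    def condition_samples(self) -> dict[str, list[str]]:
        """Sample names grouped by condition, in display order."""
        out: dict[str, list[str]] = {}
        for a in sorted(self.samples, key=lambda a: a.display_order):
            out.setdefault(a.condition, []).append(a.sample_name)
        return out


class SequenceSet(dict):
    """Mapping accession -> uppercase amino-acid sequence."""

    def __setitem__(self, key: str, value: str) -> None:
        value = value.upper()
        if not value:
            raise FormatError(f"empty sequence for accession {key!r}")
        bad = set(value) - SEQUENCE_ALPHABET
        if bad:
            raise FormatError(
                f"sequence for {key!r} contains invalid residues {sorted(bad)}"
            )
        super().__setitem__(key, value)


@dataclass(frozen=True)
class PTMDatabaseEntry:
    accession: str
    position: int          # 1-based
    residue: str           # one-letter code
    modification: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"PTM database positions are 1-based; got {self.position}"
            )
        if len(self.residue) != 1 or not self.residue.isalpha():
            raise ValidationError(
                f"residue must be a single letter, got {self.residue!r}"
            )


@dataclass
class PTMDatabase:
    """A reference or custom PTM site collection, e.g. an imported
    PhosphoSitePlus/PLMD-style dump."""

    source_name: str
    entries: list[PTMDatabaseEntry] = field(default_factory=list)

    def for_accession(self, accession: str) -> list[PTMDatabaseEntry]:
        return [e for e in self.entries if e.accession == accession]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ProjectMetadata:
    """PRIDE-style free-text project descriptors carried into the session."""

    title: str = ""
    description: str = ""
    sample_processing_protocol: str = ""
    data_processing_protocol: str = ""
    instrument: str = ""
    authors: str = ""
    affiliations: str = ""

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "description": self.description,
            "sample_processing_protocol": self.sample_processing_protocol,
            "data_processing_protocol": self.data_processing_protocol,
            "instrument": self.instrument,
            "authors": self.authors,
            "affiliations": self.affiliations,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProjectMetadata":
        return cls(**{k: d.get(k, "") for k in cls.__dataclass_fields__})


def representative_accession(group_id: str) -> str:
    """First accession of a semicolon-separated protein group."""
    return group_id.split(";")[0].strip()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse as tab-delimited text: {exc}"
                          ) from exc
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str | None],
                     path: str | Path) -> None:
    for c in cols:
        if c is not None and c not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column {c!r} not found in header "
                f"(available: {list(df.columns)})"
            )


def read_differential(path: str | Path, colmap: ColumnMap) -> DifferentialTable:
    """Read a differential-analysis table and transform it to volcano space.

    Fold changes on a ``linear`` scale become log2(FC); significance on a
    ``raw_p`` scale becomes -log10(p). Rows whose transform inputs are
    unparseable or have no finite transform (FC <= 0 under linear, p <= 0 or
    p > 1 under raw_p, negative -log10 values) are dropped and counted in the
    returned report rather than clamped — a clamped point would sit at a
    fabricated spot on the volcano.
    """
    df = _read_tsv(path)
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: no data rows")
    _require_columns(df, [colmap.primary_id_col, colmap.fc_col,
                          colmap.sig_col, colmap.gene_col], path)

    report = ReadReport(rows_read=len(df))
    fc = pd.to_numeric(df[colmap.fc_col], errors="coerce")
    sig = pd.to_numeric(df[colmap.sig_col], errors="coerce")

    bad_parse = fc.isna() | sig.isna()

    if colmap.fc_scale == "linear":
        bad_fc = fc <= 0
        log2_fc = np.log2(fc.where(fc > 0))
    else:
        bad_fc = pd.Series(False, index=df.index)
        log2_fc = fc

    if colmap.sig_scale == "raw_p":
        bad_sig = (sig <= 0) | (sig > 1)
        neglog10 = -np.log10(sig.where((sig > 0) & (sig <= 1)))
    else:
        bad_sig = sig < 0
        neglog10 = sig.where(sig >= 0)

    nonfinite = (~np.isfinite(log2_fc.fillna(np.inf))
                 | ~np.isfinite(neglog10.fillna(np.inf)))

    # disjoint drop categories, priority: unparseable > bad FC > bad sig
    report.drop("unparseable_value", int(bad_parse.sum()))
    report.drop("nonpositive_fc", int((bad_fc & ~bad_parse).sum()))
    report.drop("invalid_significance",
                int((bad_sig & ~bad_parse & ~bad_fc).sum()))
    report.drop("nonfinite_after_transform", int(
        (nonfinite & ~bad_parse & ~bad_fc & ~bad_sig).sum()))

    keep = ~(bad_parse | bad_fc | bad_sig | nonfinite)

    out = pd.DataFrame({
        "primary_id": df[colmap.primary_id_col].astype(str),
        "gene": (df[colmap.gene_col].astype(str)
                 if colmap.gene_col else ""),
        "log2_fc": log2_fc.astype(float),
        "neglog10_sig": neglog10.astype(float),
        "comparison": colmap.comparison_label,
    })[keep].reset_index(drop=True)

    dup = out["primary_id"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate primary ids, keeping first",
                       path, int(dup.sum()))
        report.drop("duplicate_id", int(dup.sum()))
        out = out[~dup].reset_index(drop=True)

    return DifferentialTable(data=out, report=report)


def read_raw(path: str | Path, id_col: str,
             annotations: list[SampleAnnotation]) -> RawQuantMatrix:
    """Read a search-engine quantitation table into a feature x sample matrix.

    Columns are assembled in annotation ``display_order``; zeros become
    missing (the MaxQuant convention for non-detected features); duplicate
    feature ids keep the first occurrence with a logged warning.
    """
    validate_annotations(annotations)
    df = _read_tsv(path)
    _require_columns(df, [id_col], path)
    ordered = sorted(annotations, key=lambda a: a.display_order)
    _require_columns(df, [a.sample_name for a in ordered], path)

    ids = df[id_col].astype(str)
    dup = ids.duplicated(keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate feature ids, keeping first",
                       path, int(dup.sum()))
        df = df[~dup]
        ids = ids[~dup]

    mat = df[[a.sample_name for a in ordered]].apply(
        pd.to_numeric, errors="coerce")
    if (mat < 0).any().any():
        raise FormatError(f"{path}: negative intensity values present")
    mat = mat.where(mat != 0)          # 0 == not detected
    mat.index = pd.Index(ids, name="feature_id")
    return RawQuantMatrix(intensities=mat, samples=ordered)


def write_raw(matrix: RawQuantMatrix, path: str | Path,
              id_col: str = "feature_id") -> None:
    """Write a quant matrix back to TSV (missing rendered as 0)."""
    out = matrix.intensities.fillna(0.0)
    out.index.name = id_col
    out.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA; accession = first whitespace token, with UniProt
    ``db|ACC|name`` headers reduced to ``ACC``. Duplicate accessions error."""
    seqs = SequenceSet()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        token = record.id.split()[0] if record.id else ""
        if not token:
            raise FormatError(f"{path}: record {n} has a malformed header")
        parts = token.split("|")
        acc = parts[1] if len(parts) >= 3 and parts[1] else token
        if acc in seqs:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seqs[acc] = str(record.seq)
    if n == 0:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in seqs:
            fh.write(f">{acc}\n{seqs[acc]}\n")


CUSTOM_DB_COLUMNS = ("accession", "position", "residue", "modification")


def read_custom_ptm_db(path: str | Path, source_name: str) -> PTMDatabase:
    """Read a tabulated custom PTM database.

    The dialect is fixed: a TSV with header columns ``accession``,
    ``position`` (1-based integer), ``residue`` (one letter),
    ``modification``. An empty (0-row) file yields a valid empty database.
    """
    df = _read_tsv(path)
    _require_columns(df, CUSTOM_DB_COLUMNS, path)
    entries = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path} row {i + 1}: position {row['position']!r} "
                "is not an integer") from exc
        try:
            entries.append(PTMDatabaseEntry(
                accession=str(row["accession"]),
                position=pos,
                residue=str(row["residue"]).upper(),
                modification=str(row["modification"]),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    return PTMDatabase(source_name=source_name, entries=entries)


def write_custom_ptm_db(db: PTMDatabase, path: str | Path) -> None:
    rows = [{"accession": e.accession, "position": e.position,
             "residue": e.residue, "modification": e.modification}
            for e in db.entries]
    pd.DataFrame(rows, columns=list(CUSTOM_DB_COLUMNS)).to_csv(
        path, sep="\t", index=False)
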