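"""Pluggable, offline-first protein annotation providers.

The interactive ancestor of this toolkit decorates each selected protein
with live lookups (UniProt metadata, interactor lists, expression
profiles). Here that surface is a provider interface with one shipped
implementation backed by a local TSV fixture, so every pipeline — and the
entire test suite — runs with zero network access. A live web provider is
an extension point, not a dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

from .errors import FormatError, ValidationError
from .diffexp import CutoffConfig, SignificanceClass, classify
from .formats_io import DifferentialTable


@dataclass(frozen=True)
class DomainSpan:
    name: str
    start: int       # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid domain span {self.name} [{self.start}, {self.end}]")


@dataclass
class AnnotationRecord:
    accession: str
    gene: str = ""
    protein_name: str = ""
    function: str = ""
    subcellular_location: str = ""
    domains: list[DomainSpan] = field(default_factory=list)
    interactors: list[str] = field(default_factory=list)
    provider: str = ""


class AnnotationProvider(Protocol):
    name: str

    def lookup(self, accession: str) -> AnnotationRecord | None: ...


FIXTURE_COLUMNS = ("accession", "gene", "protein_name", "function",
                   "subcellular_location", "domains", "interactors")


class FixtureAnnotationProvider:
    """Annotation provider backed by a local TSV.

    Columns: accession, gene, protein_name, function, subcellular_location,
    domains (``name:start-end`` entries joined by ``;``), interactors
    (accessions joined by ``;``).
    """

    def __init__(self, path: str | Path, name: str = "fixture") -> None:
        self.name = name
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        self._records: dict[str, AnnotationRecord] = {}
        for _, row in df.iterrows():
            domains = []
            for token in filter(None, row["domains"].split(";")):
                dname, _, span = token.rpartition(":")
                lo, _, hi = span.partition("-")
                domains.append(DomainSpan(name=dname, start=int(lo),
                                          end=int(hi)))
            interactors = [t for t in row["interactors"].split(";") if t]
            self._records[row["accession"]] = AnnotationRecord(
                accession=row["accession"], gene=row["gene"],
                protein_name=row["protein_name"], function=row["function"],
                subcellular_location=row["subcellular_location"],
                domains=domains, interactors=interactors,
                provider=self.name)

    def lookup(self, accession: str) -> AnnotationRecord | None:
        return self._records.get(accession)


@dataclass
class AnnotationResult:
    records: dict[str, AnnotationRecord]
    missing: list[str]
    errors: list[str] = field(default_factory=list)


def annotate(ids: Iterable[str],
             provider: AnnotationProvider) -> AnnotationResult:
    """Look each id up once (duplicates collapsed); ids the provider does
    not know are reported as missing, never fabricated. A provider failure
    on one id yields partial results plus an error report."""
    seen: list[str] = []
    for i in ids:
        if i not in seen:
            seen.append(i)
    records: dict[str, AnnotationRecord] = {}
    missing: list[str] = []
    errors: list[str] = []
    for acc in seen:
        try:
            rec = provider.lookup(acc)
        except Exception as exc:  # provider failure must not kill the batch
            errors.append(f"{acc}: {exc}")
            continue
        if rec is None:
            missing.append(acc)
        else:
            records[acc] = rec
    return AnnotationResult(records=records, missing=missing, errors=errors)


class InteractorClass(str, Enum):
    """Display class of a known interactor relative to the loaded dataset:
    red/up, blue/down, pink/present-but-unchanged, black/not detected."""

    UP = "up"
    DOWN = "down"
    PRESENT_UNCHANGED = "present_unchanged"
    ABSENT = "absent"


def interactor_overlay(record: AnnotationRecord, table: DifferentialTable,
                       cutoffs: CutoffConfig) -> dict[str, InteractorClass]:
    """Classify each known interactor of a protein against the dataset.

    An interactor absent from the table is ABSENT; one classified S_C is UP
    or DOWN by fold-change sign; anything else detected is
    PRESENT_UNCHANGED. The classes partition the interactor list."""
    by_id = table.data.set_index("primary_id")
    out: dict[str, InteractorClass] = {}
    for acc in record.interactors:
        if acc not in by_id.index:
            out[acc] = InteractorClass.ABSENT
            continue
        row = by_id.loc[acc]
        cls = classify(float(row["log2_fc"]), float(row["neglog10_sig"]),
                       cutoffs)
        if cls == SignificanceClass.S_C:
            out[acc] = (InteractorClass.UP if float(row["log2_fc"]) > 0
                        else InteractorClass.DOWN)
        else:
            out[acc] = InteractorClass.PRESENT_UNCHANGED
    return out
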