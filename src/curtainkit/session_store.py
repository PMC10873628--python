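"""Persist and restore a complete analysis as a versioned JSON document.

A session document captures everything needed to re-open an analysis
exactly as it was left: project metadata, the column map, sample
annotations, cutoffs, saved selection sets, style, and the data payloads
(differential table, raw matrix, harmonized PTM sites). Payloads are
embedded by default so a document is fully self-contained and portable;
lightweight documents may reference payload files by relative path instead.

Contract: ``load_session(save_session(state)) == state`` field for field.
Field ordering in the serialized file is deterministic (sorted keys) so
documents diff cleanly; two saves of the same state differ only in
``session_id`` (a fresh UUID4 per save — the opaque token behind a share
link). Top-level keys this build does not understand are preserved verbatim
on round trip, and a document declaring an unsupported ``schema_version``
refuses to load rather than silently dropping content.
"""

from __future__ import annotations

import json
import math
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .errors import FormatError, UnsupportedSchemaError, ValidationError
from .formats_io import (ColumnMap, DifferentialTable, ProjectMetadata,
                         RawQuantMatrix, SampleAnnotation)
from .diffexp import CutoffConfig, SelectionSet, StyleOptions
from .ptm_harmonize import PTMSiteRecord

SCHEMA_VERSION = "1.0"
SUPPORTED_VERSIONS = frozenset({"1.0"})

_KNOWN_KEYS = frozenset({
    "schema_version", "session_id", "metadata", "colmap", "annotations",
    "cutoffs", "selections", "style", "differential", "raw_matrix",
    "ptm_sites",
})


@dataclass
class AnalysisState:
    """Everything the toolkit knows about one analysis."""

    metadata: ProjectMetadata = field(default_factory=ProjectMetadata)
    colmap: ColumnMap | None = None
    annotations: list[SampleAnnotation] = field(default_factory=list)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    selections: list[SelectionSet] = field(default_factory=list)
    style: StyleOptions = field(default_factory=StyleOptions)
    differential: DifferentialTable | None = None
    raw_matrix: RawQuantMatrix | None = None
    ptm_sites: list[PTMSiteRecord] = field(default_factory=list)
    extras: dict = field(default_factory=dict)   # unknown fields, preserved

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisState):
            return NotImplemented
        if (self.metadata, self.colmap, self.annotations, self.cutoffs,
                self.extras) != (other.metadata, other.colmap,
                                 other.annotations, other.cutoffs,
                                 other.extras):
            return False
        if [s.to_dict() for s in self.selections] != \
                [s.to_dict() for s in other.selections]:
            return False
        if self.style.to_dict() != other.style.to_dict():
            return False
        if (self.differential is None) != (other.differential is None):
            return False
        if self.differential is not None and \
                not self.differential.data.equals(other.differential.data):
            return False
        if (self.raw_matrix is None) != (other.raw_matrix is None):
            return False
        if self.raw_matrix is not None:
            if self.raw_matrix.samples != other.raw_matrix.samples:
                return False
            if not self.raw_matrix.intensities.equals(
                    other.raw_matrix.intensities):
                return False
        return self.ptm_sites == other.ptm_sites


@dataclass
class SessionDocument:
    """A materialized session: plain JSON-ready dict plus helpers."""

    data: dict

    @property
    def session_id(self) -> str:
        return self.data["session_id"]

    @property
    def schema_version(self) -> str:
        return self.data["schema_version"]

    def dumps(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2,
                          ensure_ascii=False, allow_nan=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _num(x: float) -> float | None:
    """JSON has no NaN; encode missing as null."""
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def _differential_to_dict(table: DifferentialTable) -> dict:
    df = table.data
    return {
        "columns": list(df.columns),
        "rows": [[_num(v) if isinstance(v, float) else v for v in row]
                 for row in df.itertuples(index=False, name=None)],
    }


def _differential_from_dict(d: Mapping) -> DifferentialTable:
    df = pd.DataFrame(d["rows"], columns=d["columns"])
    for col in ("log2_fc", "neglog10_sig"):
        df[col] = df[col].astype(float)
    return DifferentialTable(data=df)


def _matrix_to_dict(m: RawQuantMatrix) -> dict:
    return {
        "feature_ids": list(m.intensities.index),
        "samples": [a.to_dict() for a in m.samples],
        "intensities": [[_num(float(v)) for v in row]
                        for row in m.intensities.itertuples(index=False,
                                                            name=None)],
    }


def _matrix_from_dict(d: Mapping) -> RawQuantMatrix:
    samples = [SampleAnnotation.from_dict(a) for a in d["samples"]]
    df = pd.DataFrame(d["intensities"], index=d["feature_ids"],
                      columns=[a.sample_name for a in samples], dtype=float)
    df.index.name = "feature_id"
    return RawQuantMatrix(intensities=df, samples=samples)


def _site_to_dict(r: PTMSiteRecord) -> dict:
    return {
        "accession": r.accession, "peptide": r.peptide,
        "position_in_peptide": r.position_in_peptide,
        "position_in_protein": r.position_in_protein,
        "residue": r.residue,
        "localization_probability": r.localization_probability,
        "modification": r.modification,
        "quant": {k: _num(v) for k, v in r.quant.items()},
        "protein_group": r.protein_group,
        "ambiguous": r.ambiguous, "valid": r.valid,
        "invalid_reason": r.invalid_reason,
    }


def _site_from_dict(d: Mapping) -> PTMSiteRecord:
    return PTMSiteRecord(
        accession=d["accession"], peptide=d["peptide"],
        position_in_peptide=int(d["position_in_peptide"]),
        position_in_protein=int(d["position_in_protein"]),
        residue=d["residue"],
        localization_probability=float(d["localization_probability"]),
        modification=d["modification"],
        quant=dict(d.get("quant", {})),
        protein_group=d.get("protein_group"),
        ambiguous=bool(d.get("ambiguous", False)),
        valid=bool(d.get("valid", True)),
        invalid_reason=d.get("invalid_reason"),
    )


# ---------------------------------------------------------------------------
# save / load
# ---------------------------------------------------------------------------

def save_session(state: AnalysisState, path: str | Path | None = None,
                 session_id: str | None = None) -> SessionDocument:
    """Serialize an analysis state into a session document.

    A fresh UUID4 ``session_id`` is generated per save unless one is passed
    explicitly (tests and deterministic pipelines may pin it). Selections
    referencing unknown ids are permitted — the reference report lives with
    the volcano builder — but the state must serialize completely.
    """
    data: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session_id or str(uuid.uuid4()),
        "metadata": state.metadata.to_dict(),
        "colmap": state.colmap.to_dict() if state.colmap else None,
        "annotations": [a.to_dict() for a in state.annotations],
        "cutoffs": state.cutoffs.to_dict(),
        "selections": [s.to_dict() for s in state.selections],
        "style": state.style.to_dict(),
        "differential": (_differential_to_dict(state.differential)
                         if state.differential is not None else None),
        "raw_matrix": (_matrix_to_dict(state.raw_matrix)
                       if state.raw_matrix is not None else None),
        "ptm_sites": [_site_to_dict(r) for r in state.ptm_sites],
    }
    overlap = _KNOWN_KEYS & set(state.extras)
    if overlap:
        raise ValidationError(
            f"extras would shadow reserved session keys: {sorted(overlap)}")
    data.update(state.extras)
    try:
        doc = SessionDocument(data=json.loads(
            json.dumps(data, sort_keys=True, allow_nan=False)))
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"state contains an unserializable payload: "
                              f"{exc}") from exc
    if path is not None:
        doc.write(path)
    return doc


def load_session(source: str | Path | Mapping | SessionDocument,
                 ) -> AnalysisState:
    """Restore an analysis state from a session document or file.

    Refuses documents with an unsupported ``schema_version`` — a silent
    partial load would corrupt a shared analysis. Unknown top-level keys are
    kept in ``state.extras`` and re-emitted verbatim by the next save.
    """
    if isinstance(source, SessionDocument):
        data = source.data
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        text = Path(source).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"{source}: malformed session JSON at line {exc.lineno} "
                f"column {exc.colno} (char {exc.pos})") from exc
    version = data.get("schema_version")
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedSchemaError(
            f"session declares schema_version {version!r}; this build "
            f"supports {sorted(SUPPORTED_VERSIONS)}")

    extras = {k: v for k, v in data.items() if k not in _KNOWN_KEYS}
    return AnalysisState(
        metadata=ProjectMetadata.from_dict(data.get("metadata") or {}),
        colmap=(ColumnMap.from_dict(data["colmap"])
                if data.get("colmap") else None),
        annotations=[SampleAnnotation.from_dict(a)
                     for a in data.get("annotations", [])],
        cutoffs=CutoffConfig.from_dict(
            data.get("cutoffs") or CutoffConfig().to_dict()),
        selections=[SelectionSet.from_dict(s)
                    for s in data.get("selections", [])],
        style=StyleOptions.from_dict(data.get("style") or {}),
        differential=(_differential_from_dict(data["differential"])
                      if data.get("differential") else None),
        raw_matrix=(_matrix_from_dict(data["raw_matrix"])
                    if data.get("raw_matrix") else None),
        ptm_sites=[_site_from_dict(r) for r in data.get("ptm_sites", [])],
        extras=extras,
    )
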