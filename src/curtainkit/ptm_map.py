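"""Remap PTM residue numbers between splice variants and compare against
reference databases.

Search engines number modified residues on whatever splice variant the
search database reported, which frequently disagrees with the canonical
isoform used by public PTM resources and the literature (an N-terminal
extension of 11 residues shifts every site number by 11). This module
aligns the experimental isoform to the canonical sequence with a global
(Needleman-Wunsch) affine-gap aligner and remaps site numbers through the
resulting position map.

The aligner is deliberately deterministic: among co-optimal alignments it
returns the one whose move sequence, read from the N-terminus, is
lexicographically first under the order diagonal < up < left ("up" consumes
an experimental residue against a gap, "left" a canonical residue). Scores
use BLOSUM62 with gap open -10 (first gap residue) and gap extend -0.5
(each further residue) by default.

Site comparison against one or more PTM databases assigns each canonical
position one of four display classes: BOTH (purple in the original UI:
experimental site confirmed by a database), EXPERIMENT_ONLY (red),
DATABASE_ONLY (blue), or SELECTED (green, the user's current peptide, which
overrides the others); significantly changed sites additionally carry an
asterisk-style flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .formats_io import PTMDatabase
from .diffexp import SignificanceClass

# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring scheme.

    ``matrix`` names a standard substitution matrix (BLOSUM62 by default);
    setting ``match``/``mismatch`` instead selects a simple two-value scheme.
    Gap penalties follow the open/extend convention: the first residue of a
    gap costs ``gap_open``, each additional one ``gap_extend``; both must be
    non-positive.
    """

    matrix: str | None = "BLOSUM62"
    match: float | None = None
    mismatch: float | None = None
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("gap penalties must be <= 0 "
                                  "(score convention)")
        if self.matrix is None and (self.match is None
                                    or self.mismatch is None):
            raise ValidationError(
                "either a matrix name or match/mismatch scores are required")


_MATRIX_CACHE: dict[str, object] = {}


def _scorer(params: AlignmentParams):
    """Return a substitution-score function letter x letter -> float."""
    if params.match is not None and params.mismatch is not None:
        match, mismatch = params.match, params.mismatch

        def simple(a: str, b: str) -> float:
            return match if a == b else mismatch
        return simple

    name = params.matrix
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    mat = _MATRIX_CACHE[name]
    alphabet = set(mat.alphabet)

    def lookup(a: str, b: str) -> float:
        a = a if a in alphabet else "X"
        b = b if b in alphabet else "X"
        return float(mat[a, b])
    return lookup


@dataclass
class AlignedPair:
    exp_position: int        # 1-based
    canonical_position: int  # 1-based
    exp_residue: str
    canonical_residue: str


@dataclass
class AlignmentMap:
    """Position-to-position correspondence between an experimental isoform
    and the canonical sequence; the mapping is strictly monotone increasing
    over the aligned pairs. Identity fraction = identical pairs / aligned
    pairs."""

    exp_seq: str
    canonical_seq: str
    pairs: list[AlignedPair]
    score: float
    exp_to_canonical: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.exp_to_canonical = {
            p.exp_position: p.canonical_position for p in self.pairs}

    @property
    def identity_fraction(self) -> float:
        if not self.pairs:
            return 0.0
        same = sum(p.exp_residue == p.canonical_residue for p in self.pairs)
        return same / len(self.pairs)

    def blocks(self) -> list[tuple[int, int, int]]:
        """Contiguous aligned runs as (exp_start, canonical_start, length)."""
        out: list[tuple[int, int, int]] = []
        for p in self.pairs:
            if out and p.exp_position == out[-1][0] + out[-1][2] \
                    and p.canonical_position == out[-1][1] + out[-1][2]:
                out[-1] = (out[-1][0], out[-1][1], out[-1][2] + 1)
            else:
                out.append((p.exp_position, p.canonical_position, 1))
        return out


# move/state encoding for the affine-gap DP
_MATCH, _UP, _LEFT = 0, 1, 2


def _suffix_tables(a: str, b: str, params: AlignmentParams):
    """Suffix DP: S[state][i][j] = best score of aligning a[i:] with b[j:]
    given that the previous emitted column was of type ``state``."""
    n, m = len(a), len(b)
    sub = _scorer(params)
    go, ge = params.gap_open, params.gap_extend
    NEG = float("-inf")
    S = np.full((3, n + 1, m + 1), NEG)
    S[:, n, m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            for state in (_MATCH, _UP, _LEFT):
                best = NEG
                if i < n and j < m:
                    v = sub(a[i], b[j]) + S[_MATCH, i + 1, j + 1]
                    if v > best:
                        best = v
                if i < n:
                    v = (ge if state == _UP else go) + S[_UP, i + 1, j]
                    if v > best:
                        best = v
                if j < m:
                    v = (ge if state == _LEFT else go) + S[_LEFT, i, j + 1]
                    if v > best:
                        best = v
                S[state, i, j] = best
    return S


def align_isoforms(exp_seq: str, canonical_seq: str,
                   params: AlignmentParams | None = None) -> AlignmentMap:
    """Optimal global alignment of the experimental isoform against the
    canonical sequence, with deterministic tie-breaking (diagonal > up >
    left at every choice point, reading from the N-terminus). Identical
    sequences short-circuit to the identity map.
    """
    if not exp_seq or not canonical_seq:
        raise ValidationError("both sequences must be non-empty")
    params = params or AlignmentParams()
    if exp_seq == canonical_seq:
        sub = _scorer(params)
        pairs = [AlignedPair(i + 1, i + 1, c, c)
                 for i, c in enumerate(exp_seq)]
        score = float(sum(sub(c, c) for c in exp_seq))
        return AlignmentMap(exp_seq=exp_seq, canonical_seq=canonical_seq,
                            pairs=pairs, score=score)

    a, b = exp_seq, canonical_seq
    n, m = len(a), len(b)
    sub = _scorer(params)
    go, ge = params.gap_open, params.gap_extend
    S = _suffix_tables(a, b, params)

    # greedy forward walk: at each step take the most-preferred move that
    # still achieves the optimal remaining score
    pairs: list[AlignedPair] = []
    i = j = 0
    state = _MATCH      # before any column, a gap would pay the open cost
    score = S[_MATCH, 0, 0]
    remaining = score
    while i < n or j < m:
        if i < n and j < m and \
                sub(a[i], b[j]) + S[_MATCH, i + 1, j + 1] == remaining:
            pairs.append(AlignedPair(i + 1, j + 1, a[i], b[j]))
            remaining -= sub(a[i], b[j])
            i, j, state = i + 1, j + 1, _MATCH
        elif i < n and (ge if state == _UP else go) \
                + S[_UP, i + 1, j] == remaining:
            remaining -= ge if state == _UP else go
            i, state = i + 1, _UP
        else:
            remaining -= ge if state == _LEFT else go
            j, state = j, _LEFT
            j += 1
    return AlignmentMap(exp_seq=exp_seq, canonical_seq=canonical_seq,
                        pairs=pairs, score=float(score))


class _Unaligned:
    """Sentinel: the experimental residue sits opposite a gap."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNALIGNED"

    def __bool__(self) -> bool:
        return False


UNALIGNED = _Unaligned()


@dataclass
class RemappedPosition:
    """Remap outcome with both residues retained for mismatch auditing."""

    exp_position: int
    canonical_position: int | None
    exp_residue: str
    canonical_residue: str | None

    @property
    def unaligned(self) -> bool:
        return self.canonical_position is None

    @property
    def residue_match(self) -> bool:
        return (self.canonical_residue is not None
                and self.exp_residue == self.canonical_residue)


def remap_site_detail(amap: AlignmentMap,
                      exp_position: int) -> RemappedPosition:
    if not 1 <= exp_position <= len(amap.exp_seq):
        raise ValidationError(
            f"position {exp_position} outside experimental sequence "
            f"(length {len(amap.exp_seq)})")
    canon = amap.exp_to_canonical.get(exp_position)
    return RemappedPosition(
        exp_position=exp_position,
        canonical_position=canon,
        exp_residue=amap.exp_seq[exp_position - 1],
        canonical_residue=(amap.canonical_seq[canon - 1]
                           if canon is not None else None))


def remap_site(amap: AlignmentMap, exp_position: int):
    """Canonical residue number for an experimental position, or
    :data:`UNALIGNED` when that residue aligns to a gap."""
    detail = remap_site_detail(amap, exp_position)
    return UNALIGNED if detail.unaligned else detail.canonical_position


# ---------------------------------------------------------------------------
# database comparison
# ---------------------------------------------------------------------------

class SiteClass(str, Enum):
    BOTH = "BOTH"                      # experimental site confirmed by a db
    EXPERIMENT_ONLY = "EXPERIMENT_ONLY"
    DATABASE_ONLY = "DATABASE_ONLY"
    SELECTED = "SELECTED"              # user's current site, overrides all


@dataclass
class RemappedSite:
    """An experimental PTM site carried into canonical numbering; the
    pre-remap (experimental) position is retained for display."""

    canonical_position: int
    experimental_position: int
    residue: str
    modification: str
    accession: str = ""


@dataclass
class SiteComparisonEntry:
    canonical_position: int
    site_class: SiteClass
    significant: bool = False
    db_presence: dict = field(default_factory=dict)   # source -> bool
    experimental_position: int | None = None
    residue_conflict: bool = False


def compare_sites(experimental: Sequence[RemappedSite],
                  databases: Sequence[PTMDatabase],
                  accession: str | None = None,
                  selected_positions: Iterable[int] = (),
                  significance: Mapping[int, SignificanceClass] | None = None,
                  ) -> dict[int, SiteComparisonEntry]:
    """Classify every canonical position carrying an experimental or
    database site.

    A position is BOTH when an experimental site coincides with a database
    entry at the same position with the same modification type; a coinciding
    entry whose residue letter disagrees (possible after remapping across
    isoforms) demotes the position to EXPERIMENT_ONLY with
    ``residue_conflict`` set. Selected positions override to SELECTED.
    ``significant`` is set for positions whose significance class is S_C
    (the asterisk flag, independent of the color class).
    """
    significance = significance or {}
    selected = set(selected_positions)
    if accession is None and experimental:
        accs = {s.accession for s in experimental if s.accession}
        if len(accs) > 1:
            raise ValidationError(
                f"experimental sites span multiple accessions {sorted(accs)};"
                " pass accession= explicitly")
        accession = next(iter(accs), None)

    exp_by_pos: dict[int, RemappedSite] = {}
    for s in experimental:
        exp_by_pos[s.canonical_position] = s

    db_by_pos: dict[int, dict[str, list]] = {}
    for db in databases:
        entries = (db.for_accession(accession) if accession is not None
                   else db.entries)
        for e in entries:
            db_by_pos.setdefault(e.position, {}).setdefault(
                db.source_name, []).append(e)

    out: dict[int, SiteComparisonEntry] = {}
    for pos in sorted(set(exp_by_pos) | set(db_by_pos)):
        exp = exp_by_pos.get(pos)
        sources = db_by_pos.get(pos, {})
        presence = {db.source_name: db.source_name in sources
                    for db in databases}
        conflict = False
        if exp is None:
            cls = SiteClass.DATABASE_ONLY
        else:
            matching = [e for es in sources.values() for e in es
                        if e.modification == exp.modification]
            if matching:
                if any(e.residue == exp.residue for e in matching):
                    cls = SiteClass.BOTH
                else:
                    cls = SiteClass.EXPERIMENT_ONLY
                    conflict = True
            else:
                cls = SiteClass.EXPERIMENT_ONLY
        if pos in selected:
            cls = SiteClass.SELECTED
        out[pos] = SiteComparisonEntry(
            canonical_position=pos, site_class=cls,
            significant=(significance.get(pos) == SignificanceClass.S_C),
            db_presence=presence,
            experimental_position=(exp.experimental_position
                                   if exp else None),
            residue_conflict=conflict)
    return out


def comparison_to_frame(
        comparison: Mapping[int, SiteComparisonEntry]) -> pd.DataFrame:
    rows = []
    for pos in sorted(comparison):
        e = comparison[pos]
        row = {"canonical_position": e.canonical_position,
               "class": e.site_class.value,
               "significant": e.significant,
               "experimental_position": e.experimental_position,
               "residue_conflict": e.residue_conflict}
        for src, present in e.db_presence.items():
            row[f"in_{src}"] = present
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif windows
# ---------------------------------------------------------------------------

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
PAD_CHAR = "_"


@dataclass(frozen=True)
class MotifWindow:
    """Sequence window of length 2*halfwidth+1 centered on a site; positions
    beyond the sequence ends are padded. The 15-mer default (halfwidth 7) is
    the convention of the major kinase-substrate resources."""

    window: str
    halfwidth: int

    def __post_init__(self) -> None:
        if len(self.window) != 2 * self.halfwidth + 1:
            raise ValidationError(
                f"window {self.window!r} is not {2 * self.halfwidth + 1} "
                "characters")

    @property
    def center(self) -> str:
        return self.window[self.halfwidth]


def extract_window(seq: str, position: int, halfwidth: int = 7,
                   pad: str = PAD_CHAR) -> MotifWindow:
    """Extract the +-halfwidth residue window around a 1-based position,
    padding beyond the sequence ends."""
    if not 1 <= position <= len(seq):
        raise ValidationError(
            f"position {position} outside sequence of length {len(seq)}")
    if halfwidth < 0:
        raise ValidationError("halfwidth must be >= 0")
    lo = position - 1 - halfwidth
    hi = position - 1 + halfwidth
    chars = [seq[k] if 0 <= k < len(seq) else pad
             for k in range(lo, hi + 1)]
    return MotifWindow(window="".join(chars), halfwidth=halfwidth)


def position_frequency_matrix(
        windows: Sequence[MotifWindow]) -> pd.DataFrame:
    """Residue counts per window column: a (20 residues + pad) x window-length
    matrix whose column sums all equal the number of windows; the tabulated
    form consumed by sequence-logo renderers."""
    if not windows:
        raise ValidationError("at least one window is required")
    length = len(windows[0].window)
    if any(len(w.window) != length for w in windows):
        raise ValidationError("windows have mixed lengths")
    rows = list(STANDARD_RESIDUES) + [PAD_CHAR]
    counts = pd.DataFrame(0, index=rows,
                          columns=[str(c) for c in range(length)])
    index = {r: k for k, r in enumerate(rows)}
    arr = counts.to_numpy()
    for w in windows:
        for col, ch in enumerate(w.window):
            if ch not in index:
                raise ValidationError(
                    f"unexpected character {ch!r} in window {w.window!r}")
            arr[index[ch], col] += 1
    return pd.DataFrame(arr, index=rows, columns=counts.columns)
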