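"""Volcano-space classification, selection sets, and replicate summaries.

Every feature of a differential table lives at (log2 fold change, -log10
significance). Two user cutoffs — drawn as dotted vertical/horizontal lines
on the plot — partition the plane into four classes:

* ``S_C``   significant and changed (beyond both lines),
* ``S_NC``  significant but fold change within the vertical lines,
* ``NS_C``  large fold change but not significant,
* ``NS_NC`` neither.

Cutoff comparisons are strict (``>``): a point sitting exactly on a dotted
line belongs to the less-extreme class, which keeps classification
deterministic and the lines unambiguous boundary markers.

The default cutoffs (|log2 FC| > 0.6, -log10 p > 1.301, i.e. p < 0.05) are
presets, not universal truths; both are always explicit parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .formats_io import DifferentialTable, RawQuantMatrix


class SignificanceClass(str, Enum):
    """Four-way volcano partition."""

    NS_NC = "NS_NC"   # nonsignificant, no change
    S_NC = "S_NC"     # significant, no change
    NS_C = "NS_C"     # nonsignificant, changed
    S_C = "S_C"       # significant and changed


@dataclass(frozen=True)
class CutoffConfig:
    """Volcano cutoffs: ``fc_cutoff`` in log2 units, ``sig_cutoff`` in
    -log10 units; both non-negative and finite."""

    fc_cutoff: float = 0.6
    sig_cutoff: float = 1.301

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fc_cutoff)
                and math.isfinite(self.sig_cutoff)):
            raise ValidationError("cutoffs must be finite")
        if self.fc_cutoff < 0 or self.sig_cutoff < 0:
            raise ValidationError("cutoffs must be non-negative")

    def to_dict(self) -> dict:
        return {"fc_cutoff": self.fc_cutoff, "sig_cutoff": self.sig_cutoff}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CutoffConfig":
        return cls(fc_cutoff=float(d["fc_cutoff"]),
                   sig_cutoff=float(d["sig_cutoff"]))


def classify(log2_fc: float, neglog10_sig: float,
             cutoffs: CutoffConfig) -> SignificanceClass:
    """Classify one volcano point. Strict comparisons; symmetric in the sign
    of the fold change."""
    significant = neglog10_sig > cutoffs.sig_cutoff
    changed = abs(log2_fc) > cutoffs.fc_cutoff
    if significant and changed:
        return SignificanceClass.S_C
    if significant:
        return SignificanceClass.S_NC
    if changed:
        return SignificanceClass.NS_C
    return SignificanceClass.NS_NC


def classify_table(table: DifferentialTable,
                   cutoffs: CutoffConfig) -> pd.Series:
    """Vectorized classification of a whole table; index = primary_id."""
    fc = table.data["log2_fc"].to_numpy()
    sig = table.data["neglog10_sig"].to_numpy()
    significant = sig > cutoffs.sig_cutoff
    changed = np.abs(fc) > cutoffs.fc_cutoff
    out = np.where(
        significant & changed, SignificanceClass.S_C.value,
        np.where(significant, SignificanceClass.S_NC.value,
                 np.where(changed, SignificanceClass.NS_C.value,
                          SignificanceClass.NS_NC.value)))
    return pd.Series([SignificanceClass(v) for v in out],
                     index=table.data["primary_id"].to_numpy(), name="class")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass
class SelectionSet:
    """A named, ordered, colored set of feature ids saved for follow-up."""

    name: str
    member_ids: list[str] = field(default_factory=list)
    color: str = "#f5c142"

    def __post_init__(self) -> None:
        deduped: list[str] = []
        seen = set()
        for m in self.member_ids:
            if m not in seen:
                seen.add(m)
                deduped.append(m)
        self.member_ids = deduped

    def to_dict(self) -> dict:
        return {"name": self.name, "member_ids": list(self.member_ids),
                "color": self.color}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SelectionSet":
        return cls(name=d["name"], member_ids=list(d["member_ids"]),
                   color=d.get("color", "#f5c142"))


def batch_select(table: DifferentialTable, gene_list: Iterable[str],
                 name: str, color: str = "#f5c142",
                 ) -> tuple[SelectionSet, list[str]]:
    """Build a selection from a gene list (e.g. a pathway or disease panel).

    Matching is case-insensitive exact match on the gene field — human and
    mouse symbols differ only by case, and substring matching is too noisy.
    Returns the set plus the list of query genes that matched nothing.
    """
    genes = [g for g in gene_list if g]
    if not genes:
        raise ConfigurationError("batch_select requires a non-empty gene list")
    wanted: dict[str, str] = {}
    for g in genes:
        wanted.setdefault(g.lower(), g)
    lower = table.data["gene"].astype(str).str.lower()
    members: list[str] = []
    hit: set[str] = set()
    for pid, g in zip(table.data["primary_id"], lower):
        if g in wanted:
            members.append(pid)
            hit.add(g)
    unmatched = [orig for low, orig in wanted.items() if low not in hit]
    return SelectionSet(name=name, member_ids=members, color=color), unmatched


# ---------------------------------------------------------------------------
# per-feature replicate summaries
# ---------------------------------------------------------------------------

@dataclass
class ConditionStats:
    """Replicate-level values and their mean/SD/SEM within one condition.

    SD is the sample standard deviation (n-1 denominator); SEM = SD/sqrt(n).
    With a single replicate both are reported as 0 with
    ``insufficient_replicates`` set, so pilot data still renders."""

    replicate_values: list[float]
    mean: float
    sd: float
    sem: float
    n: int
    insufficient_replicates: bool = False


@dataclass
class FeatureSummary:
    feature_id: str
    conditions: dict[str, ConditionStats]


def summarize_feature(matrix: RawQuantMatrix, feature_id: str,
                      ) -> FeatureSummary:
    """Per-condition replicate values, mean, SD and SEM for one feature.

    Missing values are excluded; ``n`` counts non-missing replicates only.
    The raw value lists double as violin-plot input.
    """
    if feature_id not in matrix.intensities.index:
        raise ConfigurationError(f"unknown feature id {feature_id!r}")
    row = matrix.intensities.loc[feature_id]
    out: dict[str, ConditionStats] = {}
    for condition, sample_names in matrix.condition_samples().items():
        values = [float(row[s]) for s in sample_names if pd.notna(row[s])]
        n = len(values)
        if n == 0:
            out[condition] = ConditionStats([], math.nan, 0.0, 0.0, 0, True)
        elif n == 1:
            out[condition] = ConditionStats(values, values[0], 0.0, 0.0, 1,
                                            insufficient_replicates=True)
        else:
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1))
            out[condition] = ConditionStats(values, mean, sd,
                                            sd / math.sqrt(n), n)
    return FeatureSummary(feature_id=feature_id, conditions=out)


# ---------------------------------------------------------------------------
# volcano figure data
# ---------------------------------------------------------------------------

#: Default class colors and a color-blind-safe (Okabe-Ito derived) alternative.
PALETTES: dict[str, dict[SignificanceClass, str]] = {
    "default": {
        SignificanceClass.NS_NC: "#a8a8a8",
        SignificanceClass.S_NC: "#2b6cb0",
        SignificanceClass.NS_C: "#b07f2b",
        SignificanceClass.S_C: "#2f855a",
    },
    "colorblind": {
        SignificanceClass.NS_NC: "#999999",
        SignificanceClass.S_NC: "#0072B2",
        SignificanceClass.NS_C: "#E69F00",
        SignificanceClass.S_C: "#009E73",
    },
}


@dataclass
class StyleOptions:
    palette: str = "default"
    class_colors: dict = field(default_factory=dict)   # overrides
    font_family: str = "DejaVu Sans"
    fade_alpha: float = 0.15
    x_bounds: tuple[float, float] | None = None
    y_bounds: tuple[float, float] | None = None

    def color_for(self, cls: SignificanceClass) -> str:
        if cls.value in self.class_colors:
            return self.class_colors[cls.value]
        if self.palette not in PALETTES:
            raise ConfigurationError(f"unknown palette {self.palette!r}")
        return PALETTES[self.palette][cls]

    def to_dict(self) -> dict:
        return {"palette": self.palette,
                "class_colors": dict(self.class_colors),
                "font_family": self.font_family,
                "fade_alpha": self.fade_alpha,
                "x_bounds": list(self.x_bounds) if self.x_bounds else None,
                "y_bounds": list(self.y_bounds) if self.y_bounds else None}

    @classmethod
    def from_dict(cls, d: Mapping) -> "StyleOptions":
        return cls(palette=d.get("palette", "default"),
                   class_colors=dict(d.get("class_colors", {})),
                   font_family=d.get("font_family", "DejaVu Sans"),
                   fade_alpha=float(d.get("fade_alpha", 0.15)),
                   x_bounds=tuple(d["x_bounds"]) if d.get("x_bounds") else None,
                   y_bounds=tuple(d["y_bounds"]) if d.get("y_bounds") else None)


@dataclass
class VolcanoPoint:
    primary_id: str
    x: float          # log2 fold change
    y: float          # -log10 significance
    label: str


@dataclass
class VolcanoFigureData:
    """Plot-ready volcano content: base series split by class, selection
    overlays (which duplicate, never remove, base points), dotted cutoff
    line positions, and ids to fade when hiding non-selected features."""

    base_series: dict[SignificanceClass, list[VolcanoPoint]]
    overlays: list[tuple[str, str, list[VolcanoPoint]]]  # (name, color, pts)
    cutoff_lines: dict[str, list[float]]
    faded_ids: list[str]
    missing_selection_members: dict[str, list[str]]
    style: StyleOptions


def build_volcano(table: DifferentialTable, cutoffs: CutoffConfig,
                  selections: Iterable[SelectionSet] = (),
                  style: StyleOptions | None = None,
                  fade_unselected: bool = False) -> VolcanoFigureData:
    """Assemble everything a volcano rendering needs.

    Every table row lands in exactly one base series; selection members are
    rendered again as overlays in the set's color; with ``fade_unselected``
    all non-selected base points are listed for fading. Selection members
    absent from the table are reported, not fatal.
    """
    if len(table) == 0:
        raise ValidationError("cannot build a volcano from an empty table")
    style = style or StyleOptions()
    classes = classify_table(table, cutoffs)
    base: dict[SignificanceClass, list[VolcanoPoint]] = {
        c: [] for c in SignificanceClass}
    by_id: dict[str, VolcanoPoint] = {}
    for row, cls in zip(table.data.itertuples(index=False), classes):
        pt = VolcanoPoint(primary_id=row.primary_id, x=row.log2_fc,
                          y=row.neglog10_sig,
                          label=row.gene or row.primary_id)
        base[cls].append(pt)
        by_id[row.primary_id] = pt

    overlays = []
    missing: dict[str, list[str]] = {}
    selected_ids: set[str] = set()
    for sel in selections:
        pts = []
        absent = []
        for m in sel.member_ids:
            if m in by_id:
                pts.append(by_id[m])
                selected_ids.add(m)
            else:
                absent.append(m)
        overlays.append((sel.name, sel.color, pts))
        if absent:
            missing[sel.name] = absent

    faded: list[str] = []
    if fade_unselected and selected_ids:
        faded = [pid for pid in by_id if pid not in selected_ids]

    return VolcanoFigureData(
        base_series=base, overlays=overlays,
        cutoff_lines={"vertical": [-cutoffs.fc_cutoff, cutoffs.fc_cutoff],
                      "horizontal": [cutoffs.sig_cutoff]},
        faded_ids=faded, missing_selection_members=missing, style=style)


def volcano_to_dict(fig: VolcanoFigureData) -> dict:
    """Serialize figure data to plain JSON-ready structures."""
    return {
        "base_series": {
            cls.value: [{"id": p.primary_id, "x": p.x, "y": p.y,
                         "label": p.label} for p in pts]
            for cls, pts in fig.base_series.items()},
        "overlays": [{"name": n, "color": c,
                      "points": [{"id": p.primary_id, "x": p.x, "y": p.y,
                                  "label": p.label} for p in pts]}
                     for n, c, pts in fig.overlays],
        "cutoff_lines": fig.cutoff_lines,
        "faded_ids": fig.faded_ids,
        "missing_selection_members": fig.missing_selection_members,
        "style": fig.style.to_dict(),
    }


def render_volcano_svg(fig: VolcanoFigureData, path: str) -> None:
    """Static SVG rendering of the volcano (matplotlib backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    faded = set(fig.faded_ids)
    f, ax = plt.subplots(figsize=(6, 5))
    for cls, pts in fig.base_series.items():
        if not pts:
            continue
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        alphas = [fig.style.fade_alpha if p.primary_id in faded else 0.8
                  for p in pts]
        ax.scatter(xs, ys, s=12, c=fig.style.color_for(cls), alpha=alphas,
                   label=cls.value, linewidths=0)
    for name, color, pts in fig.overlays:
        if pts:
            ax.scatter([p.x for p in pts], [p.y for p in pts], s=30,
                       facecolors="none", edgecolors=color, label=name)
    for x in fig.cutoff_lines["vertical"]:
        ax.axvline(x, linestyle=":", color="#555555", linewidth=1)
    for y in fig.cutoff_lines["horizontal"]:
        ax.axhline(y, linestyle=":", color="#555555", linewidth=1)
    if fig.style.x_bounds:
        ax.set_xlim(*fig.style.x_bounds)
    if fig.style.y_bounds:
        ax.set_ylim(*fig.style.y_bounds)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 significance")
    ax.legend(fontsize=7, frameon=False)
    f.tight_layout()
    f.savefig(path, format="svg")
    plt.close(f)
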