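"""Data-quality views: per-sample ranked profile plots and the global
sample-sample correlation matrix.

Profile plots show, per sample, all non-missing log2 intensities sorted in
descending order against their rank — well-behaved replicates share the same
curve, and a highlighted protein should sit at a similar rank everywhere.
The correlation matrix summarizes replicate agreement in one view; in clean
label-free experiments replicate-replicate coefficients typically land
around 0.98.

Both views work on log2-transformed intensities by default: raw MS
intensities span orders of magnitude and a handful of abundant proteins
would otherwise dominate Pearson's r. Missing values are handled
pairwise-complete per sample pair; a pair with fewer than three shared
features has no meaningful coefficient and is reported as undefined (NaN),
never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import RawQuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class HighlightMarker:
    feature_id: str
    rank: int
    log2_value: float


@dataclass
class ProfileSeries:
    """Descending-ranked log2 intensities per sample plus highlight markers.

    ``per_sample[s]`` is a DataFrame with columns (rank, feature_id,
    log2_intensity), rank 1 = most intense, rows = non-missing features of
    that sample only. ``highlights[fid][s]`` marks where a highlighted
    feature sits in sample ``s`` (absent when the feature is missing there).
    """

    per_sample: dict[str, pd.DataFrame]
    highlights: dict[str, dict[str, HighlightMarker]]
    missing_highlights: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)


def profile_data(matrix: RawQuantMatrix,
                 highlight_ids: list[str] | None = None) -> ProfileSeries:
    """Rank each sample's non-missing log2 intensities in descending order.

    Highlight ids absent from every sample are reported in
    ``missing_highlights``; an all-missing sample yields an empty series and
    a warning.
    """
    if matrix.intensities.empty:
        raise ValidationError("profile_data requires a non-empty matrix")
    highlight_ids = highlight_ids or []
    per_sample: dict[str, pd.DataFrame] = {}
    highlights: dict[str, dict[str, HighlightMarker]] = {
        h: {} for h in highlight_ids}
    empty = []
    for ann in matrix.samples:
        s = ann.sample_name
        col = matrix.intensities[s].dropna()
        if col.empty:
            empty.append(s)
            logger.warning("sample %s has no detected features", s)
            per_sample[s] = pd.DataFrame(
                columns=["rank", "feature_id", "log2_intensity"])
            continue
        log2 = np.log2(col).sort_values(ascending=False)
        df = pd.DataFrame({
            "rank": np.arange(1, len(log2) + 1),
            "feature_id": log2.index,
            "log2_intensity": log2.to_numpy(),
        })
        per_sample[s] = df
        if highlight_ids:
            rank_of = pd.Series(df["rank"].to_numpy(),
                                index=df["feature_id"])
            val_of = pd.Series(df["log2_intensity"].to_numpy(),
                               index=df["feature_id"])
            for h in highlight_ids:
                if h in rank_of.index:
                    highlights[h][s] = HighlightMarker(
                        feature_id=h, rank=int(rank_of[h]),
                        log2_value=float(val_of[h]))
    missing = [h for h in highlight_ids if not highlights[h]]
    return ProfileSeries(per_sample=per_sample, highlights=highlights,
                         missing_highlights=missing, empty_samples=empty)


@dataclass
class CorrMatrix:
    """Sample x sample correlation coefficients; NaN marks an undefined
    coefficient (fewer than ``min_shared`` pairwise-complete features)."""

    values: pd.DataFrame
    method: str

    def is_symmetric(self) -> bool:
        v = self.values.to_numpy()
        both = np.isfinite(v) & np.isfinite(v.T)
        return bool(np.allclose(v[both], v.T[both]) and
                    (np.isfinite(v) == np.isfinite(v.T)).all())


def correlation_matrix(matrix: RawQuantMatrix, method: str = "pearson",
                       log_transform: bool = True,
                       min_shared: int = 3) -> CorrMatrix:
    """Pairwise sample correlation over features detected in both samples.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``; values are
    log2-transformed first unless ``log_transform`` is disabled. The
    diagonal is 1 by definition; pairs sharing fewer than ``min_shared``
    features are undefined (NaN).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if len(matrix.samples) < 2:
        raise ValidationError("correlation requires at least 2 samples")
    data = matrix.intensities
    if log_transform:
        data = np.log2(data)
    corr = data.corr(method=method, min_periods=min_shared)
    # pandas also needs nonzero variance; keep its NaN for constant columns.
    for s in corr.index:
        corr.loc[s, s] = 1.0
    label = method + ("_log2" if log_transform else "_raw")
    return CorrMatrix(values=corr, method=label)


def mean_replicate_correlation(cm: CorrMatrix,
                               matrix: RawQuantMatrix) -> float:
    """Mean off-diagonal coefficient among samples of the same condition."""
    vals = []
    anns = matrix.samples
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            if anns[i].condition == anns[j].condition:
                v = cm.values.iloc[i, j]
                if pd.notna(v):
                    vals.append(float(v))
    return float(np.mean(vals)) if vals else math.nan
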