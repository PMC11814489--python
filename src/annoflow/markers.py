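"""Modality-aware marker relevance scoring.

Two strategies select the markers worth displaying when comparing two cell
populations:

* **low-dimensional** modalities (e.g. ADT surface proteins, tens of
  features): rank every feature directly by the absolute difference in mean
  normalized expression between the two selections;
* **high-dimensional** modalities (e.g. RNA, thousands of features): first
  pre-select candidates per annotation group — the top-k most upregulated
  features by the *median pairwise Cohen's d* of each group against every
  other group — then rank that candidate union by absolute mean difference.

Dispatch is on feature count (strictly more than ``high_dim_threshold``
features triggers pre-selection), or bypassed entirely for matrices the user
has already filtered to markers of interest.

The single most important numerical convention in this package is the
Cohen's d denominator: ``sqrt((s1^2 + s2^2) / 2)`` with *population*
variances (denominator n).  Two zero-variance groups with different means
give ±inf (sign of the mean difference); with equal means, 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import (
    ExpressionMatrix,
    LinkProvenance,
    MultimodalDataset,
    NodeProvenance,
    Selection,
)
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


def cohens_d(x, y) -> float:
    """Standardized mean difference between two samples (x minus y).

    ``d = (mean(x) - mean(y)) / sqrt((var(x) + var(y)) / 2)`` with population
    variances.  If both variances are zero: 0 when the means are equal,
    otherwise ±inf with the sign of the difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("cohens_d: empty input vector")
    diff = x.mean() - y.mean()
    denom = np.sqrt((x.var() + y.var()) / 2.0)
    if denom == 0.0:
        if diff == 0.0:
            return 0.0
        return float(np.sign(diff) * np.inf)
    return float(diff / denom)


@dataclass
class EffectTable:
    """All pairwise Cohen's d values per feature plus per-group medians.

    ``pairwise`` has shape (n_groups, n_groups, n_features) with NaN on the
    diagonal; ``pairwise[a, b, f]`` is d of group a minus group b on feature
    f, so the array is antisymmetric in its first two axes.  ``median``
    (n_groups, n_features) holds each group's median d against all other
    groups; ``top_k[g]`` lists up to k features with the largest strictly
    positive median d, ties broken by feature id ascending.
    """

    groups: list[str]
    features: list[str]
    pairwise: np.ndarray
    median: np.ndarray
    top_k: dict[str, list[str]]
    k: int

    def pairwise_d(self, feature: str, group_a: str, group_b: str) -> float:
        f = self.features.index(feature)
        return float(self.pairwise[self.groups.index(group_a), self.groups.index(group_b), f])

    def median_d(self, feature: str, group: str) -> float:
        return float(self.median[self.groups.index(group), self.features.index(feature)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (feature, group, median_d) table."""
        rows = [
            (f, g, self.median[gi, fi])
            for gi, g in enumerate(self.groups)
            for fi, f in enumerate(self.features)
        ]
        return pd.DataFrame(rows, columns=["feature", "group", "median_d"])


def _group_stats(values, indices: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-group feature means and population variances, sparse-aware."""
    n_groups = len(indices)
    n_features = values.shape[1]
    means = np.empty((n_groups, n_features))
    variances = np.empty((n_groups, n_features))
    for gi, idx in enumerate(indices):
        sub = values[idx]
        if sp.issparse(sub):
            m = np.asarray(sub.mean(axis=0)).ravel()
            msq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
        else:
            m = sub.mean(axis=0)
            msq = np.mean(sub * sub, axis=0)
        means[gi] = m
        # clip: msq - m^2 can go microscopically negative in floating point
        variances[gi] = np.maximum(msq - m * m, 0.0)
    return means, variances


def _median_with_inf(block: np.ndarray) -> np.ndarray:
    """Median along axis 0 with ±inf ordered beyond all finite values.

    Even count: arithmetic mean of the two middle values; a (-inf, +inf)
    middle pair is defined as 0 (balanced separation in both directions).
    """
    a = np.sort(block, axis=0)
    m = a.shape[0]
    if m % 2 == 1:
        return a[m // 2]
    lo, hi = a[m // 2 - 1], a[m // 2]
    with np.errstate(invalid="ignore"):
        mid = (lo + hi) / 2.0
    return np.where(np.isneginf(lo) & np.isposinf(hi), 0.0, mid)


def effect_table(
    matrix: ExpressionMatrix,
    labels: Sequence[str],
    k: int = 10,
    min_group_size: int = 2,
) -> EffectTable:
    """Score every feature's expression difference across every group pair.

    For each feature and each ordered pair of groups (a, b), compute Cohen's
    d of a minus b; summarize per (feature, group) as the median of that
    group's d against all other groups; report each group's top ``k`` most
    upregulated features — those with the largest strictly positive median d
    (k defaults to 10).

    Groups with fewer than two cells have undefined variance and are dropped
    with a warning; at least two eligible groups are required.
    """
    labels = np.asarray([str(x) for x in labels], dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValidationError(
            f"effect_table: {len(labels)} labels for {matrix.n_cells} cells"
        )
    groups = sorted(pd.unique(labels))
    indices = {g: np.flatnonzero(labels == g) for g in groups}
    small = [g for g in groups if len(indices[g]) < min_group_size]
    if small:
        logger.warning(
            "effect_table: dropping %d group(s) with < %d cells: %s",
            len(small), min_group_size, small,
        )
        groups = [g for g in groups if g not in small]
    if len(groups) < 2:
        raise ValidationError(
            f"effect_table: need >= 2 groups with >= {min_group_size} cells, "
            f"have {len(groups)}"
        )

    means, variances = _group_stats(matrix.values, [indices[g] for g in groups])
    n_groups, n_features = means.shape

    diff = means[:, None, :] - means[None, :, :]            # (a, b, f)
    denom = np.sqrt((variances[:, None, :] + variances[None, :, :]) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pairwise = diff / denom
    zero_denom = denom == 0.0
    # zero pooled spread: equal means -> 0, else +-inf by sign of difference
    pairwise = np.where(zero_denom & (diff == 0.0), 0.0, pairwise)
    pairwise = np.where(zero_denom & (diff > 0.0), np.inf, pairwise)
    pairwise = np.where(zero_denom & (diff < 0.0), -np.inf, pairwise)
    di = np.arange(n_groups)
    pairwise[di, di, :] = np.nan

    median = np.empty((n_groups, n_features))
    others = np.arange(n_groups)
    for gi in range(n_groups):
        block = pairwise[gi, others != gi, :]               # (n_groups-1, f)
        median[gi] = _median_with_inf(block)

    feature_ids = [str(f) for f in matrix.feature_ids]
    top_k: dict[str, list[str]] = {}
    for gi, g in enumerate(groups):
        pos = [(float(median[gi, fi]), feature_ids[fi]) for fi in range(n_features)
               if median[gi, fi] > 0]
        pos.sort(key=lambda t: (-t[0], t[1]))
        top_k[g] = [fid for _, fid in pos[:k]]

    return EffectTable(
        groups=list(groups), features=feature_ids,
        pairwise=pairwise, median=median, top_k=top_k, k=k,
    )


def annotation_effect_table(
    dataset: MultimodalDataset, modality: str, annotation: str, k: int = 10
) -> EffectTable:
    """Effect table of one modality grouped by one annotation column, cached.

    Cells carrying the missing token are excluded from the grouping.  The
    result is cached on the dataset keyed by (modality, annotation, k).
    """
    key = ("effect_table", modality, annotation, k)
    if key in dataset._cache:
        return dataset._cache[key]
    if modality not in dataset.modalities:
        raise ConfigurationError(
            f"unknown modality {modality!r}; available: {list(dataset.modalities)}"
        )
    labels = dataset.annotation(annotation)
    keep = labels != dataset.missing_token
    mat = dataset.modalities[modality]
    if not keep.all():
        mat = mat.subset_cells(np.flatnonzero(keep))
        labels = labels[keep]
    table = effect_table(mat, labels, k=k)
    dataset._cache[key] = table
    return table


def mean_expression(matrix: ExpressionMatrix, selection) -> np.ndarray:
    """Arithmetic mean of each feature over the selected cells."""
    mask = selection.cell_mask if isinstance(selection, Selection) else np.asarray(selection)
    if mask.dtype == bool:
        if mask.shape[0] != matrix.n_cells:
            raise ValidationError(
                f"mean_expression: mask length {mask.shape[0]} != {matrix.n_cells} cells"
            )
        idx = np.flatnonzero(mask)
    else:
        idx = mask
    if idx.size == 0:
        raise ValidationError("mean_expression: empty selection")
    sub = matrix.values[idx]
    if sp.issparse(sub):
        return np.asarray(sub.mean(axis=0)).ravel()
    return sub.mean(axis=0)


@dataclass
class MarkerPanel:
    """The ordered feature list chosen for display in a comparison.

    ``required`` features (user-forced) come first in their given order,
    followed by the ranked data-driven picks.  ``strategy`` records which
    dispatch path produced the panel; ``ranking`` keeps every candidate's
    absolute mean difference for serialization.
    """

    markers: list[str]
    required: list[str]
    strategy: str            # "low_dim" | "high_dim" | "prefiltered"
    modality: str
    n_display: int
    ranking: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        delta = dict(zip(self.ranking.get("feature", []), self.ranking.get("abs_delta_mean", [])))
        for rank, m in enumerate(self.markers, start=1):
            rows.append(
                (rank, m, m in self.required, delta.get(m, np.nan))
            )
        return pd.DataFrame(rows, columns=["rank", "feature", "required", "abs_delta_mean"])


def _provenance_annotations(*selections: Selection) -> list[str]:
    names: list[str] = []
    for sel in selections:
        p = sel.provenance
        if isinstance(p, NodeProvenance):
            cand = [p.annotation]
        elif isinstance(p, LinkProvenance):
            cand = [p.left_annotation, p.right_annotation]
        else:
            cand = []
        for a in cand:
            if a not in names:
                names.append(a)
    return names


def select_display_markers(
    dataset: MultimodalDataset,
    modality: str,
    sel1: Selection,
    sel2: Selection,
    required: Sequence[str] = (),
    n_display: int = 8,
    high_dim_threshold: int = 1000,
    prefiltered: bool = False,
    k: int = 10,
) -> MarkerPanel:
    """Choose the features to display when comparing two cell populations.

    Candidates are all features when the modality is low-dimensional
    (feature count ≤ ``high_dim_threshold``) or when ``prefiltered`` declares
    the matrix already restricted to markers of interest; otherwise the
    candidate set is the union of per-group top-k upregulated features
    (by median Cohen's d) over every annotation referenced by the two
    selections' provenance, so either side's discriminative features can
    surface.  Candidates are ranked by absolute difference in mean
    expression between the two selections (descending, ties by feature id)
    and the first ``n_display`` are kept; ``required`` features are always
    included, first, in their given order.
    """
    if modality not in dataset.modalities:
        raise ConfigurationError(
            f"unknown modality {modality!r}; available: {list(dataset.modalities)}"
        )
    mat = dataset.modalities[modality]
    feature_set = set(str(f) for f in mat.feature_ids)
    required = [str(f) for f in required]
    for f in required:
        if f not in feature_set:
            raise ConfigurationError(
                f"required feature {f!r} absent from modality {modality!r}"
            )
    if sel1.n_cells == 0 or sel2.n_cells == 0:
        raise ValidationError("select_display_markers: empty selection")
    overlap = int((sel1.cell_mask & sel2.cell_mask).sum())
    if overlap:
        logger.info(
            "select_display_markers: selections overlap in %d cell(s)", overlap
        )

    if prefiltered:
        strategy = "prefiltered"
        candidates = [str(f) for f in mat.feature_ids]
    elif mat.n_features <= high_dim_threshold:
        strategy = "low_dim"
        candidates = [str(f) for f in mat.feature_ids]
    else:
        strategy = "high_dim"
        union: list[str] = []
        seen = set()
        for ann in _provenance_annotations(sel1, sel2):
            table = annotation_effect_table(dataset, modality, ann, k=k)
            for group_features in table.top_k.values():
                for f in group_features:
                    if f not in seen:
                        seen.add(f)
                        union.append(f)
        candidates = sorted(union)
        logger.info(
            "select_display_markers: high-dim pre-selection reduced %d -> %d candidates",
            mat.n_features, len(candidates),
        )

    m1 = mean_expression(mat, sel1)
    m2 = mean_expression(mat, sel2)
    delta = np.abs(m1 - m2)
    by_feature = {str(f): float(delta[j]) for j, f in enumerate(mat.feature_ids)}
    ranked = sorted(candidates, key=lambda f: (-by_feature[f], f))
    picks = ranked[:n_display]
    markers = list(required) + [f for f in picks if f not in required]

    ranking = pd.DataFrame(
        {"feature": ranked, "abs_delta_mean": [by_feature[f] for f in ranked]}
    )
    return MarkerPanel(
        markers=markers,
        required=list(required),
        strategy=strategy,
        modality=modality,
        n_display=n_display,
        ranking=ranking,
    )


def write_effect_csv(table: EffectTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_panel_csv(panel: MarkerPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)
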