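"""Cross-annotation contingency structure behind the Sankey diagram.

The raw object is a :class:`ContingencyTable`: counts of cells per
(left-label, right-label) pair for two annotation columns.  Filtering links
and nodes below a minimum cell count produces a :class:`LinkSet` — the
Sankey skeleton.  Filtering is iterated to a fixed point: dropping a node
removes its links, which can push other nodes below threshold, so a single
pass would be order-dependent.  Node totals are always computed from
surviving links so displayed node sizes equal visible flow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import MultimodalDataset
from .errors import AllFilteredError, ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Counts of cells per (left label, right label) pair.

    Zero-count pairs are never stored; label order inside ``counts`` is
    lexicographic on (left, right).  Cells missing in either annotation are
    excluded (a flow needs both endpoints).
    """

    left_annotation: str
    right_annotation: str
    counts: dict[tuple[str, str], int]
    subset_context: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def left_labels(self) -> list[str]:
        return sorted({a for a, _ in self.counts})

    def right_labels(self) -> list[str]:
        return sorted({b for _, b in self.counts})

    def to_frame(self) -> pd.DataFrame:
        """Dense label × label count matrix (rows: left, columns: right)."""
        frame = pd.DataFrame(
            0, index=self.left_labels(), columns=self.right_labels(), dtype=int
        )
        for (a, b), n in self.counts.items():
            frame.loc[a, b] = n
        frame.index.name = self.left_annotation
        frame.columns.name = self.right_annotation
        return frame


@dataclass
class LinkSet:
    """Surviving links and per-side node totals after min-cell filtering.

    Invariants: each node total equals the sum of its surviving incident
    links, and every link endpoint exists among the nodes.
    """

    links: list[tuple[str, str, int]]
    left_nodes: list[tuple[str, int]]
    right_nodes: list[tuple[str, int]]
    min_cells: int
    left_annotation: str = ""
    right_annotation: str = ""

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.links)

    def to_links_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, columns=["left", "right", "count"])


def build_crosstab(
    dataset: MultimodalDataset, left: str, right: str
) -> ContingencyTable:
    """Count cells per (left-label, right-label) pair of two annotations.

    Cells carrying the missing token in either column are excluded (count
    logged).  Output label order is deterministic (lexicographic).
    """
    if left == right:
        raise ConfigurationError(
            f"left and right annotations must differ (both {left!r})"
        )
    lvals = dataset.annotation(left)
    rvals = dataset.annotation(right)
    ok = (lvals != dataset.missing_token) & (rvals != dataset.missing_token)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "build_crosstab(%s, %s): excluding %d cell(s) missing in either annotation",
            left, right, n_excluded,
        )
    table = pd.crosstab(pd.Series(lvals[ok]), pd.Series(rvals[ok]))
    counts: dict[tuple[str, str], int] = {}
    for a in sorted(table.index):
        for b in sorted(table.columns):
            n = int(table.loc[a, b])
            if n > 0:
                counts[(str(a), str(b))] = n
    return ContingencyTable(
        left_annotation=left,
        right_annotation=right,
        counts=counts,
        subset_context=getattr(dataset, "subset_context", ""),
    )


def _fixed_point_filter(
    counts: Mapping[tuple[str, str], int], min_cells: int
) -> dict[tuple[str, str], int]:
    """Drop links < min_cells, then iteratively drop nodes whose surviving
    flow < min_cells (with all their links) until stable."""
    surviving = {k: n for k, n in counts.items() if n >= min_cells}
    while True:
        left_tot: dict[str, int] = {}
        right_tot: dict[str, int] = {}
        for (a, b), n in surviving.items():
            left_tot[a] = left_tot.get(a, 0) + n
            right_tot[b] = right_tot.get(b, 0) + n
        bad_left = {a for a, t in left_tot.items() if t < min_cells}
        bad_right = {b for b, t in right_tot.items() if t < min_cells}
        if not bad_left and not bad_right:
            return surviving
        surviving = {
            (a, b): n
            for (a, b), n in surviving.items()
            if a not in bad_left and b not in bad_right
        }


def filter_links(table: ContingencyTable, min_cells: int = 20) -> LinkSet:
    """Filter out links and nodes containing fewer than ``min_cells`` cells.

    The default of 20 matches the usage convention of filtering Sankey noise;
    it is freely adjustable.  Node totals are recomputed from surviving links
    and node dropping is iterated to a fixed point (the only order-independent
    reading of "drop links and nodes below the threshold").

    Raises :class:`AllFilteredError` — carrying the largest threshold at which
    anything would survive — if the filter removes everything.
    """
    if min_cells < 0:
        raise ConfigurationError(f"min_cells must be >= 0, got {min_cells}")
    surviving = _fixed_point_filter(table.counts, min_cells)
    if not surviving and table.counts:
        # largest threshold with a non-empty fixed point; thresholds only
        # change behaviour at observed link counts
        viable = 0
        for t in sorted({n for n in table.counts.values()}):
            if _fixed_point_filter(table.counts, t):
                viable = t
        raise AllFilteredError(
            f"min_cells={min_cells} filters out every link; the largest viable "
            f"threshold for this table is {viable}",
            max_viable_threshold=viable,
        )
    left_tot: dict[str, int] = {}
    right_tot: dict[str, int] = {}
    for (a, b), n in surviving.items():
        left_tot[a] = left_tot.get(a, 0) + n
        right_tot[b] = right_tot.get(b, 0) + n
    return LinkSet(
        links=[(a, b, n) for (a, b), n in sorted(surviving.items())],
        left_nodes=sorted(left_tot.items()),
        right_nodes=sorted(right_tot.items()),
        min_cells=min_cells,
        left_annotation=table.left_annotation,
        right_annotation=table.right_annotation,
    )


def merge_labels(
    dataset: MultimodalDataset, annotation: str, mapping: Mapping[str, str]
) -> MultimodalDataset:
    """Collapse labels of one annotation into groups, as a new column.

    The new column is named ``<annotation>__grouped``; the original column is
    preserved.  Labels absent from ``mapping`` pass through unchanged (logged).
    Useful for strategically grouping populations across main cell types
    before building a crosstab.
    """
    for src, dst in mapping.items():
        if dst == dataset.missing_token:
            raise ConfigurationError(
                f"mapping {src!r} -> {dst!r} targets the missing token"
            )
    col = dataset.annotation(annotation)
    observed = set(pd.unique(col))
    unmapped = sorted(observed - set(mapping) - {dataset.missing_token})
    if unmapped:
        logger.info(
            "merge_labels(%s): %d label(s) pass through unchanged: %s",
            annotation, len(unmapped), unmapped,
        )
    merged = [mapping.get(v, v) for v in col]
    return dataset.with_annotation(f"{annotation}__grouped", merged)


def sankey_payload(
    linkset: LinkSet,
    selected_links: Mapping[tuple[str, str], int] | None = None,
) -> dict:
    """Plot-ready Sankey structure with stable, deterministic ordering.

    Nodes are ordered per side by descending total then lexicographic label;
    node indices are global (left side first).  Links are
    (source-index, target-index, value) ordered by (source, target).
    ``selected_links`` maps (left,right) label pairs to color-tag slots.
    """
    if not linkset.links:
        raise ConfigurationError("sankey_payload: empty LinkSet")
    selected_links = dict(selected_links or {})
    left_order = sorted(linkset.left_nodes, key=lambda kv: (-kv[1], kv[0]))
    right_order = sorted(linkset.right_nodes, key=lambda kv: (-kv[1], kv[0]))
    left_index = {label: i for i, (label, _) in enumerate(left_order)}
    right_index = {
        label: len(left_order) + i for i, (label, _) in enumerate(right_order)
    }
    links = sorted(
        (
            {
                "source": left_index[a],
                "target": right_index[b],
                "value": n,
                "color_tag": selected_links.get((a, b), 0),
            }
            for a, b, n in linkset.links
        ),
        key=lambda d: (d["source"], d["target"]),
    )
    return {
        "left_annotation": linkset.left_annotation,
        "right_annotation": linkset.right_annotation,
        "min_cells": linkset.min_cells,
        "nodes": (
            [{"label": l, "side": "left", "total": t} for l, t in left_order]
            + [{"label": l, "side": "right", "total": t} for l, t in right_order]
        ),
        "links": links,
    }


# -- serialization ------------------------------------------------------------


def write_links_csv(linkset: LinkSet, path: str | Path) -> None:
    linkset.to_links_frame().to_csv(path, index=False)


def write_sankey_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
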