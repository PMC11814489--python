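"""Population-comparison figure payloads.

Given two resolved selections and a display marker panel, this module
produces the numbers behind the comparison figures:

* **bars** — raw mean normalized expression per selection per panel feature;
* **rose** — the same means min–max scaled per feature onto [0, 1] across
  the two displayed selections (min → 0, max → 1; equal means → 0.5 each),
  so every petal of a radial plot is comparable;
* **umap** — a seeded, single-threaded 2-D embedding of the active subset
  over *all* features of a modality, with per-cell tags (sel1 / sel2 /
  both / background) matching the selected links' colors.

Everything is assembled into a :class:`ComparisonReport` carrying every
parameter used, so a report can be rebuilt bit-identically from its params
block plus the dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import MultimodalDataset, Selection
from .errors import ConfigurationError, ValidationError
from .markers import MarkerPanel, mean_expression

logger = logging.getLogger(__name__)

TAG_SEL1 = "sel1"
TAG_SEL2 = "sel2"
TAG_BOTH = "both"
TAG_BACKGROUND = "background"


@dataclass
class ComparisonReport:
    """Figure payload for one two-population comparison.

    ``rose`` and ``bars`` are (feature × selection) DataFrames over the
    panel's markers; ``umap`` maps modality name to a DataFrame with columns
    (cell_id, x, y, tag).  ``params`` records every setting used.
    """

    panel: MarkerPanel
    rose: pd.DataFrame
    bars: pd.DataFrame
    umap: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def rose_scale(bars: pd.DataFrame) -> pd.DataFrame:
    """Per-feature min–max scaling of displayed means onto [0, 1].

    For each feature (row): minimum mean → 0, maximum → 1; when all displayed
    means are equal there is nothing to contrast and every value becomes 0.5.
    Invariant under affine transforms of a feature's expression.
    """
    values = bars.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (values - lo) / span
    scaled = np.where(span == 0, 0.5, scaled)
    return pd.DataFrame(scaled, index=bars.index, columns=bars.columns)


def compare_populations(
    dataset: MultimodalDataset,
    modality: str,
    sel1: Selection,
    sel2: Selection,
    panel: MarkerPanel,
) -> ComparisonReport:
    """Raw and scaled mean expression of the panel's markers for two selections."""
    if modality not in dataset.modalities:
        raise ConfigurationError(
            f"unknown modality {modality!r}; available: {list(dataset.modalities)}"
        )
    mat = dataset.modalities[modality]
    missing = [f for f in panel.markers if f not in set(map(str, mat.feature_ids))]
    if missing:
        raise ConfigurationError(
            f"panel features absent from modality {modality!r}: {missing}"
        )
    sub = mat.subset_features(panel.markers)
    bars = pd.DataFrame(
        {
            sel1.display_name: mean_expression(sub, sel1),
            sel2.display_name: mean_expression(sub, sel2),
        },
        index=pd.Index(panel.markers, name="feature"),
    )
    report = ComparisonReport(
        panel=panel,
        rose=rose_scale(bars),
        bars=bars,
        params={
            "modality": modality,
            "sel1": sel1.display_name,
            "sel2": sel2.display_name,
            "markers": list(panel.markers),
            "required": list(panel.required),
            "strategy": panel.strategy,
            "n_display": panel.n_display,
        },
    )
    return report


def embed_umap(
    dataset: MultimodalDataset,
    modality: str,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Seeded 2-D UMAP of all cells of the dataset over all features of a modality.

    Runs single-threaded with a fixed random state so identical invocations
    give bit-identical coordinates (reproducible exports outrank speed).
    Coordinates are cached on the dataset per (modality, params).
    """
    if modality not in dataset.modalities:
        raise ConfigurationError(
            f"unknown modality {modality!r}; available: {list(dataset.modalities)}"
        )
    if dataset.n_cells < n_neighbors + 1:
        raise ValidationError(
            f"embed_umap: {dataset.n_cells} cells < n_neighbors+1 = {n_neighbors + 1}; "
            "reduce n_neighbors"
        )
    key = ("umap", modality, seed, n_neighbors, min_dist)
    if key in dataset._cache:
        return dataset._cache[key]
    import umap  # deferred: numba compilation is expensive at import time

    mat = dataset.modalities[modality]
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    coords = np.asarray(reducer.fit_transform(mat.dense()), dtype=float)
    dataset._cache[key] = coords
    logger.info(
        "embed_umap(%s): %d cells embedded (seed=%d, n_neighbors=%d, min_dist=%g)",
        modality, dataset.n_cells, seed, n_neighbors, min_dist,
    )
    return coords


def tag_cells(sel1: Selection, sel2: Selection) -> np.ndarray:
    """Per-cell tags: sel1 / sel2 / both (overlap, logged) / background."""
    if sel1.cell_mask.shape != sel2.cell_mask.shape:
        raise ValidationError("tag_cells: selections resolved on different subsets")
    tags = np.full(sel1.cell_mask.shape[0], TAG_BACKGROUND, dtype=object)
    tags[sel1.cell_mask] = TAG_SEL1
    tags[sel2.cell_mask] = TAG_SEL2
    both = sel1.cell_mask & sel2.cell_mask
    if both.any():
        logger.info("tag_cells: %d cell(s) in both selections", int(both.sum()))
        tags[both] = TAG_BOTH
    return tags


def add_umap_panel(
    report: ComparisonReport,
    dataset: MultimodalDataset,
    modality: str,
    sel1: Selection,
    sel2: Selection,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ComparisonReport:
    """Attach a tagged UMAP panel for one modality to a report.

    Rows are ordered background first (so highlighted cells draw on top),
    then sel1, sel2, both, preserving cell order within each tag.
    """
    coords = embed_umap(dataset, modality, seed=seed, n_neighbors=n_neighbors,
                        min_dist=min_dist)
    tags = tag_cells(sel1, sel2)
    frame = pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "tag": tags,
        }
    )
    order = {TAG_BACKGROUND: 0, TAG_SEL1: 1, TAG_SEL2: 2, TAG_BOTH: 3}
    frame = frame.sort_values("tag", key=lambda s: s.map(order), kind="stable")
    report.umap[modality] = frame.reset_index(drop=True)
    report.params.setdefault("umap", {})[modality] = {
        "seed": seed, "n_neighbors": n_neighbors, "min_dist": min_dist,
    }
    return report


# -- serialization ------------------------------------------------------------


def save_report(report: ComparisonReport, out_dir: str | Path,
                figures: bool = True) -> Path:
    """Write a report as a directory of CSVs + params JSON (+ static figures)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.bars.to_csv(out_dir / "bars.csv")
    report.rose.to_csv(out_dir / "rose.csv")
    report.panel.to_frame().to_csv(out_dir / "panel.csv", index=False)
    for modality, frame in report.umap.items():
        frame.to_csv(out_dir / f"umap_{modality}.csv", index=False)
    (out_dir / "params.json").write_text(
        json.dumps(report.params, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if figures:
        from . import plotting

        plotting.rose_figure(report.rose, out_dir / "rose.svg")
        plotting.bars_figure(report.bars, out_dir / "bars.svg")
        for modality, frame in report.umap.items():
            plotting.umap_figure(frame, out_dir / f"umap_{modality}.svg",
                                 title=f"UMAP ({modality})")
    return out_dir
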