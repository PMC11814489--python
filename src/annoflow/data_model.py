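"""Core in-memory types shared by every module.

A :class:`MultimodalDataset` couples one or more expression modalities
(e.g. log-normalized RNA, normalized ADT) over a shared, ordered set of
cells with a table of categorical per-cell annotations.  All comparison
operations — crosstabs, marker scoring, population reports — run on this
container.  No I/O and no statistics live here.

Cells are matched by position within one dataset; a designated missing
token (default ``"NA"``) marks cells without a label in an annotation and
is excluded from crosstabs and selections unless explicitly included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    ConfigurationError,
    EmptySelectionError,
    EmptySubsetError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default token marking a cell with no label in an annotation column.
MISSING_TOKEN = "NA"

MatrixLike = Union[np.ndarray, sp.spmatrix]


class ExpressionMatrix:
    """A cells × features matrix of already-normalized expression values.

    Values may be dense (ndarray) or sparse (any scipy.sparse format; stored
    as CSR).  NaNs are an input error: normalization happens upstream and a
    missing measurement has no meaning here.
    """

    def __init__(self, values: MatrixLike, feature_ids: Sequence[str]):
        if sp.issparse(values):
            values = values.tocsr()
            if np.isnan(values.data).any():
                raise ValidationError("expression matrix contains NaN values")
        else:
            values = np.asarray(values, dtype=float)
            if values.ndim != 2:
                raise ValidationError(
                    f"expression matrix must be 2-D, got shape {values.shape}"
                )
            if np.isnan(values).any():
                raise ValidationError("expression matrix contains NaN values")
        feature_ids = pd.Index([str(f) for f in feature_ids], name="feature")
        if len(feature_ids) == 0:
            raise ValidationError("expression matrix needs at least one feature")
        if feature_ids.has_duplicates:
            dup = feature_ids[feature_ids.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate feature ids: {dup}")
        if values.shape[1] != len(feature_ids):
            raise ValidationError(
                f"matrix has {values.shape[1]} columns but {len(feature_ids)} feature ids"
            )
        self.values = values
        self.feature_ids = feature_ids

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float ndarray (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def column(self, feature: str) -> np.ndarray:
        """Dense 1-D vector of one feature's values across all cells."""
        try:
            j = self.feature_ids.get_loc(feature)
        except KeyError:
            raise ConfigurationError(f"unknown feature {feature!r}") from None
        if sp.issparse(self.values):
            return np.asarray(self.values[:, j].todense()).ravel()
        return self.values[:, j]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[index], self.feature_ids)

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        idx = self.feature_ids.get_indexer(list(features))
        missing = [f for f, i in zip(features, idx) if i < 0]
        if missing:
            raise ConfigurationError(f"unknown features: {missing}")
        return ExpressionMatrix(self.values[:, idx], [str(f) for f in features])

    def __repr__(self) -> str:  # pragma: no cover
        kind = "sparse" if sp.issparse(self.values) else "dense"
        return f"ExpressionMatrix({self.n_cells} cells x {self.n_features} features, {kind})"


class MultimodalDataset:
    """Shared cell index + named expression modalities + annotation table.

    Parameters
    ----------
    cell_ids
        Ordered, unique cell identifiers (stringified).
    modalities
        Mapping from modality name (non-empty string) to
        :class:`ExpressionMatrix`, each with one row per cell in order.
    annotations
        DataFrame (or mapping of column name to per-cell labels) with one
        row per cell; every column is treated as a categorical annotation
        stored as strings.
    missing_token
        Label treated as "no annotation" in this dataset.
    """

    def __init__(
        self,
        cell_ids: Sequence[str],
        modalities: Mapping[str, ExpressionMatrix],
        annotations: Union[pd.DataFrame, Mapping[str, Sequence[str]]],
        missing_token: str = MISSING_TOKEN,
    ):
        cell_ids = pd.Index([str(c) for c in cell_ids], name="cell_id")
        if len(cell_ids) == 0:
            raise ValidationError("dataset must contain at least one cell")
        if cell_ids.has_duplicates:
            dup = cell_ids[cell_ids.duplicated()].unique().tolist()[:10]
            raise ValidationError(f"duplicate cell ids: {dup}")
        self.cell_ids = cell_ids

        self.modalities: dict[str, ExpressionMatrix] = {}
        for name, mat in dict(modalities).items():
            if not isinstance(name, str) or not name:
                raise ValidationError("modality names must be non-empty strings")
            if not isinstance(mat, ExpressionMatrix):
                mat = ExpressionMatrix(
                    mat.values if hasattr(mat, "values") else mat,
                    getattr(mat, "feature_ids", range(np.shape(mat)[1])),
                )
            if mat.n_cells != len(cell_ids):
                raise ValidationError(
                    f"modality {name!r} has {mat.n_cells} rows for {len(cell_ids)} cells"
                )
            self.modalities[name] = mat

        if not isinstance(annotations, pd.DataFrame):
            annotations = pd.DataFrame(dict(annotations))
        if len(annotations) != len(cell_ids):
            raise ValidationError(
                f"annotation table has {len(annotations)} rows for {len(cell_ids)} cells"
            )
        annotations = annotations.astype("string").astype(object)
        annotations.index = cell_ids
        self.annotations = annotations
        self.missing_token = missing_token
        # per-dataset cache used by markers.annotation_effect_table / compare.embed_umap
        self._cache: dict = {}

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def annotation_names(self) -> list[str]:
        return list(self.annotations.columns)

    def annotation(self, name: str) -> np.ndarray:
        """Per-cell label vector (object dtype) for one annotation column."""
        if name not in self.annotations.columns:
            raise ConfigurationError(
                f"unknown annotation {name!r}; available: {self.annotation_names}"
            )
        return self.annotations[name].to_numpy()

    def labels_of(self, name: str, include_missing: bool = False) -> list[str]:
        vals = pd.unique(self.annotation(name))
        out = [v for v in vals if include_missing or v != self.missing_token]
        return sorted(out)

    # -- structural ops ------------------------------------------------------

    def with_annotation(self, name: str, labels: Sequence[str]) -> "MultimodalDataset":
        """Return a copy with an extra (or replaced) annotation column."""
        ann = self.annotations.copy()
        ann[name] = [str(x) for x in labels]
        return MultimodalDataset(self.cell_ids, self.modalities, ann, self.missing_token)

    def take(self, index: np.ndarray, context: str = "") -> "MultimodalDataset":
        """Positional subset of cells; all modalities/annotations sliced consistently."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ds = MultimodalDataset(
            self.cell_ids[index],
            {n: m.subset_cells(index) for n, m in self.modalities.items()},
            self.annotations.iloc[index],
            self.missing_token,
        )
        ds.subset_context = getattr(self, "subset_context", "") + context
        return ds

    def __repr__(self) -> str:  # pragma: no cover
        mods = ", ".join(
            f"{n}[{m.n_features}]" for n, m in self.modalities.items()
        )
        return (
            f"MultimodalDataset({self.n_cells} cells; modalities: {mods}; "
            f"annotations: {self.annotation_names})"
        )


# -- selections ---------------------------------------------------------------


@dataclass(frozen=True)
class NodeProvenance:
    """One label in one annotation — a Sankey node."""

    annotation: str
    label: str

    def describe(self) -> str:
        return f"{self.annotation}={self.label}"


@dataclass(frozen=True)
class LinkProvenance:
    """A pair of labels in two annotations — a Sankey link."""

    left_annotation: str
    left_label: str
    right_annotation: str
    right_label: str

    def describe(self) -> str:
        return (
            f"{self.left_annotation}={self.left_label} & "
            f"{self.right_annotation}={self.right_label}"
        )


Provenance = Union[NodeProvenance, LinkProvenance]


@dataclass
class Selection:
    """A resolved set of cells, named by where it came from (node or link)."""

    cell_mask: np.ndarray
    provenance: Provenance
    display_name: str
    color_tag: int = 0

    def __post_init__(self):
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.cell_mask)


# -- operations ---------------------------------------------------------------


def subset(
    dataset: MultimodalDataset, annotation: str, labels: Iterable[str]
) -> MultimodalDataset:
    """Restrict a dataset to cells whose label in ``annotation`` is in ``labels``.

    All modalities and annotation columns are sliced consistently; the input
    dataset is untouched.  Raises :class:`EmptySubsetError` if nothing matches
    (a silent empty dataset would poison everything downstream).
    """
    labels = [str(x) for x in labels]
    if not labels:
        raise ConfigurationError("subset requires a non-empty label set")
    col = dataset.annotation(annotation)
    mask = np.isin(col, labels)
    if not mask.any():
        raise EmptySubsetError(
            f"no cells have {annotation!r} in {sorted(labels)}; "
            f"observed labels: {dataset.labels_of(annotation, include_missing=True)}"
        )
    context = f"[subset {annotation} in {sorted(labels)}]"
    logger.info("subset %s: %d/%d cells kept", context, int(mask.sum()), dataset.n_cells)
    return dataset.take(mask, context)


def resolve_selection(
    dataset: MultimodalDataset,
    provenance: Provenance,
    display_name: str | None = None,
    color_tag: int = 0,
    include_missing: bool = False,
) -> Selection:
    """Turn a node/link provenance into a concrete cell mask on ``dataset``.

    A node selects every cell carrying that label in that annotation; a link
    selects cells matching both of its labels simultaneously, so a link's
    cells are always a subset of each endpoint node's cells.
    """
    if isinstance(provenance, NodeProvenance):
        if not include_missing and provenance.label == dataset.missing_token:
            raise ConfigurationError(
                f"label {provenance.label!r} is the missing token; "
                "pass include_missing=True to select it"
            )
        mask = dataset.annotation(provenance.annotation) == provenance.label
    elif isinstance(provenance, LinkProvenance):
        if not include_missing and dataset.missing_token in (
            provenance.left_label,
            provenance.right_label,
        ):
            raise ConfigurationError(
                "link endpoints may not be the missing token "
                "(pass include_missing=True to allow it)"
            )
        mask = (
            dataset.annotation(provenance.left_annotation) == provenance.left_label
        ) & (dataset.annotation(provenance.right_annotation) == provenance.right_label)
    else:  # pragma: no cover
        raise ConfigurationError(f"unsupported provenance type: {type(provenance)!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySelectionError(f"selection {provenance.describe()} matches no cells")
    return Selection(
        cell_mask=mask,
        provenance=provenance,
        display_name=display_name or provenance.describe(),
        color_tag=color_tag,
    )
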