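"""Readers and writers for the standard single-cell formats this tool touches.

Three input routes produce a :class:`~annoflow.data_model.MultimodalDataset`:

* an h5ad-style hierarchical container (via :mod:`anndata`),
* a MatrixMarket bundle (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
  + ``metadata.csv``),
* a plain delimited table with named annotation and feature columns.

All expression inputs are assumed already normalized (log-scale RNA,
normalized ADT); :func:`lognorm_counts` is a convenience for raw counts only.
In memory, cells are always rows regardless of the on-disk orientation.
This module never computes statistics.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data_model import ExpressionMatrix, MultimodalDataset, MISSING_TOKEN
from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)


# -- h5ad ---------------------------------------------------------------------


def read_h5ad_like(
    path: str | Path,
    modality_key_map: Mapping[str, str] | None = None,
    missing_token: str = MISSING_TOKEN,
) -> MultimodalDataset:
    """Load an AnnData ``.h5ad`` container as a multimodal dataset.

    ``modality_key_map`` maps a modality name to where its matrix lives:
    ``"X"`` (the main matrix), ``"layers:<name>"``, or ``"obsm:<name>"``
    (an obsm DataFrame keeps its column names as feature ids; a bare array
    gets generated ids).  Default: ``{"RNA": "X"}``.  Every string or
    categorical ``obs`` column becomes an annotation.
    """
    import anndata

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    adata = anndata.read_h5ad(path)
    if modality_key_map is None:
        modality_key_map = {"RNA": "X"}

    modalities: dict[str, ExpressionMatrix] = {}
    for name, key in modality_key_map.items():
        if key == "X":
            if adata.X is None:
                raise FormatError(f"{path}: container has no X matrix")
            values = adata.X
            features = [str(v) for v in adata.var_names]
        elif key.startswith("layers:"):
            lname = key.split(":", 1)[1]
            if lname not in adata.layers:
                raise FormatError(f"{path}: no layer {lname!r} (for modality {name!r})")
            values = adata.layers[lname]
            features = [str(v) for v in adata.var_names]
        elif key.startswith("obsm:"):
            oname = key.split(":", 1)[1]
            if oname not in adata.obsm:
                raise FormatError(f"{path}: no obsm entry {oname!r} (for modality {name!r})")
            entry = adata.obsm[oname]
            if isinstance(entry, pd.DataFrame):
                values = entry.to_numpy(dtype=float)
                features = [str(c) for c in entry.columns]
            else:
                values = np.asarray(entry, dtype=float)
                features = [f"{name}_{j:03d}" for j in range(values.shape[1])]
        else:
            raise ConfigurationError(
                f"modality key {key!r} must be 'X', 'layers:<name>' or 'obsm:<name>'"
            )
        modalities[name] = ExpressionMatrix(values, features)

    ann_cols = {}
    for col in adata.obs.columns:
        s = adata.obs[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or pd.api.types.is_string_dtype(s):
            ann_cols[col] = s.astype(str).to_numpy()
    annotations = pd.DataFrame(ann_cols, index=range(adata.n_obs))
    logger.info(
        "read_h5ad_like(%s): %d cells, modalities %s, %d annotation columns",
        path, adata.n_obs, list(modalities), annotations.shape[1],
    )
    return MultimodalDataset(
        [str(c) for c in adata.obs_names], modalities, annotations, missing_token
    )


# -- MTX bundle ---------------------------------------------------------------


def read_mtx_bundle(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path | None = None,
    modality: str = "RNA",
    orientation: str = "auto",
    missing_token: str = MISSING_TOKEN,
) -> MultimodalDataset:
    """Load a MatrixMarket bundle (matrix + features + barcodes [+ metadata]).

    Orientation is auto-detected by matching the barcode count against the
    matrix dimensions; a square matrix is ambiguous and demands an explicit
    ``orientation`` of ``"cells_rows"`` or ``"features_rows"``.  Metadata is
    joined on barcode; unmatched barcodes are an error.
    """
    values = scipy.io.mmread(str(matrix_path)).tocsr()
    features = _read_single_column_tsv(features_path)
    barcodes = _read_single_column_tsv(barcodes_path)
    n_rows, n_cols = values.shape

    if orientation == "auto":
        if n_rows == n_cols:
            raise FormatError(
                f"{matrix_path}: square matrix ({n_rows}x{n_cols}); orientation is "
                "ambiguous — pass orientation='cells_rows' or 'features_rows'"
            )
        if n_rows == len(barcodes) and n_cols == len(features):
            orientation = "cells_rows"
        elif n_cols == len(barcodes) and n_rows == len(features):
            orientation = "features_rows"
        else:
            raise FormatError(
                f"{matrix_path}: shape {values.shape} matches neither "
                f"{len(barcodes)} barcodes x {len(features)} features nor its transpose"
            )
    if orientation == "features_rows":
        values = values.T.tocsr()
    elif orientation != "cells_rows":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if values.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"{matrix_path}: shape {values.shape} inconsistent with "
            f"{len(barcodes)} barcodes and {len(features)} features"
        )

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, dtype=str)
        bc_col = meta.columns[0]
        meta = meta.set_index(bc_col)
        missing = [b for b in barcodes if b not in meta.index]
        if missing:
            raise FormatError(
                f"{metadata_path}: {len(missing)} barcodes absent from metadata, "
                f"first 10: {missing[:10]}"
            )
        annotations = meta.loc[barcodes].reset_index(drop=True)
    else:
        annotations = pd.DataFrame(index=range(len(barcodes)))

    logger.info(
        "read_mtx_bundle(%s): %d cells x %d features (%s)",
        matrix_path, values.shape[0], values.shape[1], orientation,
    )
    return MultimodalDataset(
        barcodes, {modality: ExpressionMatrix(values, features)}, annotations, missing_token
    )


def write_mtx_bundle(
    dataset: MultimodalDataset,
    out_dir: str | Path,
    modality: str = "RNA",
    write_metadata: bool = True,
) -> Path:
    """Write one modality as an exact-round-trip MatrixMarket bundle.

    Values are written with 17 significant digits so float64 entries survive
    a write→read round trip bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if modality not in dataset.modalities:
        raise ConfigurationError(
            f"unknown modality {modality!r}; available: {list(dataset.modalities)}"
        )
    mat = dataset.modalities[modality]
    values = mat.values if sp.issparse(mat.values) else sp.csr_matrix(mat.values)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), values.tocoo(), precision=17)
    (out_dir / "features.tsv").write_text(
        "".join(f"{f}\n" for f in mat.feature_ids), encoding="utf-8"
    )
    (out_dir / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in dataset.cell_ids), encoding="utf-8"
    )
    if write_metadata:
        meta = dataset.annotations.copy()
        meta.insert(0, "barcode", dataset.cell_ids)
        meta.to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def _read_single_column_tsv(path: str | Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    if not out:
        raise FormatError(f"{path}: empty file")
    return out


# -- delimited tables ---------------------------------------------------------


def read_table(
    path: str | Path,
    annotation_columns: Sequence[str],
    feature_columns: Sequence[str],
    modality: str = "RNA",
    delimiter: str | None = None,
    id_column: str | None = None,
    missing_token: str = MISSING_TOKEN,
) -> MultimodalDataset:
    """Load a CSV/TSV table, splitting columns into annotations and one modality.

    The delimiter is inferred from the extension (``.tsv``/``.txt`` → tab,
    otherwise comma) unless given explicitly.  A non-numeric value in a
    feature column is a parse error naming the row and column.
    """
    path = Path(path)
    overlap = set(annotation_columns) & set(feature_columns)
    if overlap:
        raise ConfigurationError(
            f"columns listed as both annotation and feature: {sorted(overlap)}"
        )
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    for col in list(annotation_columns) + list(feature_columns):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: no column {col!r}; have {list(df.columns)}")

    numeric = {}
    for col in feature_columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in feature column "
                f"{col!r}, row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValidationError(f"{path}: missing value in feature column {col!r}, row {row}")
        numeric[col] = converted.to_numpy(dtype=float)

    if id_column is not None:
        cell_ids = df[id_column].astype(str).tolist()
    else:
        cell_ids = [f"cell{i:06d}" for i in range(len(df))]
    matrix = ExpressionMatrix(
        np.column_stack([numeric[c] for c in feature_columns]), list(feature_columns)
    )
    annotations = df[list(annotation_columns)].fillna(missing_token)
    return MultimodalDataset(cell_ids, {modality: matrix}, annotations, missing_token)


# -- normalization convenience ------------------------------------------------


def lognorm_counts(
    raw_counts, scale: float = 1e4
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Library-size normalize raw counts and log-transform.

    Per cell: ``counts / cell_total * scale`` then ``log(1 + value)``
    (natural log, pseudo-count 1, scale 10,000 by default — the common
    log-CP10K convention).  All-zero cells cannot be normalized; they are
    dropped with a warning.

    Returns ``(matrix, kept_mask)`` where ``kept_mask`` marks the input rows
    that survived, so callers can slice their metadata consistently.
    """
    feature_ids = None
    if isinstance(raw_counts, ExpressionMatrix):
        feature_ids = list(raw_counts.feature_ids)
        raw_counts = raw_counts.values
    if sp.issparse(raw_counts):
        counts = raw_counts.tocsr().astype(float)
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("lognorm_counts: negative entries in count matrix")
        totals = np.asarray(counts.sum(axis=1)).ravel()
    else:
        counts = np.asarray(raw_counts, dtype=float)
        if counts.size and counts.min() < 0:
            raise ValidationError("lognorm_counts: negative entries in count matrix")
        totals = counts.sum(axis=1)

    kept = totals > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.warning("lognorm_counts: dropping %d all-zero cell(s)", n_dropped)
        counts = counts[kept]
        totals = totals[kept]

    if sp.issparse(counts):
        scaling = sp.diags(scale / totals)
        normed = scaling @ counts
        normed.data = np.log1p(normed.data)
        values = normed.tocsr()
    else:
        values = np.log1p(counts / totals[:, None] * scale)
    if feature_ids is None:
        feature_ids = [f"feature{j:05d}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, feature_ids), kept


# -- dataset-level convenience loader ----------------------------------------


def load_dataset(
    path: str | Path,
    modality_key_map: Mapping[str, str] | None = None,
    missing_token: str = MISSING_TOKEN,
) -> MultimodalDataset:
    """Dispatch on path type: ``.h5ad`` file, or a simulator-style directory.

    A directory is expected to hold one subdirectory per modality (each a
    MatrixMarket bundle) plus a top-level ``metadata.csv`` with per-cell
    annotations keyed by barcode.
    """
    path = Path(path)
    if path.is_dir():
        mod_dirs = sorted(
            d for d in path.iterdir() if d.is_dir() and (d / "matrix.mtx").exists()
        )
        if not mod_dirs:
            raise FormatError(f"{path}: no modality subdirectories with matrix.mtx found")
        meta_path = path / "metadata.csv"
        first = read_mtx_bundle(
            mod_dirs[0] / "matrix.mtx",
            mod_dirs[0] / "features.tsv",
            mod_dirs[0] / "barcodes.tsv",
            meta_path if meta_path.exists() else None,
            modality=mod_dirs[0].name,
            missing_token=missing_token,
        )
        modalities = dict(first.modalities)
        for d in mod_dirs[1:]:
            extra = read_mtx_bundle(
                d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
                None, modality=d.name, missing_token=missing_token,
            )
            if list(extra.cell_ids) != list(first.cell_ids):
                raise FormatError(f"{d}: barcodes disagree with {mod_dirs[0]}")
            modalities[d.name] = extra.modalities[d.name]
        return MultimodalDataset(first.cell_ids, modalities, first.annotations, missing_token)
    if path.suffix == ".h5ad":
        return read_h5ad_like(path, modality_key_map, missing_token)
    raise FormatError(
        f"{path}: cannot infer format (expected .h5ad file or a bundle directory); "
        "use read_table for delimited tables"
    )
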