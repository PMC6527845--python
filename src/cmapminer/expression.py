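"""Expression-matrix normalization and probe-to-gene collapsing.

Matrices are pandas DataFrames with features as rows and samples as
columns. Quantile normalization forces all sample columns onto a shared
empirical distribution (each order statistic replaced by its
cross-sample mean); intensities detected as linear-scale are
log2-transformed; probe-level rows mapped to the same gene are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "quantile_normalize",
    "log2_if_needed",
    "collapse_to_genes",
    "read_expression_tsv",
    "read_metadata_tsv",
    "normalize_dataset",
]

#: log2 microarray intensities rarely exceed ~20; a maximum above this
#: threshold marks the matrix as linear-scale.
LOG_SCALE_MAX_THRESHOLD = 50.0


@dataclass
class ExpressionDataset:
    """A (features x samples) expression matrix with per-sample labels.

    ``metadata`` is indexed by sample_id with columns ``group``
    (tumor/normal), ``hpv`` (positive/negative/unknown) and ``smoking``
    (smoker/non-smoker/unknown); missing columns mean the labels are
    unavailable for that dataset.
    """

    dataset_id: str
    matrix: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate feature ids")
        if self.matrix.columns.has_duplicates:
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if not self.metadata.empty:
            missing = set(self.matrix.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(
                    f"{self.dataset_id}: samples missing from metadata: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a features x samples matrix.

    The value at rank r of every column is replaced by the mean over
    columns of the r-th order statistics; tied values within a column
    receive the mean of their tied target values. Rows containing any
    missing value are excluded from the target computation and returned
    as all-missing (they have no well-defined rank in every column).

    A single-column matrix is returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn(
            "quantile normalization needs >= 2 samples; matrix returned "
            "unchanged",
            stacklevel=2,
        )
        return matrix.copy()
    complete = matrix.dropna(axis=0)
    values = complete.to_numpy(dtype=float)
    n_rows = values.shape[0]
    out = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    if n_rows == 0:
        return out
    target = np.sort(values, axis=0).mean(axis=1)
    normed = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie groups in the sorted column share the mean of their targets
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_rows]))
        col_out = np.empty(n_rows)
        for s, e in zip(starts, ends):
            col_out[order[s:e]] = target[s:e].mean()
        normed[:, j] = col_out
    out.loc[complete.index] = normed
    return out


def log2_if_needed(
    matrix: pd.DataFrame,
    threshold: float = LOG_SCALE_MAX_THRESHOLD,
    epsilon: float = 1.0,
) -> tuple[pd.DataFrame, bool]:
    """log2-transform a matrix iff it looks linear-scale.

    The heuristic: a matrix whose maximum exceeds ``threshold`` is taken
    to hold raw intensities and transformed as ``log2(x + epsilon)``
    (``epsilon`` guards zeros); otherwise it is already in log space and
    returned unchanged. Returns ``(matrix, was_transformed)``.
    """
    max_value = matrix.max().max()
    if not (max_value > threshold):
        return matrix.copy(), False
    if (matrix < 0).any().any():
        raise ValueError(
            "matrix flagged as linear-scale contains negative values; "
            "cannot log2-transform"
        )
    return np.log2(matrix + epsilon), True


def collapse_to_genes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Average probe-level rows into gene-level rows.

    Probes absent from the map are dropped; each gene's row is the
    arithmetic mean of its mapped probes' rows. Output genes are sorted
    lexicographically.
    """
    mapped = [f for f in matrix.index if f in probe_to_gene]
    if not mapped:
        raise ValueError("no matrix feature is present in the probe-gene map")
    sub = matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[f] for f in mapped], name="gene_id")
    collapsed = sub.groupby(genes).mean()
    return collapsed.sort_index()


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (feature ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata TSV keyed by sample_id."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def normalize_dataset(
    ds: ExpressionDataset,
    quantile: bool = True,
    log_threshold: float = LOG_SCALE_MAX_THRESHOLD,
    epsilon: float = 1.0,
    probe_to_gene: Mapping[str, str] | None = None,
) -> ExpressionDataset:
    """Standard normalization chain: quantile -> conditional log2 ->
    optional probe collapsing. Returns a new dataset flagged as log2."""
    matrix = ds.matrix
    if quantile:
        matrix = quantile_normalize(matrix)
    matrix, _ = log2_if_needed(matrix, threshold=log_threshold, epsilon=epsilon)
    if probe_to_gene is not None:
        matrix = collapse_to_genes(matrix, probe_to_gene)
    return ExpressionDataset(ds.dataset_id, matrix, ds.metadata, is_log2=True)
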