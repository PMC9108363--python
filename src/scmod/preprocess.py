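"""Expression loading and gene filtering.

Input is a genes x samples matrix of non-negative expression values
(FPKM or comparable) plus a two-column sample -> subtype label file.
Genes are filtered in two passes: a mean-expression floor on the raw
scale, then a variability cut keeping the top fraction of genes by
median absolute deviation (mad) of the working (possibly log2) values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample subtype labels.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``labels`` maps every sample id to a subtype name. Ids must be
    unique, every sample must carry exactly one label, every subtype
    must have at least two samples, and the matrix must be complete.
    """

    values: pd.DataFrame
    labels: pd.Series
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.values.columns.equals(pd.Index(self.labels.index)):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without a label: {missing[:5]}")
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("expression matrix contains missing values")
        counts = self.labels.value_counts()
        if (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise ValueError(f"subtypes with fewer than 2 samples: {small}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subtypes(self) -> list[str]:
        """Subtype names in their canonical (sorted) order."""
        return sorted(self.labels.unique())

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, subtype: str) -> list[str]:
        """Sample ids of one subtype, in matrix column order."""
        if subtype not in set(self.labels):
            raise KeyError(f"unknown subtype: {subtype}")
        return list(self.labels.index[self.labels == subtype])

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[list(gene_ids)], self.labels, self.log_transformed
        )

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(
            self.values[ids], self.labels.loc[ids], self.log_transformed
        )


def _read_labels(labels_path) -> pd.Series:
    rows = []
    with open(labels_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"labels file: expected 2 columns, got {len(parts)}")
            rows.append(parts)
    labels = pd.Series({s: t for s, t in rows}, name="subtype")
    if len(labels) != len(rows):
        raise ValueError("duplicate sample ids in labels file")
    return labels


def load_expression(matrix_path, labels_path, log_transform: bool = True) -> ExpressionDataset:
    """Load an expression TSV and a label TSV into an ExpressionDataset.

    The matrix file has gene ids in the first column and a header row of
    sample ids. Samples present in the matrix but absent from the label
    file are dropped with a warning; an empty intersection is an error.
    With ``log_transform`` the values become log2(x + 1).
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.has_duplicates:
        raise ValueError("duplicate gene ids in matrix file")
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids in matrix file")
    labels = _read_labels(labels_path)

    shared = [s for s in values.columns if s in labels.index]
    dropped = [s for s in values.columns if s not in labels.index]
    if dropped:
        logger.warning(
            "%d samples in matrix have no label and are excluded: %s",
            len(dropped), dropped[:5],
        )
    if not shared:
        raise ValueError("no samples shared between matrix and labels")
    values = values[shared]
    labels = labels.loc[shared]

    if log_transform:
        values = np.log2(values + 1.0)
    return ExpressionDataset(values=values, labels=labels, log_transformed=log_transform)


def mad(x) -> float:
    """Median absolute deviation, median(|x_i - median(x)|), unscaled."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty vector")
    return float(np.median(np.abs(x - np.median(x))))


def filter_genes(
    ds: ExpressionDataset, min_mean: float = 10.0, keep_fraction: float = 0.9
) -> ExpressionDataset:
    """Drop low-expression genes, then keep the most variable fraction.

    The mean filter acts on the raw (pre-log) scale: genes whose average
    raw expression over all samples is below ``min_mean`` are removed.
    Of the survivors, the ceil(keep_fraction * n) genes with the largest
    mad of the working values are kept (ties at the boundary broken by
    gene id), preserving original gene order.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    raw = ds.values.to_numpy()
    if ds.log_transformed:
        raw = np.power(2.0, raw) - 1.0
    mean_ok = raw.mean(axis=1) >= min_mean
    survivors = ds.values.index[mean_ok]
    if len(survivors) == 0:
        raise ValueError("mean-expression filter removed every gene")

    mads = ds.values.loc[survivors].apply(mad, axis=1)
    k = math.ceil(keep_fraction * len(survivors))
    order = sorted(survivors, key=lambda g: (-mads[g], g))
    kept = set(order[:k])
    kept_in_order = [g for g in ds.values.index if g in kept]
    if not kept_in_order:
        raise ValueError("all genes filtered out")
    return ds.subset_genes(kept_in_order)
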