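"""Expression matrices, sample metadata and the expression index (EI).

The expression index of a sample is the summed expression of all genes in
that sample.  Ordering samples by ascending EI turns a collection of
steady-state samples into a pseudo-continuous axis along which quasi-dynamic
ODEs can be formulated; every downstream stage of the package works on
EI-ordered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionIndex",
    "load_expression",
    "load_metadata",
    "compute_expression_index",
    "reorder_by_ei",
]


class ExpressionValidationError(ValueError):
    """Raised when an expression table violates the matrix contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (usually non-negative) expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (m, N)
        Expression values; units are arbitrary but shared across genes.
    metadata : DataFrame, optional
        Per-sample table indexed by sample id; recognised columns are
        ``subject``, ``group`` and ``time_label``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionValidationError("values must be 2-dimensional")
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise ExpressionValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ExpressionValidationError(f"duplicated {name} ID(s): {dupes}")
        if np.isnan(self.values).any():
            raise ExpressionValidationError(
                "missing values present; impute explicitly (impute_missing) first"
            )
        if (self.values < 0).any():
            warnings.warn(
                "negative expression values present; EI is still the raw column sum",
                UserWarning,
                stacklevel=2,
            )
        if self.metadata is not None:
            missing = [s for s in self.sample_ids if s not in self.metadata.index]
            if missing:
                raise ExpressionValidationError(
                    f"metadata missing sample(s): {missing[:5]}"
                )
            self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: pd.DataFrame | None = None):
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            metadata=metadata,
        )

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            metadata=meta,
        )

    def impute_missing(self) -> "ExpressionMatrix":
        """Per-gene median imputation of NaNs (opt-in; loading refuses NaNs)."""
        vals = self.values.copy()
        med = np.nanmedian(vals, axis=1)
        rows, cols = np.where(np.isnan(vals))
        vals[rows, cols] = med[rows]
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), vals, self.metadata)

    def write(self, path, format: str = "tsv") -> None:
        sep = "\t" if format == "tsv" else ","
        self.to_frame().to_csv(path, sep=sep, index_label="gene_id")


@dataclass
class ExpressionIndex:
    """Per-sample EI values and the ascending-EI sample ordering."""

    ei: np.ndarray
    order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ei = np.asarray(self.ei, dtype=float)
        if self.order is None:
            # stable sort: EI ties broken by original column order
            self.order = np.argsort(self.ei, kind="stable")
        self.order = np.asarray(self.order, dtype=int)

    @property
    def sorted_ei(self) -> np.ndarray:
        return self.ei[self.order]

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        rank = np.empty_like(self.order)
        rank[self.order] = np.arange(len(self.order))
        return pd.DataFrame({"sample_id": sample_ids, "ei": self.ei, "rank": rank})


def _read_table(path, format: str | None) -> pd.DataFrame:
    if format is None:
        format = "csv" if str(path).endswith(".csv") else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'csv'")
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ExpressionValidationError(f"malformed table {path}: {exc}") from exc
    return df


def load_expression(
    path,
    format: str | None = None,
    metadata: pd.DataFrame | None = None,
    allow_negative: bool = True,
) -> ExpressionMatrix:
    """Read a genes x samples table (first row sample IDs, first column gene IDs).

    ``format`` is ``"tsv"`` or ``"csv"``; inferred from the extension when
    omitted.  Duplicate gene IDs and missing entries are rejected.  Negative
    values raise a warning by default, or an error with
    ``allow_negative=False``.
    """
    df = _read_table(path, format)
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        bad = df[non_numeric[0]]
        offender = bad[pd.to_numeric(bad, errors="coerce").isna()].index
        raise ExpressionValidationError(
            f"non-numeric value in column {non_numeric[0]!r}"
            + (f" at gene {offender[0]!r}" if len(offender) else "")
        )
    if not allow_negative and (df.to_numpy() < 0).any():
        raise ExpressionValidationError("negative expression values present")
    return ExpressionMatrix.from_frame(df, metadata=metadata)


def load_metadata(path, format: str | None = None) -> pd.DataFrame:
    """Read a per-sample metadata table keyed by sample ID."""
    return _read_table(path, format)


def compute_expression_index(x: ExpressionMatrix) -> ExpressionIndex:
    """EI of sample i = sum over genes of expression in sample i."""
    return ExpressionIndex(ei=x.values.sum(axis=0))


def reorder_by_ei(x: ExpressionMatrix, e: ExpressionIndex) -> ExpressionMatrix:
    """Permute samples so the EI is non-decreasing (metadata follows)."""
    if len(e.ei) != x.n_samples:
        raise ExpressionValidationError(
            f"EI length {len(e.ei)} does not match {x.n_samples} samples"
        )
    return x.subset_samples(e.order)
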