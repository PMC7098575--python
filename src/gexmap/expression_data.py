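"""Expression-matrix ingestion and unsupervised gene filtering.

The input is a genes x samples table of log-scale abundances
(log2(TPM + 0.001) in the Pan-Cancer export dialect): first column gene
identifiers, header row of sample identifiers, tab-separated, optionally
gzip-compressed.  Pre-processing is fully unsupervised: genes that are
constant across samples are removed, then the top-k genes by median
absolute deviation (MAD) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "read_expression_matrix",
    "read_phenotype_table",
    "filter_constant_genes",
    "select_top_mad",
    "mean_expression",
    "split_cohorts",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples matrix of finite log-scale expression values.

    ``data`` is a pandas DataFrame indexed by gene identifier with one column
    per sample.  Identifiers must be unique and every value finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_vector(self, sample_id) -> pd.Series:
        """One sample's gene-expression vector g_i."""
        return self.data[sample_id]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample clinical annotations: cohort label and PFI outcome.

    ``data`` is indexed by sample identifier with columns ``cohort``,
    ``pfi_event`` (0/1 or NaN) and ``pfi_time`` (days, >= 0 or NaN).
    Missing outcome values are permitted at load time; they are rejected
    only when labels are actually derived.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"cohort", "pfi_event", "pfi_time"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        ev = df["pfi_event"].dropna()
        if not ev.isin([0, 1]).all():
            bad = ev[~ev.isin([0, 1])].iloc[0]
            raise ValueError(f"pfi_event must be 0/1, got {bad!r}")
        tm = df["pfi_time"].dropna()
        if (tm < 0).any():
            raise ValueError("pfi_time must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def cohort_of(self, sample_id) -> str:
        try:
            return self.data.at[sample_id, "cohort"]
        except KeyError:
            raise KeyError(f"unknown sample: {sample_id!r}") from None


_ORIENTATIONS = ("genes-in-rows", "samples-in-rows")


def read_expression_matrix(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a tab-separated expression table (Xena dialect, gzip accepted).

    Parameters
    ----------
    path:
        TSV file whose first column holds identifiers and whose header row
        holds the other axis' identifiers.
    orientation:
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"``; the result is
        always normalized to genes x samples.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression table {path}: {exc}") from exc
    if df.index.name is None and df.shape[1] == 0:
        raise ValueError(f"malformed expression table {path}: no data columns")
    # Locate any non-numeric cell and report it by row/column.
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric value at row {row!r}, column {col!r} in {path}"
                )
            df[col] = coerced
    if df.isna().any().any():
        stacked = df.isna().stack()
        row, col = stacked[stacked].index[0]
        raise ValueError(f"non-numeric value at row {row!r}, column {col!r} in {path}")
    if orientation == "samples-in-rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df.astype(float))


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample, cohort, PFI, PFI.time."""
    df = pd.read_csv(path, sep="\t")
    aliases = {"sample": "sample", "cohort": "cohort", "PFI": "pfi_event", "PFI.time": "pfi_time"}
    missing = [c for c in aliases if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table {path} missing columns: {missing}")
    df = df.rename(columns=aliases).set_index("sample")
    return PhenotypeTable(df[["cohort", "pfi_event", "pfi_time"]])


def filter_constant_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose expression is constant across all samples.

    "Constant" is literal: population standard deviation exactly zero.
    """
    sd = X.values.std(axis=1, ddof=0)
    keep = sd > 0.0
    if not keep.any():
        raise ValueError("all genes have constant expression; nothing retained")
    return ExpressionMatrix(X.data.loc[keep])


def _mad(values: np.ndarray) -> np.ndarray:
    """Per-row median absolute deviation, median(|x - median(x)|), unscaled."""
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def select_top_mad(X: ExpressionMatrix, k: int = 20_000) -> ExpressionMatrix:
    """Retain the k most variably expressed genes by MAD.

    Ties at the k-th rank are broken by input order (stable sort) and the
    relative input order of the surviving genes is preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= X.n_genes:
        return X
    mad = _mad(X.values)
    top = np.sort(np.argsort(-mad, kind="stable")[:k])
    return ExpressionMatrix(X.data.iloc[top])


def mean_expression(X: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean expression of each gene across all samples."""
    return X.data.mean(axis=1)


def split_cohorts(X: ExpressionMatrix, pheno: PhenotypeTable, target_cohorts):
    """Partition samples into a base set and a target set by cohort label.

    Returns ``(base, target)`` where target holds exactly the samples whose
    cohort label is in ``target_cohorts`` (e.g. {"LUAD", "LUSC"}) and base
    holds every other sample.
    """
    target_cohorts = set(target_cohorts)
    known = set(pheno.sample_ids)
    unknown = [s for s in X.sample_ids if s not in known]
    if unknown:
        raise KeyError(f"samples absent from phenotype table: {unknown[:5]}")
    cohorts = pheno.data["cohort"]
    in_target = [s for s in X.sample_ids if cohorts[s] in target_cohorts]
    in_base = [s for s in X.sample_ids if cohorts[s] not in target_cohorts]
    return X.subset_samples(in_base), X.subset_samples(in_target)
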