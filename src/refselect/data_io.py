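"""Reading, writing and transforming expression tables.

Wide tables are samples x genes.  Values may be threshold-cycle (Ct)
numbers, linear-scale relative expression, or log-scale expression; the
``scale`` tag on :class:`ExpressionMatrix` records which, and determines
which transforms are legal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Scale = Literal["log_expression", "ct", "linear_expression"]

_SCALES = ("log_expression", "ct", "linear_expression")

#: Scales on which variance/covariance analysis operates directly.
#: Ct numbers are already on a log2-like scale (one cycle = one doubling),
#: so they may be analyzed without any transform.
ANALYSIS_SCALES = ("log_expression", "ct")


@dataclass
class ExpressionMatrix:
    """N samples x J genes of expression values with a scale tag.

    Parameters
    ----------
    values : (N, J) float array
        One row per sample, one column per gene.
    gene_ids : sequence of str
        J unique gene labels.
    sample_ids : sequence of str
        N sample labels.
    scale : {"log_expression", "ct", "linear_expression"}
        What the values are.
    covariates : pandas.DataFrame, optional
        Per-sample factors (e.g. tissue type), indexed like ``sample_ids``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: Scale = "log_expression"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x genes) array")
        n, j = self.values.shape
        if n < 1 or j < 1:
            raise ValueError("need at least one sample and one gene")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != j:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {j} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(set(self.gene_ids)) != j:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicated gene ids: {dupes}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not np.all(np.isfinite(self.values)):
            bad = _locate_nonfinite(self.values, self.sample_ids, self.gene_ids)
            raise ValueError(f"non-finite values at {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def require_scale(self, *scales: str) -> None:
        if self.scale not in scales:
            raise ValueError(
                f"operation requires scale in {scales}, got {self.scale!r}"
            )


@dataclass
class ReplicateTable:
    """Long-format technical replicate records.

    ``records`` has columns sample, gene, replicate, value (one row per
    technical replicate of a reaction).
    """

    records: pd.DataFrame
    scale: Scale = "ct"
    covariates: pd.DataFrame | None = field(default=None)

    REQUIRED = ("sample", "gene", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"replicate table missing columns: {missing}")
        if not np.all(np.isfinite(self.records["value"].to_numpy(dtype=float))):
            raise ValueError("replicate table contains non-finite values")


def _locate_nonfinite(values, sample_ids, gene_ids, limit: int = 5) -> list[tuple[str, str]]:
    rows, cols = np.where(~np.isfinite(values))
    return [(sample_ids[r], gene_ids[c]) for r, c in zip(rows[:limit], cols[:limit])]


def _sniff_sep(path) -> str:
    import csv

    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _check_duplicate_header(path, sep: str, orientation: str) -> None:
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    ids = [h.strip() for h in header[1:]]
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        kind = "gene" if orientation == "samples_rows" else "sample"
        raise ValueError(f"duplicated {kind} ids in header: {dupes}")


def read_expression_table(
    path,
    orientation: Literal["samples_rows", "genes_rows"] = "samples_rows",
    scale: Scale = "log_expression",
    missing: Literal["error", "drop_sample"] = "error",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited wide table into an :class:`ExpressionMatrix`.

    The first column holds row identifiers and the header row column
    identifiers.  ``orientation`` states which axis carries samples; no
    auto-detection is attempted.  ``missing="drop_sample"`` removes samples
    with any missing value (complete-case: covariance estimation needs
    complete per-sample gene vectors); the default rejects missing data.
    """
    if sep is None:
        sep = _sniff_sep(path)
    # pandas silently renames duplicate header entries, so check the raw
    # header; duplicate row ids survive parsing and are caught downstream
    _check_duplicate_header(path, sep, orientation)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "genes_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        cell = _first_nonnumeric_cell(df)
        raise ValueError(f"non-numeric cell at sample={cell[0]!r}, gene={cell[1]!r}")

    sample_ids = [str(s) for s in df.index]
    gene_ids = [str(g) for g in df.columns]

    bad_mask = ~np.isfinite(values)
    if bad_mask.any():
        if missing == "error":
            bad = _locate_nonfinite(values, sample_ids, gene_ids)
            raise ValueError(f"missing values at (sample, gene): {bad}")
        if missing == "drop_sample":
            keep = ~bad_mask.any(axis=1)
            if not keep.any():
                raise ValueError("all samples have missing values")
            values = values[keep]
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        else:
            raise ValueError(f"unknown missing policy {missing!r}")

    return ExpressionMatrix(values, gene_ids, sample_ids, scale=scale)


def _first_nonnumeric_cell(df: pd.DataFrame) -> tuple[str, str]:
    for gene in df.columns:
        converted = pd.to_numeric(df[gene], errors="coerce")
        bad = converted.isna() & df[gene].notna()
        if bad.any():
            return str(df.index[bad.argmax()]), str(gene)
    return "?", "?"


def write_expression_table(matrix: ExpressionMatrix, path, sep: str = ",") -> None:
    """Write a wide table (samples x genes) losslessly (full float repr)."""
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_replicate_table(path, scale: Scale = "ct", sep: str | None = None) -> ReplicateTable:
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return ReplicateTable(df, scale=scale)


def average_replicates(table: ReplicateTable) -> ExpressionMatrix:
    """Average technical replicates of the same reaction.

    Returns the samples x genes matrix of arithmetic means per
    (sample, gene) group; the scale is inherited.  Every sample must have
    every gene measured at least once.
    """
    rec = table.records
    wide = rec.groupby(["sample", "gene"], sort=False)["value"].mean().unstack("gene")
    if wide.isna().any().any():
        missing = [
            (str(s), str(g))
            for s in wide.index
            for g in wide.columns
            if pd.isna(wide.loc[s, g])
        ]
        raise ValueError(f"missing (sample, gene) pairs: {missing}")
    return ExpressionMatrix(
        wide.to_numpy(dtype=float),
        gene_ids=[str(g) for g in wide.columns],
        sample_ids=[str(s) for s in wide.index],
        scale=table.scale,
        covariates=table.covariates,
    )


def ct_to_relative_expression(
    ct: ExpressionMatrix, anchor: Literal["min", "max"] = "min"
) -> ExpressionMatrix:
    """Convert Ct numbers to linear relative expression, gene by gene.

    With the default ``anchor="min"`` (geNorm convention),
    ``Q_ij = 2**(min_i Ct_ij - Ct_ij)``: values lie in (0, 1] with 1 at the
    sample with the smallest threshold cycle (largest copy number) of each
    gene.  ``anchor="max"`` flips the sign of the per-gene constant; the two
    differ only by a per-gene additive constant on the log scale, which
    cancels in every variance computation downstream.
    """
    ct.require_scale("ct")
    if anchor == "min":
        ref = ct.values.min(axis=0)
        values = np.exp2(ref - ct.values)
    elif anchor == "max":
        ref = ct.values.max(axis=0)
        values = np.exp2(ref - ct.values)
    else:
        raise ValueError(f"anchor must be 'min' or 'max', got {anchor!r}")
    return ExpressionMatrix(
        values,
        gene_ids=list(ct.gene_ids),
        sample_ids=list(ct.sample_ids),
        scale="linear_expression",
        covariates=ct.covariates,
    )


def log_transform(
    x: ExpressionMatrix, base: Literal["e", "2", 2] = "e"
) -> ExpressionMatrix:
    """Elementwise log of a linear-scale matrix (default natural log)."""
    x.require_scale("linear_expression")
    if np.any(x.values <= 0):
        bad = [
            (x.sample_ids[r], x.gene_ids[c])
            for r, c in zip(*np.where(x.values <= 0))
        ][:5]
        raise ValueError(f"nonpositive values at (sample, gene): {bad}")
    if base == "e":
        values = np.log(x.values)
    elif base in ("2", 2):
        values = np.log2(x.values)
    else:
        raise ValueError(f"base must be 'e' or 2, got {base!r}")
    return ExpressionMatrix(
        values,
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        scale="log_expression",
        covariates=x.covariates,
    )
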