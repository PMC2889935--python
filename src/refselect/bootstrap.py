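"""Bootstrap ranking of gene subsets and the A/B/C selection criteria.

Whole samples (rows) are resampled with replacement so that cross-gene
correlation is preserved.  For each of B bootstrap replicates the
unstructured covariance is re-estimated, the log-NF variance of every
nonempty subset is computed, and the subsets are ranked from smallest to
largest variance.  Per subset, the summary records the 95th percentile of
the bootstrap variances (the 95% UCL) and the average rank; the three
selection criteria operate on this summary:

A. minimize the 95% UCL of the log-NF variance;
B. minimize the subset size subject to the UCL (SD scale) being under an
   acceptable threshold;
C. minimize the average bootstrap rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refselect.covariance import DesignSpec, estimate_covariance
from refselect.data_io import ExpressionMatrix
from refselect.subsets import (
    GeneSubset,
    all_subset_variances,
    enumerate_subsets,
    rank_subsets,
    subset_indicator_matrix,
)

MAX_REDRAWS = 1000


@dataclass
class BootstrapSummary:
    """Per-subset bootstrap summary in canonical subset order.

    ``table`` columns: subset (indicator string), genes, size,
    point_variance (full-data estimate), ucl95_variance, ucl95_sd
    (= sqrt of the variance UCL), mean_rank.
    """

    table: pd.DataFrame
    subsets: list[GeneSubset]
    gene_ids: list[str]
    B: int
    seed: int | None
    n_redraws: int = 0
    replicate_variances: np.ndarray | None = None  # B x S, kept on request

    def best_by_size(self) -> pd.DataFrame:
        """For each subset size, the row with the smallest ucl95_variance."""
        idx = self.table.groupby("size")["ucl95_variance"].idxmin()
        return self.table.loc[idx].reset_index(drop=True)

    def top_by_rank(self, n: int = 10) -> pd.DataFrame:
        return (
            self.table.sort_values(["mean_rank", "size", "subset"])
            .head(n)
            .reset_index(drop=True)
        )


@dataclass
class SelectionResult:
    """Outcome of one selection criterion."""

    criterion: str
    subsets: list[GeneSubset]
    metrics: dict = field(default_factory=dict)
    threshold: float | None = None
    status: str = "ok"

    @property
    def subset(self) -> GeneSubset | None:
        return self.subsets[0] if self.subsets else None

    def to_json_dict(self, gene_ids: list[str] | None = None) -> dict:
        out = {
            "criterion": self.criterion,
            "status": self.status,
            "threshold": self.threshold,
            "metrics": self.metrics,
            "subsets": [s.indicator_string() for s in self.subsets],
        }
        if gene_ids is not None:
            out["genes"] = [s.gene_labels(gene_ids) for s in self.subsets]
        return out


def _bootstrap_variances_intercept(
    y: np.ndarray, indicators: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(B, S) log-NF variances from vectorized intercept-only resampling."""
    n = y.shape[0]
    idx = rng.integers(0, n, size=(B, n))
    yb = y[idx]  # B x N x J
    centered = yb - yb.mean(axis=1, keepdims=True)
    vb = np.einsum("bnj,bnk->bjk", centered, centered) / (n - 1)
    return all_subset_variances(vb, indicators)


def _bootstrap_variances_design(
    y: np.ndarray,
    a: np.ndarray,
    indicators: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Loop path for a non-trivial design; redraws rank-deficient replicates."""
    n, p = a.shape
    out = np.empty((B, indicators.shape[0]))
    redraws = 0
    for b in range(B):
        for _ in range(MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            ab = a[idx]
            if np.linalg.matrix_rank(ab) == p:
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"could not draw a full-rank bootstrap design in {MAX_REDRAWS} tries"
            )
        yb = y[idx]
        beta, *_ = np.linalg.lstsq(ab, yb, rcond=None)
        resid = yb - ab @ beta
        vb = (resid.T @ resid) / (n - p)
        out[b] = all_subset_variances(vb, indicators)
    return out, redraws


def bootstrap_selection(
    data: ExpressionMatrix,
    B: int = 1000,
    seed: int | None = None,
    design: DesignSpec | None = None,
    keep_replicates: bool = False,
) -> BootstrapSummary:
    """Resample samples with replacement and summarize all subset variances.

    Deterministic given ``seed``.  Bootstrap replicates with fewer than two
    distinct samples are legal (their subset variances are all zero); a
    replicate whose resampled design matrix loses rank is redrawn (counted
    and warned about).
    """
    n, j = data.values.shape
    if n < 3:
        raise ValueError(f"need N >= 3 samples to bootstrap, got {n}")
    if B < 1:
        raise ValueError("B must be >= 1")

    subsets = enumerate_subsets(j)
    indicators = subset_indicator_matrix(j)
    point = estimate_covariance(data, design)
    point_variances = all_subset_variances(point.V_hat, indicators)

    rng = np.random.default_rng(seed)
    redraws = 0
    if design is None or design.n_params == 1:
        variances = _bootstrap_variances_intercept(data.values, indicators, B, rng)
    else:
        variances, redraws = _bootstrap_variances_design(
            data.values, design.matrix, indicators, B, rng
        )
        if redraws:
            warnings.warn(
                f"{redraws} bootstrap replicate(s) redrawn for rank-deficient design",
                UserWarning,
                stacklevel=2,
            )

    ranks = rank_subsets(variances)
    ucl_var = np.percentile(variances, 95, axis=0, method="linear")
    mean_rank = ranks.mean(axis=0)

    table = pd.DataFrame(
        {
            "subset": [s.indicator_string() for s in subsets],
            "genes": [",".join(s.gene_labels(data.gene_ids)) for s in subsets],
            "size": [s.size for s in subsets],
            "point_variance": point_variances,
            "ucl95_variance": ucl_var,
            "ucl95_sd": np.sqrt(np.clip(ucl_var, 0.0, None)),
            "mean_rank": mean_rank,
        }
    )
    return BootstrapSummary(
        table=table,
        subsets=subsets,
        gene_ids=list(data.gene_ids),
        B=B,
        seed=seed,
        n_redraws=redraws,
        replicate_variances=variances if keep_replicates else None,
    )


def _argmin_canonical(values: np.ndarray) -> int:
    """First index attaining the minimum.

    Subsets are in canonical (size-major, lexicographic) order, so the
    first minimum implements the tie rule: smaller size, then
    lexicographically first.
    """
    return int(np.argmin(values))


def select_criterion_A(summary: BootstrapSummary) -> SelectionResult:
    """Smallest 95% UCL of the log-NF variance, any size."""
    i = _argmin_canonical(summary.table["ucl95_variance"].to_numpy())
    row = summary.table.iloc[i]
    return SelectionResult(
        criterion="A",
        subsets=[summary.subsets[i]],
        metrics={
            "ucl95_variance": float(row["ucl95_variance"]),
            "ucl95_sd": float(row["ucl95_sd"]),
        },
    )


def select_criterion_B(summary: BootstrapSummary, sd_threshold: float) -> SelectionResult:
    """Fewest genes with UCL (SD scale) under the acceptable threshold."""
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    tab = summary.table
    ok = tab[tab["ucl95_sd"] <= sd_threshold]
    if ok.empty:
        return SelectionResult(
            criterion="B",
            subsets=[],
            threshold=sd_threshold,
            status=f"no subset has ucl95_sd <= {sd_threshold:g}",
        )
    min_size = int(ok["size"].min())
    at_size = ok[ok["size"] == min_size]
    i = int(at_size["ucl95_sd"].idxmin())
    row = tab.loc[i]
    return SelectionResult(
        criterion="B",
        subsets=[summary.subsets[i]],
        threshold=sd_threshold,
        metrics={
            "size": min_size,
            "ucl95_variance": float(row["ucl95_variance"]),
            "ucl95_sd": float(row["ucl95_sd"]),
        },
    )


def select_criterion_C(summary: BootstrapSummary) -> SelectionResult:
    """Smallest average bootstrap rank of the log-NF variance."""
    i = _argmin_canonical(summary.table["mean_rank"].to_numpy())
    row = summary.table.iloc[i]
    return SelectionResult(
        criterion="C",
        subsets=[summary.subsets[i]],
        metrics={"mean_rank": float(row["mean_rank"])},
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def ucl_vs_rank_plotdata(
    summary: BootstrapSummary, rank_cutoff: float | None = None
) -> pd.DataFrame:
    """Coordinates for the UCL-vs-mean-rank scatter (criteria A and C).

    Each subset is a point (mean_rank, ucl95_sd); after min-max scaling
    both axes to [0, 1] over all subsets, ``normalized_distance`` is the
    Euclidean distance to the lower-left corner.  The subset closest to the
    origin is optimal under both criteria.  Rows are sorted by distance;
    ``rank_cutoff`` optionally drops subsets with mean rank above it (large
    J makes the full cloud unreadable).
    """
    tab = summary.table
    x = _minmax(tab["mean_rank"].to_numpy(dtype=float))
    y = _minmax(tab["ucl95_sd"].to_numpy(dtype=float))
    out = tab[["subset", "genes", "size", "mean_rank", "ucl95_sd"]].copy()
    out["normalized_distance"] = np.hypot(x, y)
    if rank_cutoff is not None:
        out = out[out["mean_rank"] < rank_cutoff]
    return out.sort_values(
        ["normalized_distance", "size", "subset"]
    ).reset_index(drop=True)


def top_subsets_by_size(summary: BootstrapSummary) -> pd.DataFrame:
    """Table-style report: best subset (by UCL) for each size."""
    best = summary.best_by_size()
    return _expand_indicators(best, summary.gene_ids)[
        ["size"] + summary.gene_ids + ["ucl95_variance", "ucl95_sd"]
    ]


def top_subsets_by_rank(summary: BootstrapSummary, n: int = 10) -> pd.DataFrame:
    """Table-style report: the n subsets with smallest mean rank."""
    top = summary.top_by_rank(n)
    return _expand_indicators(top, summary.gene_ids)[
        ["size"] + summary.gene_ids + ["mean_rank"]
    ]


def _expand_indicators(tab: pd.DataFrame, gene_ids: list[str]) -> pd.DataFrame:
    out = tab.copy()
    for g, gene in enumerate(gene_ids):
        out[gene] = [int(s[g]) for s in out["subset"]]
    return out
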