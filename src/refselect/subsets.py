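"""Exhaustive gene-subset enumeration and log-NF variance computation.

For a subset of L genes with 0/1 indicator vector C, the log normalizing
factor of sample i is F_i = C'y_i / L (the log of the geometric mean of the
linear expressions), and its variance under a joint covariance V is the
quadratic form C'VC / L^2.  All 2^J - 1 nonempty subsets are evaluated; the
minimum is always attained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from refselect.data_io import ANALYSIS_SCALES, ExpressionMatrix

#: Default guard against combinatorial blowup (2^20 - 1 ~ 1e6 subsets).
MAX_GENES = 20


@dataclass(frozen=True)
class GeneSubset:
    """A nonempty subset of the J candidate genes.

    ``genes`` holds the included 0-based column indices in increasing
    order; ``indicator`` is the corresponding length-J 0/1 vector.
    """

    genes: tuple[int, ...]
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("subset must be nonempty")
        if tuple(sorted(set(self.genes))) != self.genes:
            raise ValueError("genes must be strictly increasing indices")
        if self.genes[0] < 0 or self.genes[-1] >= self.n_genes:
            raise ValueError("gene index out of range")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def indicator(self) -> np.ndarray:
        c = np.zeros(self.n_genes, dtype=int)
        c[list(self.genes)] = 1
        return c

    def indicator_string(self) -> str:
        return "".join(map(str, self.indicator))

    def gene_labels(self, gene_ids: Sequence[str]) -> list[str]:
        return [gene_ids[g] for g in self.genes]

    @classmethod
    def from_indicator(cls, indicator) -> "GeneSubset":
        c = np.asarray(indicator)
        if not np.isin(c, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")
        return cls(tuple(int(i) for i in np.flatnonzero(c)), len(c))


def enumerate_subsets(n_genes: int, max_genes: int = MAX_GENES) -> list[GeneSubset]:
    """All 2^J - 1 nonempty subsets in canonical order.

    Order is deterministic: by size, then lexicographically on the sorted
    gene-index tuples (so {0,1} precedes {0,2} precedes {1,2}).
    """
    if not 1 <= n_genes <= max_genes:
        raise ValueError(f"n_genes must be in [1, {max_genes}], got {n_genes}")
    return [
        GeneSubset(genes, n_genes)
        for size in range(1, n_genes + 1)
        for genes in combinations(range(n_genes), size)
    ]


def subset_indicator_matrix(n_genes: int, max_genes: int = MAX_GENES) -> np.ndarray:
    """(2^J - 1) x J 0/1 matrix of all subset indicators, canonical order."""
    subsets = enumerate_subsets(n_genes, max_genes=max_genes)
    return np.array([s.indicator for s in subsets], dtype=float)


def log_geometric_mean(data: ExpressionMatrix, subset: GeneSubset) -> np.ndarray:
    """Per-sample log normalizing factor: mean of the subset's log columns."""
    data.require_scale(*ANALYSIS_SCALES)
    if subset.n_genes != data.n_genes:
        raise ValueError("subset dimension does not match data")
    return data.values[:, list(subset.genes)].mean(axis=1)


def subset_variance(V: np.ndarray, subset: GeneSubset, sym_tol: float = 1e-8) -> float:
    """Variance of the log NF for one subset: C'VC / L^2."""
    v = np.asarray(V, dtype=float)
    if v.shape != (subset.n_genes, subset.n_genes):
        raise ValueError("V dimension does not match subset")
    if not np.allclose(v, v.T, atol=sym_tol):
        raise ValueError("V must be symmetric")
    idx = list(subset.genes)
    block = v[np.ix_(idx, idx)]
    return float(block.sum()) / subset.size**2


def all_subset_variances(V: np.ndarray, indicators: np.ndarray) -> np.ndarray:
    """Quadratic forms C'VC / L^2 for every row C of ``indicators``.

    ``V`` may be a single J x J matrix or a stacked (..., J, J) array of
    matrices (one variance row per leading index) — the bootstrap path.
    """
    c = np.asarray(indicators, dtype=float)
    sizes = c.sum(axis=1)
    v = np.asarray(V, dtype=float)
    if v.ndim == 2:
        return np.einsum("sj,jk,sk->s", c, v, c) / sizes**2
    return np.einsum("sj,...jk,sk->...s", c, v, c) / sizes**2


def empirical_loggm_variance(data: ExpressionMatrix, subset: GeneSubset) -> float:
    """Unbiased sample variance (divisor N-1) of the computed log NF.

    Identical to ``subset_variance`` on the intercept-only estimated
    covariance of the same data — the quadratic-form identity used as this
    module's master oracle.
    """
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples for an empirical variance")
    f = log_geometric_mean(data, subset)
    return float(np.var(f, ddof=1))


def rank_subsets(variances: np.ndarray) -> np.ndarray:
    """Ranks from smallest (rank 1) to largest variance, ties averaged.

    Accepts a vector or a stacked (..., S) array ranked along the last
    axis.
    """
    return rankdata(np.asarray(variances, dtype=float), method="average", axis=-1)


def subset_variance_table(
    V: np.ndarray,
    gene_ids: Sequence[str],
    max_genes: int = MAX_GENES,
) -> pd.DataFrame:
    """One row per subset: indicator string, size, variance, sd, rank."""
    j = len(gene_ids)
    subsets = enumerate_subsets(j, max_genes=max_genes)
    indicators = np.array([s.indicator for s in subsets], dtype=float)
    variances = all_subset_variances(V, indicators)
    return pd.DataFrame(
        {
            "subset": [s.indicator_string() for s in subsets],
            "genes": [",".join(s.gene_labels(gene_ids)) for s in subsets],
            "size": [s.size for s in subsets],
            "variance": variances,
            "sd": np.sqrt(np.clip(variances, 0.0, None)),
            "rank": rank_subsets(variances),
        }
    )
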