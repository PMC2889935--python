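"""Comparator methods: geNorm stability ranking and the
independence-assuming (diagonal-covariance) subset scorer.

geNorm ranks candidate genes by the stability measure M: the average,
over all other candidates, of the standard deviation of the pairwise log
expression ratios.  The least stable gene (largest M) is removed and M is
recomputed on the remainder until two genes survive; the reversed
elimination order gives the ranking, with the surviving pair tied best.

The diagonal comparator scores a size-L subset by the sum of per-gene
variances divided by L^2 — optimal under independence, where the best
subset of each size is simply the L genes of smallest variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from refselect.covariance import residuals_fixed_sample_effects
from refselect.data_io import ANALYSIS_SCALES, ExpressionMatrix
from refselect.subsets import GeneSubset


@dataclass
class GeNormResult:
    """Outcome of the geNorm backward-elimination ranking."""

    gene_ids: list[str]
    pairwise_variation: np.ndarray  # J x J SDs of log ratios, diagonal 0
    rounds: pd.DataFrame  # columns: round, gene, M, eliminated
    elimination_order: list[int]  # gene indices, least stable first
    ranking: list[int]  # gene indices, most to least stable
    seed_pair: tuple[int, int]  # the last surviving (tied-best) pair

    def ranking_labels(self) -> list[str]:
        return [self.gene_ids[g] for g in self.ranking]

    def to_frame(self) -> pd.DataFrame:
        return self.rounds


@dataclass
class UncorrelatedComparatorResult:
    """Per-size best subsets under the independence assumption."""

    variances: np.ndarray
    per_size: pd.DataFrame  # columns: size, genes, score
    best_subset: GeneSubset
    best_score: float
    mode: str = "total"


def _resolve_gene(data: ExpressionMatrix, gene) -> int:
    if isinstance(gene, str):
        try:
            return data.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id {gene!r}") from None
    return int(gene)


def genorm_pairwise_variation(data: ExpressionMatrix, j, k) -> float:
    """SD (divisor N-1) of the pairwise log ratio of two genes.

    On the log scale the ratio of expressions is the difference of
    columns; genes may be given as indices or ids.
    """
    data.require_scale(*ANALYSIS_SCALES)
    j, k = _resolve_gene(data, j), _resolve_gene(data, k)
    if j == k:
        raise ValueError("pairwise variation of a gene with itself is undefined")
    diff = data.values[:, j] - data.values[:, k]
    return float(np.std(diff, ddof=1))


def _pairwise_variation_matrix(y: np.ndarray) -> np.ndarray:
    diffs = y[:, :, None] - y[:, None, :]  # N x J x J
    v = diffs.std(axis=0, ddof=1)
    np.fill_diagonal(v, 0.0)
    return v


def genorm_rank(data: ExpressionMatrix) -> GeNormResult:
    """Backward-elimination geNorm ranking of all candidate genes.

    At each round, M_j is the mean pairwise variation of gene j with the
    other remaining genes; the gene with the largest M (ties broken toward
    the larger index, matching sequential recomputation) is eliminated
    until two genes remain.  Equivalent to the forward description that
    seeds with the most agreeing pair: that pair is the one surviving last.
    """
    data.require_scale(*ANALYSIS_SCALES)
    n, j = data.values.shape
    if j < 3:
        raise ValueError(f"geNorm ranking needs at least 3 genes, got {j}")
    if n < 2:
        raise ValueError("need at least 2 samples")

    vmat = _pairwise_variation_matrix(data.values)
    remaining = list(range(j))
    elimination: list[int] = []
    rows = []
    rnd = 0
    while len(remaining) > 2:
        rnd += 1
        sub = vmat[np.ix_(remaining, remaining)]
        m = sub.sum(axis=1) / (len(remaining) - 1)
        worst_pos = int(np.argmax(m[::-1]))  # ties -> larger index
        worst_pos = len(remaining) - 1 - worst_pos
        worst = remaining[worst_pos]
        for pos, g in enumerate(remaining):
            rows.append(
                {
                    "round": rnd,
                    "gene": data.gene_ids[g],
                    "M": float(m[pos]),
                    "eliminated": g == remaining[worst_pos],
                }
            )
        elimination.append(worst)
        remaining.pop(worst_pos)

    # final pair: report its M values (equal by construction) without elimination
    rnd += 1
    sub = vmat[np.ix_(remaining, remaining)]
    m = sub.sum(axis=1) / (len(remaining) - 1)
    for pos, g in enumerate(remaining):
        rows.append(
            {"round": rnd, "gene": data.gene_ids[g], "M": float(m[pos]), "eliminated": False}
        )

    ranking = list(remaining) + list(reversed(elimination))
    return GeNormResult(
        gene_ids=list(data.gene_ids),
        pairwise_variation=vmat,
        rounds=pd.DataFrame(rows),
        elimination_order=elimination,
        ranking=ranking,
        seed_pair=(remaining[0], remaining[1]),
    )


def estimate_diagonal_variances(
    data: ExpressionMatrix, mode: str = "total"
) -> np.ndarray:
    """Per-gene variances for the independence-assuming comparator.

    ``mode="total"``: plain per-gene sample variances — the diagonal of the
    intercept-only covariance estimate.  ``mode="innate"``: variances of
    the residual columns after removing fixed per-sample effects by
    unweighted means (the shared experimental component subtracted out,
    but biased downward by the subtraction).  ``mode="innate_reml"``: the
    heteroscedastic fixed-sample-effect model fitted properly — per-gene
    error variances tau_j^2 with sample effects estimated by precision
    weighting, iterated to the REML stationary point (see
    :func:`heteroscedastic_innate_variances`).  This is the estimator the
    diagonal-model comparator assumes, and the one to use when comparing
    selection methods head to head.
    """
    data.require_scale(*ANALYSIS_SCALES)
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if mode == "total":
        return np.var(data.values, axis=0, ddof=1)
    if mode == "innate":
        resid = residuals_fixed_sample_effects(data)
        return np.var(resid, axis=0, ddof=1)
    if mode == "innate_reml":
        return heteroscedastic_innate_variances(data.values)
    raise ValueError(
        f"mode must be 'total', 'innate' or 'innate_reml', got {mode!r}"
    )


def heteroscedastic_innate_variances(
    y: np.ndarray,
    max_iter: int = 200,
    rtol: float = 1e-12,
    floor: float = 1e-10,
) -> np.ndarray:
    """REML variance estimates of the diagonal fixed-sample-effect model.

    Model: y_ij = g_j + s_i + e_ij with fixed sample effects s_i and
    independent heteroscedastic errors e_ij ~ N(0, tau_j^2).  The sample
    effects are estimated by precision-weighted means and each tau_j^2 by
    its REML stationary condition

        sum_i r_ij^2 = tau_j^2 * (N - 1 - (N - 1) * w_j / W),

    with w_j = 1/tau_j^2 and W = sum_k w_k (the divisor discounts the df
    absorbed by the gene mean and by gene j's share of the N sample
    effects).  Fixed point reached by simple iteration from the unweighted
    residual variances.
    """
    y = np.asarray(y, dtype=float)
    n, j = y.shape
    if j < 2:
        raise ValueError("need at least 2 genes to separate the sample effect")
    if n < 3:
        raise ValueError("need at least 3 samples")
    g = y.mean(axis=0)
    centered = y - g
    tau = np.clip(
        np.var(centered - centered.mean(axis=1, keepdims=True), axis=0, ddof=1),
        floor,
        None,
    )
    for _ in range(max_iter):
        w = 1.0 / tau
        s = ((y - g) * w).sum(axis=1) / w.sum()
        g = (y - s[:, None]).mean(axis=0)
        resid = y - g - s[:, None]
        df = n - 1 - (n - 1) * w / w.sum()
        new = np.clip((resid**2).sum(axis=0) / df, floor, None)
        if np.allclose(new, tau, rtol=rtol):
            return new
        tau = new
    return tau


def uncorrelated_subset_table(
    variances: np.ndarray, mode: str = "total"
) -> UncorrelatedComparatorResult:
    """Best subset per size under independence, and the overall minimum.

    The size-L best subset is the L genes with smallest variances (stable
    argsort: ties keep the lower index); its score is the variance sum over
    L^2.  The overall pick is the argmin over sizes, ties toward the
    smaller size.
    """
    v = np.asarray(variances, dtype=float)
    if v.ndim != 1:
        raise ValueError("variances must be a vector")
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    j = v.size
    order = np.argsort(v, kind="stable")
    rows = []
    best_score = np.inf
    best_genes: tuple[int, ...] = ()
    for size in range(1, j + 1):
        genes = tuple(sorted(int(g) for g in order[:size]))
        score = float(v[list(genes)].sum()) / size**2
        rows.append({"size": size, "genes": genes, "score": score})
        if score < best_score:
            best_score = score
            best_genes = genes
    return UncorrelatedComparatorResult(
        variances=v,
        per_size=pd.DataFrame(rows),
        best_subset=GeneSubset(best_genes, j),
        best_score=best_score,
        mode=mode,
    )
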