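"""Estimation of the unstructured total covariance matrix V.

The candidate genes' log expressions within a sample are modeled jointly
as multivariate normal with mean ``A @ beta`` (intercept-only by default)
and an unstructured J x J covariance V.  Because the per-gene mean model is
a saturated linear model and V is unconstrained, ordinary least squares
residual cross-products give the exact (REML-divisor) estimate in closed
form: V_hat = E'E / (N - p).  Intercept-only reduces to the textbook
unbiased sample covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from refselect.data_io import ANALYSIS_SCALES, ExpressionMatrix


@dataclass
class DesignSpec:
    """Per-sample design matrix for the mean model.

    The first column must be the intercept; covariate columns (e.g. tissue
    indicators) follow.  ``matrix`` is N x p with full column rank.
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if not self.labels:
            self.labels = [f"x{i}" for i in range(self.matrix.shape[1])]
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("label count does not match design columns")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def intercept_only(cls, n_samples: int) -> "DesignSpec":
        return cls(np.ones((n_samples, 1)), ["intercept"])

    @classmethod
    def from_categories(cls, categories) -> "DesignSpec":
        """Intercept + treatment-coded dummies for a categorical factor."""
        cat = pd.Categorical(categories)
        dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
        mat = np.column_stack([np.ones(len(cat)), dummies.to_numpy()])
        return cls(mat, ["intercept"] + [str(c) for c in dummies.columns])


@dataclass
class CovarianceEstimate:
    """Estimated total covariance V_hat with the fitted mean model."""

    V_hat: np.ndarray
    beta_hat: np.ndarray  # p x J fixed-effect estimates (column means if intercept-only)
    n_samples: int
    df: int  # residual degrees of freedom N - p
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.V_hat = np.asarray(self.V_hat, dtype=float)
        j = self.V_hat.shape[0]
        if self.V_hat.shape != (j, j):
            raise ValueError("V_hat must be square")
        if not np.allclose(self.V_hat, self.V_hat.T, atol=1e-8):
            raise ValueError("V_hat must be symmetric")
        if self.df < 1:
            raise ValueError("residual degrees of freedom must be >= 1")

    @property
    def g_hat(self) -> np.ndarray:
        """Intercept row of beta_hat (per-gene mean level)."""
        return np.asarray(self.beta_hat)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V_hat, index=self.gene_ids, columns=self.gene_ids)

    def to_json_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "V_hat": self.V_hat.tolist(),
            "beta_hat": np.asarray(self.beta_hat).tolist(),
            "n_samples": self.n_samples,
            "df": self.df,
        }


def estimate_covariance(
    data: ExpressionMatrix, design: DesignSpec | None = None
) -> CovarianceEstimate:
    """Estimate the unstructured covariance of gene log expressions.

    Fits each gene column on the design by OLS and forms
    ``V_hat = E'E / (N - p)`` from the residual matrix E.  With the default
    intercept-only design this is the unbiased sample covariance (divisor
    N - 1) and ``beta_hat`` holds the column means.

    Raises if N <= p or the design is rank deficient; warns (does not fail)
    when N <= (J + 3) / 2, where the model is weakly identified.
    """
    data.require_scale(*ANALYSIS_SCALES)
    y = data.values
    n, j = y.shape
    if design is None:
        design = DesignSpec.intercept_only(n)
    a = design.matrix
    if a.shape[0] != n:
        raise ValueError(f"design has {a.shape[0]} rows for {n} samples")
    p = a.shape[1]
    if n <= p:
        raise ValueError(f"need more samples than mean parameters (N={n}, p={p})")
    if np.linalg.matrix_rank(a) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= (j + 3) / 2:
        warnings.warn(
            f"N={n} <= (J+3)/2={(j + 3) / 2:g}: covariance model weakly identified",
            UserWarning,
            stacklevel=2,
        )

    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ beta
    v_hat = (resid.T @ resid) / (n - p)
    v_hat = (v_hat + v_hat.T) / 2.0  # enforce exact symmetry
    return CovarianceEstimate(
        V_hat=v_hat,
        beta_hat=beta,
        n_samples=n,
        df=n - p,
        gene_ids=list(data.gene_ids),
    )


def residuals_fixed_sample_effects(data: ExpressionMatrix) -> np.ndarray:
    """Residuals after removing per-gene means and fixed per-sample effects.

    Two-way additive fit by unweighted means: g_hat_j is the gene column
    mean, s_hat_i the row mean of gene-centered values, and the residual is
    ``y_ij - g_hat_j - s_hat_i``.  With the shared sample effect removed,
    the residuals carry only innate between-individual variation.  Residual
    rows and columns each sum to zero.
    """
    data.require_scale(*ANALYSIS_SCALES)
    y = data.values
    if y.shape[1] < 2:
        raise ValueError("need at least 2 genes to separate the sample effect")
    g_hat = y.mean(axis=0, keepdims=True)
    centered = y - g_hat
    s_hat = centered.mean(axis=1, keepdims=True)
    return centered - s_hat


def residual_correlations(residuals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations of residual columns with p-values.

    Returns ``(r, p)``: J x J matrices with unit diagonal and two-sided
    p-values from the t distribution on N - 2 degrees of freedom.
    Zero-variance columns yield NaN entries and a warning rather than a
    silent 0.
    """
    resid = np.asarray(residuals, dtype=float)
    n, j = resid.shape
    if n < 3:
        raise ValueError(f"need N >= 3 samples for correlation tests, got {n}")

    # constant columns detected exactly via range (std of a constant
    # column can be a few ulps above zero after mean subtraction)
    degenerate = np.where(np.ptp(resid, axis=0) == 0)[0]
    if degenerate.size:
        warnings.warn(
            f"zero-variance residual columns {degenerate.tolist()}: "
            "correlations undefined (NaN)",
            UserWarning,
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(resid, rowvar=False)
        r = np.asarray(r, dtype=float)
        np.fill_diagonal(r, 1.0)
        r_clipped = np.clip(r, -1.0, 1.0)
        t = r_clipped * np.sqrt((n - 2) / (1.0 - r_clipped**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, 0.0)
    # exact +/-1 correlations: t is infinite, sf gives 0 already via inf
    p = np.where(np.abs(r_clipped) == 1.0, np.where(np.eye(j, dtype=bool), p, 0.0), p)
    if degenerate.size:
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
        p[degenerate, :] = np.nan
        p[:, degenerate] = np.nan
        for d in degenerate:
            r[d, d] = np.nan
    return r, p
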