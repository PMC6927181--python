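"""Pearson residuals under the regularized model, variable-gene ranking, and
second-round regression with extra covariates.

Given regularized parameters (beta0_i, beta1_i, theta_i) the transformation
is an affine function of the counts:

    mu_ij    = exp(beta0_i + beta1_i * log10 m_j)
    sigma_ij = sqrt(mu_ij + mu_ij^2 / theta_i)
    z_ij     = (x_ij - mu_ij) / sigma_ij

Residuals are clipped symmetrically to +/- sqrt(N) (N = number of cells) to
bound the leverage of outlier cells. The residual matrix is the normalized
output of the whole pipeline: depth-independent, variance-stabilized values
suitable for variable-gene selection, PCA and differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .glm_core import THETA_CAP, _irls_batch  # noqa: F401 (cap reused by callers)

logger = logging.getLogger(__name__)


@dataclass
class ResidualMatrix:
    """Dense gene × cell matrix of (clipped) Pearson residuals."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    clip_value: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("residual matrix shape does not match identifiers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CovariateSpec:
    """A per-cell nuisance covariate for the second regression round.

    Categorical covariates are expanded to indicator columns with the first
    (sorted) level as reference; numeric covariates are used as-is. Unlike
    sequencing depth, these coefficients are never regularized across genes.
    """

    name: str
    values: np.ndarray | list = field(default_factory=list)

    def design_columns(self, n_cells: int) -> tuple[np.ndarray, list[str]]:
        vals = np.asarray(self.values)
        if vals.shape[0] != n_cells:
            raise ValueError(
                f"covariate {self.name!r} has {vals.shape[0]} values "
                f"for {n_cells} cells"
            )
        if vals.dtype.kind in "ifu" and vals.dtype != bool:
            col = vals.astype(float)
            if np.all(col == 0):
                logger.warning("covariate %r is identically zero; dropped", self.name)
                return np.zeros((n_cells, 0)), []
            return col[:, None], [self.name]
        levels = sorted(pd.unique(vals).tolist())
        if len(levels) < 2:
            return np.zeros((n_cells, 0)), []
        cols = [(vals == lev).astype(float) for lev in levels[1:]]
        names = [f"{self.name}[{lev}]" for lev in levels[1:]]
        return np.column_stack(cols), names


def _model_arrays(model: pd.DataFrame, gene_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [g for g in gene_ids if g not in model.index]
    if missing:
        raise ValueError(f"no regularized parameters for genes: {missing[:5]} ...")
    sub = model.loc[list(gene_ids)]
    b0 = sub["beta0_reg"].to_numpy(dtype=float)
    b1 = sub["beta1_reg"].to_numpy(dtype=float)
    th = sub["theta_reg"].to_numpy(dtype=float)
    bad = ~(np.isfinite(b0) & np.isfinite(b1) & np.isfinite(th) & (th > 0))
    if bad.any():
        raise ValueError(
            "non-finite or non-positive regularized parameters for gene(s): "
            f"{[list(gene_ids)[i] for i in np.flatnonzero(bad)[:5]]}"
        )
    return b0, b1, th


def pearson_residuals(
    counts: CountMatrix,
    model: pd.DataFrame,
    depths,
    clip: str | float = "sqrt_n",
) -> ResidualMatrix:
    """Transform counts into clipped Pearson residuals.

    Parameters
    ----------
    counts : CountMatrix restricted to modeled genes
    model : RegularizedModelTable (DataFrame with beta0_reg, beta1_reg,
        theta_reg indexed by gene_id); must cover every gene in ``counts``
    depths : (n_cells,) per-cell total UMI consistent with ``counts``
    clip : "sqrt_n" (default, clip at +/- sqrt(n_cells)), "none", or a
        positive float for a custom symmetric clip value
    """
    m = np.asarray(depths, dtype=float)
    if m.shape[0] != counts.n_cells:
        raise ValueError("depths length does not match number of cells")
    genes = [g for g in counts.gene_ids if g in model.index]
    if len(genes) < counts.n_genes:
        dropped = counts.n_genes - len(genes)
        logger.info("%d gene(s) without model parameters are excluded", dropped)
        counts = counts.subset_genes([counts.gene_ids.index(g) for g in genes])
    b0, b1, th = _model_arrays(model, counts.gene_ids)

    t = np.log10(m)
    mu = np.exp(b0[:, None] + b1[:, None] * t[None, :])
    sigma = np.sqrt(mu + mu * mu / th[:, None])
    x = counts.to_dense()
    z = (x - mu) / sigma

    if clip == "sqrt_n":
        clip_value = float(np.sqrt(counts.n_cells))
    elif clip == "none" or clip is None:
        clip_value = None
    else:
        clip_value = float(clip)
        if clip_value <= 0:
            raise ValueError("custom clip value must be positive")
    if clip_value is not None:
        np.clip(z, -clip_value, clip_value, out=z)
    return ResidualMatrix(z, list(counts.gene_ids), list(counts.cell_ids), clip_value)


def residual_summaries(res: ResidualMatrix) -> pd.DataFrame:
    """Per-gene mean and unbiased variance of residuals across cells."""
    if res.n_genes == 0 or res.n_cells == 0:
        raise ValueError("empty residual matrix")
    mean = res.values.mean(axis=1)
    var = res.values.var(axis=1, ddof=1) if res.n_cells > 1 else np.zeros(res.n_genes)
    return pd.DataFrame(
        {"residual_mean": mean, "residual_variance": var},
        index=pd.Index(res.gene_ids, name="gene_id"),
    )


def rank_variable_genes(
    res: ResidualMatrix, top_n: int | None = None, gmeans: pd.Series | None = None
) -> pd.DataFrame:
    """Rank genes by residual variance (descending): highly variable genes.

    Genes whose variance is not explained by sampling noise under the model
    (residual variance well above 1) carry biological heterogeneity. Ties are
    broken by geometric mean descending (when ``gmeans`` is given), then by
    gene id lexicographically.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    summ = residual_summaries(res)
    df = summ.copy()
    df["gmean"] = (
        gmeans.reindex(df.index).to_numpy() if gmeans is not None else 0.0
    )
    df = df.sort_values(
        by=["residual_variance", "gmean", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    if top_n is not None:
        df = df.head(top_n)
    return df[["residual_variance", "gmean"]]


def fit_with_covariates(
    counts: CountMatrix,
    depths,
    model: pd.DataFrame,
    covariates: list[CovariateSpec],
    clip: str | float = "sqrt_n",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[ResidualMatrix, pd.DataFrame]:
    """Second-round NB regression with additional nuisance covariates.

    The depth-dependent part beta0_reg + beta1_reg * log10(m) enters as a
    fixed offset and theta stays at its regularized value; only the covariate
    coefficients are free. Pearson residuals of this round are the normalized
    output.

    Returns (residuals, coefficient table with one column per design column).
    """
    m = np.asarray(depths, dtype=float)
    b0, b1, th = _model_arrays(model, counts.gene_ids)
    t = np.log10(m)
    offset = b0[:, None] + b1[:, None] * t[None, :]

    cols, names = [], []
    for cov in covariates:
        c, n = cov.design_columns(counts.n_cells)
        if c.shape[1]:
            cols.append(c)
            names.extend(n)
    if not cols:
        res = pearson_residuals(counts, model, depths, clip=clip)
        return res, pd.DataFrame(index=pd.Index(counts.gene_ids, name="gene_id"))
    C = np.column_stack(cols)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(m)), C]))
    if rank < C.shape[1] + 1:
        raise ValueError(
            f"rank-deficient covariate design (columns: {names}); "
            "remove collinear covariates"
        )

    x = counts.to_dense()
    G, n = x.shape
    p = C.shape[1]
    gamma = np.zeros((G, p))
    theta_col = th[:, None]
    for _ in range(max_iter):
        eta = np.clip(offset + gamma @ C.T, -690, 690)
        mu = np.maximum(np.exp(eta), 1e-300)
        w = mu / (1.0 + mu / theta_col)
        z = (eta - offset) + (x - mu) / mu
        # per-gene weighted least squares on the covariate design
        A = np.einsum("gn,np,nq->gpq", w, C, C)
        b = np.einsum("gn,np->gp", w * z, C)
        new = np.linalg.solve(A + 1e-12 * np.eye(p), b[:, :, None])[:, :, 0]
        if np.max(np.abs(new - gamma)) < tol:
            gamma = new
            break
        gamma = new

    eta = np.clip(offset + gamma @ C.T, -690, 690)
    mu = np.exp(eta)
    sigma = np.sqrt(mu + mu * mu / theta_col)
    z = (x - mu) / sigma
    if clip == "sqrt_n":
        cv = float(np.sqrt(n))
    elif clip == "none" or clip is None:
        cv = None
    else:
        cv = float(clip)
    if cv is not None:
        np.clip(z, -cv, cv, out=z)
    coef = pd.DataFrame(gamma, index=pd.Index(counts.gene_ids, name="gene_id"),
                        columns=names)
    return ResidualMatrix(z, list(counts.gene_ids), list(counts.cell_ids), cv), coef


def log_normalize(counts: CountMatrix, depths=None, scale: float = 1e4) -> ResidualMatrix:
    """Size-factor baseline: log(scale * x_ij / m_j + 1).

    This is the comparator the residual approach is benchmarked against, not
    part of the model itself.
    """
    m = (
        np.asarray(depths, dtype=float)
        if depths is not None
        else np.asarray(counts.values.sum(axis=0), dtype=float).ravel()
    )
    if np.any(m <= 0):
        raise ValueError("all cell depths must be positive")
    x = counts.to_dense()
    vals = np.log1p(scale * x / m[None, :])
    return ResidualMatrix(vals, list(counts.gene_ids), list(counts.cell_ids), None)
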