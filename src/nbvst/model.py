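"""Model/Results interface tying the pipeline together.

:class:`RegularizedNBModel` is constructed from a count matrix and holds the
configuration; :meth:`RegularizedNBModel.fit` runs the three-step procedure

1. per-gene GLM fits of counts on log10 depth for a density-weighted subset
   of genes,
2. kernel regularization of (beta0, beta1, theta) against log10 geometric
   gene mean, evaluated for every gene,
3. the affine transformation of counts into clipped Pearson residuals,

and returns a :class:`VSTResults` carrying the raw and regularized parameter
tables, the residual matrix, per-gene residual summaries and diagnostics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de_test as _de
from . import diagnostics as _diag
from .counts_io import (
    CountMatrix,
    compute_depths,
    drop_empty_cells,
    filter_genes,
    gene_means,
    load_counts,
)
from .glm_core import fit_gene_models
from .regularization import regularize, sample_estimation_genes
from .transform import (
    CovariateSpec,
    ResidualMatrix,
    fit_with_covariates,
    pearson_residuals,
    rank_variable_genes,
    residual_summaries,
)


class RegularizedNBModel:
    """Regularized negative binomial regression of UMI counts on depth.

    Parameters
    ----------
    counts : CountMatrix
        Gene × cell UMI counts. Empty cells are dropped and genes detected
        in fewer than ``min_cells`` cells filtered at construction.
    min_cells : int
        Detection threshold for keeping a gene (default 5 cells).
    n_genes : int
        Size of the density-weighted gene subset used in the initial GLM
        fitting step (default 2000; all genes when fewer).
    method : {"poisson_theta", "poisson_theta_refit", "nb_alternating"}
        Per-gene estimation method (default the fastest, ``poisson_theta``;
        the three yield near-identical residuals).
    baf : float
        Bandwidth adjustment factor multiplying the Sheather-Jones plug-in
        bandwidth in the regularization step (default 3).
    epsilon : float
        Pseudo-offset of the geometric mean (default 1).
    clip : {"sqrt_n", "none"} or float
        Residual clipping rule (default +/- sqrt(number of cells)).
    seed : int
        Governs gene subsampling (and any downstream resampling).
    """

    def __init__(
        self,
        counts: CountMatrix,
        min_cells: int = 5,
        n_genes: int = 2000,
        method: str = "poisson_theta",
        baf: float = 3.0,
        epsilon: float = 1.0,
        clip="sqrt_n",
        seed: int = 0,
    ):
        counts = drop_empty_cells(counts)
        self.counts = filter_genes(counts, min_cells=min_cells)
        self.depths = compute_depths(self.counts)
        self.min_cells = min_cells
        self.n_genes = n_genes
        self.method = method
        self.baf = baf
        self.epsilon = epsilon
        self.clip = clip
        self.seed = seed

    @classmethod
    def from_path(cls, path: str, fmt: str = "mtx_dir", **kwargs) -> "RegularizedNBModel":
        return cls(load_counts(path, fmt=fmt), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RegularizedNBModel":
        import scipy.sparse as sp

        counts = CountMatrix(
            sp.csr_matrix(df.to_numpy()),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
        )
        return cls(counts, **kwargs)

    def fit(self, covariates: list[CovariateSpec] | None = None) -> "VSTResults":
        gm = gene_means(self.counts, epsilon=self.epsilon)
        gm = gm[gm["gmean"] > 0]
        subset = sample_estimation_genes(gm, n_genes=self.n_genes, seed=self.seed)
        raw = fit_gene_models(
            self.counts, self.depths, method=self.method, genes=subset,
            epsilon=self.epsilon,
        )
        reg, bandwidths = regularize(raw, gm, baf=self.baf)
        coef = None
        if covariates:
            res, coef = fit_with_covariates(
                self.counts, self.depths, reg, covariates, clip=self.clip
            )
        else:
            res = pearson_residuals(self.counts, reg, self.depths, clip=self.clip)
        return VSTResults(
            model=self,
            gene_models=raw,
            regularized=reg,
            bandwidths=bandwidths,
            residuals=res,
            gene_means=gm,
            covariate_coefficients=coef,
        )


@dataclass
class VSTResults:
    """Fitted pipeline: parameter tables, residuals and diagnostics."""

    model: RegularizedNBModel
    gene_models: pd.DataFrame
    regularized: pd.DataFrame
    bandwidths: dict
    residuals: ResidualMatrix
    gene_means: pd.DataFrame
    covariate_coefficients: pd.DataFrame | None = None

    def __post_init__(self):
        self.gene_summary = residual_summaries(self.residuals)

    # ------------------------------------------------------------------ #
    def rank_variable_genes(self, top_n: int | None = None) -> pd.DataFrame:
        return rank_variable_genes(
            self.residuals, top_n=top_n, gmeans=self.gene_means["gmean"]
        )

    def confidence_intervals(self, level: float = 0.95) -> pd.DataFrame:
        return _diag.confidence_intervals(self.gene_models, level=level)

    def bin_genes(self, n_bins: int = 6) -> pd.Series:
        return _diag.bin_genes(self.gene_means.loc[self.residuals.gene_ids], n_bins)

    def variance_contribution(self, n_cell_bins: int = 5, n_gene_bins: int = 6):
        return _diag.variance_contribution(
            self.residuals, self.model.depths, self.bin_genes(n_gene_bins),
            n_cell_bins,
        )

    def expression_trend(self, n_gene_bins: int = 6, **kwargs) -> pd.DataFrame:
        return _diag.expression_trend(
            self.residuals, self.model.depths, self.bin_genes(n_gene_bins), **kwargs
        )

    def differential_expression(self, labels, **kwargs) -> pd.DataFrame:
        return _de.differential_expression(
            self.residuals, labels, counts=self.model.counts, **kwargs
        )

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        """Plain-text overview of the fit."""
        n_genes, n_cells = self.model.counts.n_genes, self.model.counts.n_cells
        rv = self.gene_summary["residual_variance"]
        rm = self.gene_summary["residual_mean"]
        lines = [
            "Regularized NB regression (variance-stabilizing transformation)",
            "=" * 64,
            f"genes: {n_genes}   cells: {n_cells}   "
            f"estimation subset: {len(self.gene_models)}",
            f"method: {self.model.method}   BAF: {self.model.baf}   "
            f"clip: +/-{self.residuals.clip_value:.2f}"
            if self.residuals.clip_value
            else f"method: {self.model.method}   BAF: {self.model.baf}   clip: none",
            f"depth: median {np.median(self.model.depths):.0f} UMI "
            f"[{self.model.depths.min():.0f}, {self.model.depths.max():.0f}]",
            "-" * 64,
            "bandwidths (SJ x BAF): "
            + "  ".join(f"{k}={v:.4f}" for k, v in self.bandwidths.items()),
            f"residual mean:     median {rm.median():+.4f}",
            f"residual variance: median {rv.median():.4f}  "
            f"(genes with variance > 1.5: {(rv > 1.5).sum()})",
            "-" * 64,
            "top variable genes:",
        ]
        top = self.rank_variable_genes(top_n=5)
        for g, row in top.iterrows():
            lines.append(
                f"  {g:<16s} residual variance {row['residual_variance']:8.2f}   "
                f"gmean {row['gmean']:.3f}"
            )
        return "\n".join(lines)

    def save(self, out_dir: str) -> None:
        """Write residuals.tsv, gene_summary.tsv, model.tsv, manifest.json."""
        os.makedirs(out_dir, exist_ok=True)
        self.residuals.to_frame().to_csv(
            os.path.join(out_dir, "residuals.tsv"), sep="\t"
        )
        self.gene_summary.to_csv(os.path.join(out_dir, "gene_summary.tsv"), sep="\t")
        merged = self.regularized.join(self.gene_models, how="left", rsuffix="_raw")
        merged.to_csv(os.path.join(out_dir, "model.tsv"), sep="\t")
        manifest = {
            "n_genes": self.model.counts.n_genes,
            "n_cells": self.model.counts.n_cells,
            "method": self.model.method,
            "baf": self.model.baf,
            "n_genes_estimation": int(len(self.gene_models)),
            "min_cells": self.model.min_cells,
            "seed": self.model.seed,
            "bandwidths": {k: float(v) for k, v in self.bandwidths.items()},
            "clip_value": self.residuals.clip_value,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
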