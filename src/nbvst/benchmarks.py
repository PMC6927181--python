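"""External benchmarks against the 33k-PBMC reference dataset.

These routines reproduce the published full-scale results on the 10x
Genomics "33k PBMCs from a Healthy Donor, v1 Chemistry" dataset. The data
(~100 MB) is not bundled; point ``data_dir`` at the extracted cellranger
matrix directory (matrix.mtx + genes.tsv + barcodes.tsv). The downsampling
DE benchmark additionally needs a per-cell type annotation (TSV: barcode,
cell_type) since monocyte subsets are defined by clustering, which is out
of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts_io import compute_depths, drop_empty_cells, filter_genes, load_counts
from .de_test import differential_expression
from .model import RegularizedNBModel
from .simulate import downsample_umis
from .transform import log_normalize

PBMC_DEFAULT_DIR = "data/pbmc33k"


def dataset_stats(data_dir: str = PBMC_DEFAULT_DIR, min_cells: int = 5) -> dict:
    """Cell and detected-gene counts of the reference dataset."""
    counts = drop_empty_cells(load_counts(data_dir, fmt="mtx_dir"))
    filtered = filter_genes(counts, min_cells=min_cells)
    return {
        "n_cells": counts.n_cells,
        "n_genes_detected": filtered.n_genes,
    }


def method_agreement(counts, n_genes: int = 2000, seed: int = 42,
                     max_cells: int | None = None) -> float:
    """Median per-gene correlation of residuals across the three estimation
    methods (minimum over the three method pairs)."""
    counts = filter_genes(drop_empty_cells(counts), 5)
    if max_cells is not None and counts.n_cells > max_cells:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(counts.n_cells, max_cells, replace=False))
        counts = counts.subset_cells(keep)
    residuals = {}
    for method in ("poisson_theta", "poisson_theta_refit", "nb_alternating"):
        res = RegularizedNBModel(counts, n_genes=n_genes, method=method,
                                 seed=seed).fit()
        residuals[method] = res.residuals
    medians = []
    keys = list(residuals)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = residuals[keys[i]], residuals[keys[j]]
            common = [g for g in a.gene_ids if g in set(b.gene_ids)]
            av = a.to_frame().loc[common].to_numpy()
            bv = b.to_frame().loc[common].to_numpy()
            ac = av - av.mean(axis=1, keepdims=True)
            bc = bv - bv.mean(axis=1, keepdims=True)
            cors = (ac * bc).sum(axis=1) / np.sqrt(
                (ac**2).sum(axis=1) * (bc**2).sum(axis=1)
            )
            medians.append(float(np.median(cors)))
    return min(medians)


def downsampling_de_counts(
    data_dir: str = PBMC_DEFAULT_DIR,
    labels_path: str = "data/pbmc33k/cell_types.tsv",
    cell_type: str = "CD14+ Monocyte",
    fraction: float = 0.5,
    seed: int = 42,
) -> dict:
    """Significant DE gene counts for the split-and-downsample experiment.

    Cells of one annotated type are split in half, one half binomially
    thinned to ``fraction`` of its depth, and DE is run between the halves
    on log-normalized values and on Pearson residuals. With perfect
    normalization no gene should be called.
    """
    counts = drop_empty_cells(load_counts(data_dir, fmt="mtx_dir"))
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    keep = [j for j, c in enumerate(counts.cell_ids) if labels.get(c) == cell_type]
    if not keep:
        raise ValueError(f"no cells annotated {cell_type!r}")
    sub = counts.subset_cells(keep)
    rng = np.random.default_rng(seed)
    half = rng.permutation(sub.n_cells) < sub.n_cells // 2
    thinned = downsample_umis(sub, fraction, cells=half, seed=seed + 1)
    groups = np.where(half, "down", "full")
    model = RegularizedNBModel(thinned, seed=seed + 2)
    res = model.fit()
    de_res = differential_expression(res.residuals, groups, counts=model.counts,
                                     seed=seed + 3)
    ln = log_normalize(model.counts, compute_depths(model.counts))
    de_ln = differential_expression(ln, groups, counts=model.counts, seed=seed + 3)
    return {
        "n_de_lognorm": int(de_ln["significant"].sum()),
        "n_de_residuals": int(de_res["significant"].sum()),
        "n_cells": sub.n_cells,
    }
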