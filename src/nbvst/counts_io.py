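"""Count-matrix input/output and basic summaries.

UMI count matrices are held gene × cell (genes are rows), matching the
indexing convention x_ij = count of gene i in cell j used throughout the
package. Readers for the 10x cellranger Matrix Market layout and for dense
TSV normalize to this orientation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1.0
DEFAULT_MIN_CELLS = 5


@dataclass
class CountMatrix:
    """Sparse gene × cell matrix of UMI counts with identifiers.

    Parameters
    ----------
    values : scipy.sparse.csr_matrix
        Nonnegative integer counts, genes as rows, cells as columns.
    gene_ids, cell_ids : list of str
        Unique row / column identifiers.
    """

    values: sp.csr_matrix
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.nnz:
            data = self.values.data
            if np.any(data < 0):
                raise ValueError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("count matrix contains non-integer entries")
        n_genes, n_cells = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene{i}" for i in range(n_genes)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{j}" for j in range(n_cells)]
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.values[index],
            [self.gene_ids[i] for i in index],
            list(self.cell_ids),
        )

    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.values[:, index],
            list(self.gene_ids),
            [self.cell_ids[j] for j in index],
        )


def _deduplicate(names: list[str]) -> list[str]:
    """Disambiguate duplicates deterministically: ACTB, ACTB.1, ACTB.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _read_sidecar(mtx_dir: str, candidates: tuple[str, ...], what: str) -> pd.DataFrame:
    for name in candidates:
        path = os.path.join(mtx_dir, name)
        if os.path.exists(path):
            return pd.read_csv(path, sep="\t", header=None, dtype=str)
    raise FileNotFoundError(
        f"no {what} file in {mtx_dir} (looked for {', '.join(candidates)})"
    )


def load_counts(path: str, fmt: str = "mtx_dir") -> CountMatrix:
    """Load a UMI count matrix.

    Parameters
    ----------
    path : str
        For ``mtx_dir``: a directory in cellranger layout containing
        ``matrix.mtx`` plus ``genes.tsv`` (v2) or ``features.tsv`` (v3) and
        ``barcodes.tsv``. For ``dense_tsv``: a TSV with a header row of cell
        ids and gene ids in the first column.
    fmt : {"mtx_dir", "dense_tsv"}

    Returns
    -------
    CountMatrix
        Genes as rows, cells as columns. Duplicate gene names are suffixed
        ``.1``, ``.2``, ... in order of appearance.
    """
    if fmt == "mtx_dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(f"MTX directory not found: {path}")
        mtx_path = os.path.join(path, "matrix.mtx")
        if not os.path.exists(mtx_path):
            raise FileNotFoundError(f"matrix file not found: {mtx_path}")
        mat = scipy.io.mmread(mtx_path)
        genes = _read_sidecar(path, ("genes.tsv", "features.tsv"), "gene")
        barcodes = _read_sidecar(path, ("barcodes.tsv",), "barcode")
        # cellranger: column 2 is the gene symbol when present, else column 1
        gene_names = genes.iloc[:, 1] if genes.shape[1] > 1 else genes.iloc[:, 0]
        gene_ids = _deduplicate(list(gene_names.astype(str)))
        cell_ids = _deduplicate(list(barcodes.iloc[:, 0].astype(str)))
        matrix = sp.csr_matrix(mat)
    elif fmt == "dense_tsv":
        if not os.path.exists(path):
            raise FileNotFoundError(f"file not found: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = _deduplicate([str(g) for g in df.index])
        cell_ids = _deduplicate([str(c) for c in df.columns])
        matrix = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError(f"empty count matrix loaded from {path}")
    return CountMatrix(matrix, gene_ids, cell_ids)


def save_counts_mtx(counts: CountMatrix, out_dir: str) -> None:
    """Write a CountMatrix as matrix.mtx + genes.tsv + barcodes.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(counts.values)
    )
    pd.DataFrame({"id": counts.gene_ids, "name": counts.gene_ids}).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def filter_genes(counts: CountMatrix, min_cells: int = DEFAULT_MIN_CELLS) -> CountMatrix:
    """Keep genes detected (nonzero UMI) in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    detected = (counts.values > 0).sum(axis=1)
    detected = np.asarray(detected).ravel()
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError(
            f"no gene is detected in >= {min_cells} cells; lower min_cells"
        )
    if keep.all():
        return counts
    return counts.subset_genes(keep)


def compute_depths(counts: CountMatrix) -> np.ndarray:
    """Per-cell sequencing depth m_j = sum_i x_ij (column sums).

    Cells with zero total UMI are reported via a warning; callers should drop
    them before modeling (log10 of their depth is undefined).
    """
    m = np.asarray(counts.values.sum(axis=0), dtype=float).ravel()
    n_zero = int((m == 0).sum())
    if n_zero:
        logger.warning("%d cell(s) have zero total UMI and must be dropped", n_zero)
    return m


def drop_empty_cells(counts: CountMatrix) -> CountMatrix:
    """Remove cells whose total UMI count is zero."""
    m = compute_depths(counts)
    if (m > 0).all():
        return counts
    return counts.subset_cells(m > 0)


def geometric_mean(x, epsilon: float = DEFAULT_EPSILON) -> float:
    """Geometric mean with pseudo-offset: exp(mean(log(x + eps))) - eps.

    The offset keeps zeros finite while respecting the multiplicative nature
    of count distributions; an all-zero vector maps to exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty vector")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if np.any(x < 0):
        raise ValueError("negative entries in count vector")
    return float(np.exp(np.mean(np.log(x + epsilon))) - epsilon)


def gene_means(counts: CountMatrix, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Per-gene geometric mean abundance and detection counts.

    Returns a DataFrame indexed by gene id with columns ``gmean`` and
    ``n_cells_detected``. Computed sparsely: for a gene with nnz nonzero
    entries out of n cells, mean(log(x+eps)) has (n - nnz) terms log(eps).
    """
    mat = sp.csr_matrix(counts.values)
    n = counts.n_cells
    log_eps = np.log(epsilon)
    sums = np.zeros(counts.n_genes)
    nnz = np.diff(mat.indptr)
    # sum of log(x+eps) over nonzero entries, per row
    logdata = np.log(mat.data + epsilon)
    for i in range(counts.n_genes):
        sums[i] = logdata[mat.indptr[i]:mat.indptr[i + 1]].sum()
    mean_log = (sums + (n - nnz) * log_eps) / n
    gmean = np.exp(mean_log) - epsilon
    gmean[nnz == 0] = 0.0
    return pd.DataFrame(
        {"gmean": gmean, "n_cells_detected": nnz.astype(int)},
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
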