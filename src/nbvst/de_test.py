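"""Differential expression between two cell groups on normalized values.

Per-gene Welch t-tests on the normalized matrix (Pearson residuals or the
log-normalized baseline), Benjamini-Hochberg FDR control, plus an empirical
significance threshold on the raw difference of group means: the background
distribution of mean differences is built by sampling genes and permuting the
group labels, and its 0.5th/99.5th percentiles bound what a difference of
means can look like by chance. A gene is called significant only if its FDR
is below alpha AND its mean difference falls outside the background band.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix

logger = logging.getLogger(__name__)

N_BACKGROUND_DEFAULT = 1000
PCTL_LO, PCTL_HI = 0.5, 99.5
ALPHA_DEFAULT = 0.01
MIN_CELLS_DETECTED = 5


def _as_matrix(values):
    if hasattr(values, "gene_ids"):
        return np.asarray(values.values, dtype=float), list(values.gene_ids)
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float), list(values.index)
    arr = np.asarray(values, dtype=float)
    return arr, [f"gene{i}" for i in range(arr.shape[0])]


def _two_groups(labels) -> tuple[np.ndarray, np.ndarray, tuple]:
    lab = np.asarray(labels)
    levels = np.unique(lab)  # sorted: mean_diff is first-level minus second
    if len(levels) != 2:
        raise ValueError(f"labels must define exactly two groups, got {levels}")
    return lab == levels[0], lab == levels[1], (levels[0], levels[1])


def background_thresholds(
    values,
    labels,
    n_background: int = N_BACKGROUND_DEFAULT,
    seed: int = 0,
    n_permutations: int = 1,
) -> tuple[float, float]:
    """Empirical null band for group mean differences.

    For each of ``n_background`` randomly chosen genes the group labels are
    permuted (once by default) and the difference of permuted group means
    recorded; the band is the 0.5th and 99.5th percentile of these null
    differences. Matrices with fewer genes than requested are sampled with
    replacement (warned).
    """
    mat, _ = _as_matrix(values)
    in_a, in_b, _ = _two_groups(labels)
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    n_genes, n_cells = mat.shape
    replace = n_genes < n_background
    if replace:
        logger.warning(
            "only %d genes for %d background draws; sampling with replacement",
            n_genes, n_background,
        )
    genes = rng.choice(n_genes, size=n_background, replace=replace)
    n_a = int(in_a.sum())
    diffs = np.empty(n_background * n_permutations)
    k = 0
    for g in genes:
        for _ in range(n_permutations):
            perm = rng.permutation(n_cells)
            row = mat[g, perm]
            diffs[k] = row[:n_a].mean() - row[n_a:].mean()
            k += 1
    lower, upper = np.percentile(diffs, [PCTL_LO, PCTL_HI])
    return float(lower), float(upper)


def differential_expression(
    values,
    labels,
    counts: CountMatrix | None = None,
    min_cells_detected: int = MIN_CELLS_DETECTED,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
    n_background: int = N_BACKGROUND_DEFAULT,
    use_background: bool = True,
) -> pd.DataFrame:
    """Two-group DE test on normalized values.

    Eligible genes are those detected (nonzero count) in at least
    ``min_cells_detected`` cells in at least one group, judged on the raw
    ``counts`` when provided (otherwise on nonzero normalized values). Per
    eligible gene a Welch t-test compares the two groups; p-values are BH
    adjusted; a gene is ``significant`` when fdr < alpha and its mean
    difference exceeds the permutation background band.

    Returns a DataFrame with mean_diff, t_stat, p_value, fdr, eligible,
    significant; the band is stored in ``df.attrs["background"]``.
    """
    mat, gene_ids = _as_matrix(values)
    in_a, in_b, (lev_a, lev_b) = _two_groups(labels)

    if counts is not None:
        raw = counts.values
        det_a = np.asarray((raw[:, in_a] > 0).sum(axis=1)).ravel()
        det_b = np.asarray((raw[:, in_b] > 0).sum(axis=1)).ravel()
    else:
        det_a = (mat[:, in_a] != 0).sum(axis=1)
        det_b = (mat[:, in_b] != 0).sum(axis=1)
    eligible = (det_a >= min_cells_detected) | (det_b >= min_cells_detected)

    a, b = mat[:, in_a], mat[:, in_b]
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups: no evidence either way
    degenerate = ~np.isfinite(p_value)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)

    fdr = np.full(mat.shape[0], np.nan)
    if eligible.any():
        fdr[eligible] = multipletests(p_value[eligible], method="fdr_bh")[1]

    if use_background:
        lower, upper = background_thresholds(
            mat[eligible], np.asarray(labels), n_background=n_background, seed=seed
        )
        outside = (mean_diff < lower) | (mean_diff > upper)
    else:
        lower, upper = -np.inf, np.inf
        outside = np.ones(mat.shape[0], dtype=bool)

    significant = eligible & (fdr < alpha) & outside
    out = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_stat": t_stat,
            "p_value": p_value,
            "fdr": fdr,
            "eligible": eligible,
            "significant": significant,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    out.attrs["background"] = (lower, upper)
    out.attrs["groups"] = (lev_a, lev_b)
    out.attrs["alpha"] = alpha
    return out
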