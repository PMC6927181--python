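"""Model diagnostics: parameter stability, trend curves, variance budget.

Three families of checks:

* Uncertainty of the per-gene estimates — cell bootstraps (default 13) giving
  a dimensionless uncertainty score, and Wald confidence intervals from the
  Fisher-information standard errors.
* Trends of (normalized) expression against sequencing depth within six
  equal-width bins of log10 gene abundance, smoothed with a deliberately
  large bandwidth (20x the SJ plug-in) to show systematic structure only.
* The variance budget across five equal-sized depth bins of cells: after a
  successful normalization every depth bin should contribute about 20% of
  each gene group's total squared deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, gene_means
from .glm_core import fit_gene_models
from .regularization import kernel_smooth, regularize, silverman_bandwidth, sj_bandwidth

logger = logging.getLogger(__name__)

N_BOOT_DEFAULT = 13
TREND_BANDWIDTH_FACTOR = 20.0
TREND_N_POINTS = 200
PARAMS = ("beta0", "beta1", "theta")


def bootstrap_uncertainty(
    counts: CountMatrix,
    depths,
    method: str = "poisson_theta",
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    regularized: bool = False,
    baf: float = 3.0,
) -> pd.DataFrame:
    """Cell-bootstrap uncertainty scores for the per-gene parameters.

    Cells are resampled with replacement ``n_boot`` times (depths travel with
    the sampled cells) and the models refit. The uncertainty score of a gene
    x parameter is the SD of its estimates across bootstraps divided by the
    SD of the bootstrap-mean values across all genes; scores near or above 1
    flag unstable estimates, scores near 0.01 or below very stable ones.

    With ``regularized=True`` the raw fits of each bootstrap are passed
    through the kernel regularization first and the scores describe the
    regularized parameters.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    m = np.asarray(depths, dtype=float)
    rng = np.random.default_rng(seed)
    gm_all = gene_means(counts)
    estimates: dict[str, list[pd.Series]] = {p: [] for p in PARAMS}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, counts.n_cells, counts.n_cells)
        bcounts = CountMatrix(
            counts.values[:, idx],
            list(counts.gene_ids),
            [f"bs{j}" for j in range(counts.n_cells)],
        )
        try:
            table = fit_gene_models(bcounts, m[idx], method=method)
            if regularized:
                gm = gm_all[gm_all["gmean"] > 0]
                reg, _ = regularize(table, gm, baf=baf)
                table = reg.rename(
                    columns={f"{p}_reg": p for p in PARAMS}
                )
        except ValueError:
            n_failed += 1
            continue
        for p in PARAMS:
            estimates[p].append(table[p])
    if n_failed:
        logger.warning("%d bootstrap(s) failed entirely", n_failed)

    frames = {
        p: uncertainty_scores(pd.concat(estimates[p], axis=1)) for p in PARAMS
    }
    return pd.concat(frames, names=["parameter", "gene_id"])


def uncertainty_scores(estimates: pd.DataFrame) -> pd.DataFrame:
    """Scores from a genes × bootstraps table of parameter estimates.

    score = SD across bootstraps / SD across genes of the bootstrap means.
    """
    boot_sd = estimates.std(axis=1, ddof=1)
    denom = estimates.mean(axis=1).std(ddof=1)
    return pd.DataFrame(
        {
            "bootstrap_sd": boot_sd,
            "uncertainty_score": boot_sd / denom,
            "n_boot": estimates.notna().sum(axis=1),
        }
    )


def confidence_intervals(model: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals: estimate +/- 1.96 * SE (at level 0.95).

    Parameters with missing SEs get NaN bounds (CI unavailable).
    """
    from scipy import stats

    zcrit = float(stats.norm.ppf(0.5 + level / 2.0))
    out = {}
    for p in PARAMS:
        est = model[p].astype(float)
        se = model.get(f"se_{p}")
        se = se.astype(float) if se is not None else pd.Series(np.nan, index=model.index)
        out[f"{p}_lo"] = est - zcrit * se
        out[f"{p}_hi"] = est + zcrit * se
    return pd.DataFrame(out, index=model.index)


def bin_genes(gmeans: pd.DataFrame, n_bins: int = 6) -> pd.Series:
    """Equal-width bins of log10 gene abundance (1-based labels).

    The maximum abundance is assigned to the top bin. Degenerate input (all
    abundances equal) lands in bin 1 with a warning.
    """
    g = gmeans["gmean"].to_numpy(dtype=float)
    if np.any(g <= 0):
        raise ValueError("gmeans must be positive")
    log_g = np.log10(g)
    lo, hi = log_g.min(), log_g.max()
    if hi == lo:
        logger.warning("all gene means identical: single occupied bin")
        bins = np.ones(len(g), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.digitize(log_g, edges[1:-1], right=False) + 1
    return pd.Series(bins, index=gmeans.index, name="gene_bin")


def expression_trend(
    values,
    depths,
    groups: pd.Series,
    n_points: int = TREND_N_POINTS,
    bandwidth_factor: float = TREND_BANDWIDTH_FACTOR,
) -> pd.DataFrame:
    """Smoothed expression against depth, summarized per gene group.

    Each gene's values are kernel-smoothed against log10 depth with a large
    bandwidth (``bandwidth_factor`` x the SJ plug-in of the log10 depths).
    Within each group the first, second and third quartiles across member
    genes are reported at ``n_points`` equidistant depth values spanning the
    central 90% of cells by total UMI.

    ``values`` may be a ResidualMatrix-like object (with ``.values`` and
    ``.gene_ids``) or a DataFrame indexed by gene id.
    """
    if hasattr(values, "gene_ids"):
        mat = np.asarray(values.values, dtype=float)
        gene_ids = list(values.gene_ids)
    else:
        mat = values.to_numpy(dtype=float)
        gene_ids = list(values.index)
    m = np.asarray(depths, dtype=float)
    log_m = np.log10(m)
    lo, hi = np.percentile(m, [5, 95])
    grid = np.linspace(lo, hi, n_points)
    log_grid = np.log10(grid)
    try:
        bw = sj_bandwidth(log_m) * bandwidth_factor
    except ValueError:
        bw = silverman_bandwidth(log_m) * bandwidth_factor

    groups = groups.reindex(gene_ids)
    records = []
    for bin_id, members in groups.groupby(groups):
        rows = [gene_ids.index(g) for g in members.index]
        if len(rows) < 3:
            logger.warning("gene bin %s has < 3 genes; band reported as NA", bin_id)
            records.append(
                pd.DataFrame(
                    {
                        "gene_bin": bin_id,
                        "depth": grid,
                        "q1": np.nan,
                        "median": np.nan,
                        "q3": np.nan,
                    }
                )
            )
            continue
        smoothed = np.vstack(
            [kernel_smooth(log_grid, log_m, mat[r], bw) for r in rows]
        )
        q1, q2, q3 = np.percentile(smoothed, [25, 50, 75], axis=0)
        records.append(
            pd.DataFrame(
                {"gene_bin": bin_id, "depth": grid, "q1": q1, "median": q2, "q3": q3}
            )
        )
    return pd.concat(records, ignore_index=True)


def depth_bins(depths, n_cell_bins: int = 5) -> np.ndarray:
    """Equal-sized cell bins by total UMI; bin 1 has the greatest depth.

    Ties in depth are broken by cell index for determinism; when the cell
    count is not divisible the remainder goes to the shallowest bin.
    """
    if n_cell_bins < 2:
        raise ValueError("need at least 2 cell bins")
    m = np.asarray(depths, dtype=float)
    order = np.lexsort((np.arange(m.size), -m))  # descending depth, stable
    per = m.size // n_cell_bins
    bins = np.empty(m.size, dtype=int)
    for b in range(n_cell_bins):
        start = b * per
        stop = (b + 1) * per if b < n_cell_bins - 1 else m.size
        bins[order[start:stop]] = b + 1
    return bins


def variance_contribution(
    values,
    depths,
    groups: pd.Series,
    n_cell_bins: int = 5,
) -> pd.DataFrame:
    """Fraction of each gene group's squared deviation carried by depth bins.

    Values are centered per gene and squared; for each gene group x cell bin
    the fraction is the bin's share of the total squared deviation. Rows sum
    to 1. A group with zero total variance reports NaN.
    """
    if hasattr(values, "gene_ids"):
        mat = np.asarray(values.values, dtype=float)
        gene_ids = list(values.gene_ids)
    else:
        mat = values.to_numpy(dtype=float)
        gene_ids = list(values.index)
    sq = (mat - mat.mean(axis=1, keepdims=True)) ** 2
    cbins = depth_bins(depths, n_cell_bins)
    groups = groups.reindex(gene_ids)

    rows = {}
    for bin_id, members in groups.groupby(groups):
        ridx = [gene_ids.index(g) for g in members.index]
        total = sq[ridx].sum()
        shares = []
        for cb in range(1, n_cell_bins + 1):
            s = sq[np.ix_(ridx, np.flatnonzero(cbins == cb))].sum()
            shares.append(s / total if total > 0 else np.nan)
        rows[bin_id] = shares
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"cell_bin_{b}" for b in range(1, n_cell_bins + 1)],
    )
    out.index.name = "gene_bin"
    return out
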