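"""Synthetic UMI datasets with known ground truth.

Counts are generated from the same generative model the pipeline fits: a cell
draws a total-UMI depth m_j (from an empirical depth vector or a lognormal
generator), and gene i in that cell draws x_ij ~ NB(mu_ij, theta_i) with
mu_ij = exp(beta0_i + beta1_i * log10 m_j).

Truth parameter tables come either from the caller (e.g. learned from real
data) or from :func:`default_gene_params`, a synthetic stand-in shaped like
regularization curves learned from real UMI data: slopes near ln(10) (counts
proportional to depth), intercepts anchored so the model-implied mean at the
median depth equals the target abundance, and dispersion increasing with
abundance. The two-population design plants differentially expressed genes by
shifting their group means by sqrt(fold) up and down (ratio = fold) and
re-reading all parameters from the truth curves at the shifted abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .counts_io import CountMatrix

# lognormal depth generator resembling a typical 10x experiment
# (median about 1800 UMI per cell)
DEPTH_MEANLOG = 7.5
DEPTH_SDLOG = 0.35
LN10 = np.log(10.0)


@dataclass
class SimulationSpec:
    """Design of a two-population simulation with planted DE genes."""

    n_cells_per_group: int = 5000
    frac_up: float = 0.05
    frac_down: float = 0.05
    fold: float = 10.0
    gene_params: pd.DataFrame | None = None
    depth_source: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    group_labels: np.ndarray = field(default_factory=lambda: np.array([]))
    de_labels: pd.Series | None = None
    truth: pd.DataFrame | None = None
    depths: np.ndarray | None = None


def param_curves(gmean):
    """Truth curves (beta0, beta1, theta) as functions of geometric mean.

    beta1 is ln(10) everywhere (molecule counts proportional to depth);
    beta0 anchors the mean at the median lognormal depth to the target gmean;
    log10(theta) rises linearly with log10(gmean), clipped to [-1, 2.5], so
    low-abundance genes are strongly overdispersed and abundant genes are
    nearly Poisson at the per-cell level.
    """
    g = np.asarray(gmean, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gmean must be positive")
    log_g = np.log10(g)
    median_depth = np.exp(DEPTH_MEANLOG)
    beta1 = np.full_like(g, LN10)
    beta0 = np.log(g) - beta1 * np.log10(median_depth)
    theta = 10.0 ** np.clip(0.7 + 1.0 * log_g, -1.0, 2.5)
    return beta0, beta1, theta


def default_gene_params(n_genes: int = 500, seed: int = 0,
                        gmean_range: tuple[float, float] = (0.01, 40.0),
                        theta: float | None = None,
                        profile: str = "skewed") -> pd.DataFrame:
    """Synthetic truth table of per-gene (gmean, beta0, beta1, theta).

    With ``profile="skewed"`` (the default) log10 abundances are drawn from
    a truncated normal (location -1, scale 0.9, truncated to
    ``gmean_range``), mimicking the abundance profile of droplet UMI data:
    the bulk of genes well below one molecule per cell and a sparse tail of
    highly expressed genes. ``profile="log_uniform"`` spreads abundances
    evenly in log space instead — useful for planted-effect fixtures where
    no single gene should dominate the total depth. ``theta`` overrides the
    dispersion curve with one shared value (e.g. theta=1 for a strongly
    overdispersed fixture or a large value for near-Poisson).
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(seed)
    lo, hi = np.log10(gmean_range[0]), np.log10(gmean_range[1])
    if profile == "skewed":
        loc, scale = -1.0, 0.9
        tn = _stats.truncnorm((lo - loc) / scale, (hi - loc) / scale, loc, scale)
        g = 10.0 ** tn.rvs(n_genes, random_state=rng)
    elif profile == "log_uniform":
        g = 10.0 ** rng.uniform(lo, hi, n_genes)
    else:
        raise ValueError(f"unknown abundance profile: {profile!r}")
    g = np.sort(g)[::-1]
    b0, b1, th = param_curves(g)
    if theta is not None:
        th = np.full(n_genes, float(theta))
    return pd.DataFrame(
        {"gmean": g, "beta0": b0, "beta1": b1, "theta": th},
        index=pd.Index([f"gene{i:04d}" for i in range(n_genes)], name="gene_id"),
    )


def _draw_depths(rng, n_cells, depth_source=None):
    if depth_source is not None:
        src = np.asarray(depth_source, dtype=float)
        return src[rng.integers(0, src.size, n_cells)]
    return np.ceil(rng.lognormal(DEPTH_MEANLOG, DEPTH_SDLOG, n_cells))


def _nb_counts(rng, mu, theta):
    """Draw NB(mu, theta) counts; near the Poisson limit draw Poisson."""
    theta_col = np.broadcast_to(np.asarray(theta, dtype=float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_like = theta_col >= 1e5
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        t = theta_col[nb]
        out[nb] = rng.negative_binomial(t, t / (t + mu[nb]))
    return out


def simulate_homogeneous(
    gene_params: pd.DataFrame,
    n_cells: int = 2000,
    seed: int = 0,
    depth_source=None,
    cell_prefix: str = "cell",
) -> SyntheticDataset:
    """One biologically homogeneous population.

    All variation in the counts comes from depth differences and NB sampling
    noise, so a correctly calibrated pipeline should leave no residual
    structure: residual means near 0, residual variances near 1, and no
    depth dependence.
    """
    rng = np.random.default_rng(seed)
    m = _draw_depths(rng, n_cells, depth_source)
    b0 = gene_params["beta0"].to_numpy(dtype=float)[:, None]
    b1 = gene_params["beta1"].to_numpy(dtype=float)[:, None]
    th = gene_params["theta"].to_numpy(dtype=float)
    mu = np.exp(b0 + b1 * np.log10(m)[None, :])
    if not np.isfinite(mu).all():
        bad = np.flatnonzero(~np.isfinite(mu).all(axis=1))[0]
        raise ValueError(f"non-finite mean for gene {gene_params.index[bad]}")
    x = _nb_counts(rng, mu, th)
    counts = CountMatrix(
        sp.csr_matrix(x),
        list(gene_params.index),
        [f"{cell_prefix}{j}" for j in range(n_cells)],
    )
    return SyntheticDataset(
        counts=counts,
        group_labels=np.array(["A"] * n_cells),
        de_labels=pd.Series("null", index=gene_params.index, name="de_label"),
        truth=gene_params.copy(),
        depths=m,
    )


def simulate_two_groups(spec: SimulationSpec) -> SyntheticDataset:
    """Two populations A and B with planted expression shifts.

    frac_up of the genes get mean ratio ``fold`` in A over B (mean shifted by
    sqrt(fold) up in A and down in B) and frac_down the converse; the sets
    are disjoint. Each affected gene's (beta0, beta1, theta) are re-derived
    from the truth parameter curves at its shifted abundance. Cells are
    generated in n_cells_per_group pairs (one per group) sharing the depth
    distribution.
    """
    params = spec.gene_params
    if params is None:
        params = default_gene_params(seed=spec.seed)
    n_genes = len(params)
    n_up = int(round(spec.frac_up * n_genes))
    n_down = int(round(spec.frac_down * n_genes))
    if n_up + n_down > n_genes:
        raise ValueError("DE fractions select more genes than available")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_genes)
    up_idx, down_idx = perm[:n_up], perm[n_up:n_up + n_down]
    de = pd.Series("null", index=params.index, name="de_label")
    de.iloc[up_idx] = "up_in_A"
    de.iloc[down_idx] = "up_in_B"

    root = np.sqrt(spec.fold)
    truths = {}
    for grp, sign in (("A", +1.0), ("B", -1.0)):
        g = params["gmean"].to_numpy(dtype=float).copy()
        g[up_idx] *= root**sign
        g[down_idx] *= root**-sign
        b0, b1, th = param_curves(g)
        # genes not planted keep their exact base parameters
        moved = np.zeros(n_genes, dtype=bool)
        moved[up_idx] = moved[down_idx] = True
        b0 = np.where(moved, b0, params["beta0"].to_numpy(dtype=float))
        b1 = np.where(moved, b1, params["beta1"].to_numpy(dtype=float))
        th = np.where(moved, th, params["theta"].to_numpy(dtype=float))
        truths[grp] = pd.DataFrame(
            {"gmean": g, "beta0": b0, "beta1": b1, "theta": th},
            index=params.index,
        )

    sets = []
    for grp in ("A", "B"):
        ds = simulate_homogeneous(
            truths[grp],
            n_cells=spec.n_cells_per_group,
            seed=int(rng.integers(0, 2**31 - 1)),
            depth_source=spec.depth_source,
            cell_prefix=f"{grp}_cell",
        )
        sets.append(ds)

    counts = CountMatrix(
        sp.hstack([sets[0].counts.values, sets[1].counts.values], format="csr"),
        list(params.index),
        sets[0].counts.cell_ids + sets[1].counts.cell_ids,
    )
    labels = np.array(["A"] * spec.n_cells_per_group + ["B"] * spec.n_cells_per_group)
    truth = pd.concat({g: truths[g] for g in ("A", "B")}, names=["group", "gene_id"])
    return SyntheticDataset(
        counts=counts,
        group_labels=labels,
        de_labels=de,
        truth=truth,
        depths=np.concatenate([sets[0].depths, sets[1].depths]),
    )


def downsample_umis(counts: CountMatrix, fraction: float, cells=None,
                    seed: int = 0) -> CountMatrix:
    """Binomial thinning: keep each UMI independently with ``fraction``.

    Emulates reduced sequencing depth for the selected cells (all cells when
    ``cells`` is None); expected depth per thinned cell is fraction times the
    original.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return counts
    rng = np.random.default_rng(seed)
    mat = sp.csc_matrix(counts.values, copy=True)
    if cells is None:
        sel = np.arange(counts.n_cells)
    else:
        sel = np.asarray(cells)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if sel.size == 0:
            import logging

            logging.getLogger(__name__).warning(
                "empty cell subset: downsampling is a no-op"
            )
            return counts
    mask = np.zeros(counts.n_cells, dtype=bool)
    mask[sel] = True
    col_of_entry = np.repeat(np.arange(counts.n_cells), np.diff(mat.indptr))
    entry_sel = mask[col_of_entry]
    data = mat.data.astype(np.int64)
    data[entry_sel] = rng.binomial(data[entry_sel], fraction)
    mat.data = data
    mat.eliminate_zeros()
    return CountMatrix(sp.csr_matrix(mat), list(counts.gene_ids), list(counts.cell_ids))
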