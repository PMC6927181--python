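"""Regularization of per-gene model parameters by kernel regression.

Raw per-gene GLM estimates are noisy, especially for low-abundance genes, and
an unconstrained NB model can overfit (attributing real heterogeneity to
dispersion). Information is therefore pooled across genes of similar
abundance: each parameter (beta0, beta1, theta) is smoothed as a function of
log10 geometric gene mean with a Nadaraya-Watson kernel regression, and every
gene's parameters are replaced by the value of the smooth curve at its own
abundance.

Bandwidths come from the Sheather-Jones "solve-the-equation" plug-in,
multiplied by a bandwidth adjustment factor (BAF, default 3). The normal
kernel follows the convention of R's ``ksmooth``: it is scaled so that its
quartiles sit at +/- 0.25 * bandwidth (Gaussian sigma = 0.3706506 * bandwidth),
which keeps bandwidth values comparable across implementations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_BAF = 3.0
DEFAULT_N_GENES = 2000
# sigma of the normal kernel per unit bandwidth: 0.25 / qnorm(0.75)
KSMOOTH_SIGMA = 0.25 / stats.norm.ppf(0.75)


def _phi4(x):
    return (x**4 - 6.0 * x**2 + 3.0) * stats.norm.pdf(x)


def _phi6(x):
    return (x**6 - 15.0 * x**4 + 45.0 * x**2 - 15.0) * stats.norm.pdf(x)


def silverman_bandwidth(values) -> float:
    """Silverman's rule of thumb, the fallback for degenerate samples."""
    x = np.asarray(values, dtype=float)
    n = x.size
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(np.std(x, ddof=1), iqr / 1.349) if iqr > 0 else np.std(x, ddof=1)
    if scale == 0:
        raise ValueError("zero spread; no bandwidth defined")
    return 0.9 * scale * n ** (-0.2)


def sj_bandwidth(values) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth.

    Solves h = [R(K) / (n * SD(alpha2(h)))]^(1/5) where SD is the kernel
    estimate of the integrated squared density second derivative with pilot
    bandwidth alpha2(h). Falls back to Silverman's rule (with a warning) when
    the sample is too degenerate for the plug-in equations.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 finite values for bandwidth selection")

    d = (x[:, None] - x[None, :]).ravel()

    def sd_hat(b):
        return _phi4(d / b).sum() / (n * (n - 1) * b**5)

    def td_hat(b):
        return -_phi6(d / b).sum() / (n * (n - 1) * b**7)

    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sd = np.std(x, ddof=1)
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("zero spread; no bandwidth defined")

    # pilot constants 0.920 and 0.912 of the plug-in method are stated for
    # lambda = IQR; with scale = min(sd, IQR/1.349) they become 1.24 and 1.23
    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    td = td_hat(b)
    if td <= 0:
        logger.warning("SJ plug-in failed (TD <= 0); using Silverman fallback")
        return silverman_bandwidth(x)
    alpha2_const = 1.357 * (sd_hat(a) / td) ** (1.0 / 7.0)
    rk = 0.5 / np.sqrt(np.pi)  # roughness of the Gaussian kernel

    def objective(h):
        s = sd_hat(alpha2_const * h ** (5.0 / 7.0))
        if s <= 0:
            return np.inf
        return (rk / (n * s)) ** 0.2 - h

    lo, hi = 0.1 * scale * n**-0.2, 2.0 * scale * n**-0.2
    flo, fhi = objective(lo), objective(hi)
    for _ in range(20):
        if np.isfinite(flo) and np.isfinite(fhi) and flo * fhi < 0:
            break
        lo, hi = lo / 2.0, hi * 2.0
        flo, fhi = objective(lo), objective(hi)
    else:
        logger.warning("SJ root not bracketed; using Silverman fallback")
        return silverman_bandwidth(x)
    return float(optimize.brentq(objective, lo, hi, xtol=1e-8 * scale))


def gaussian_kde_density(eval_points, data, bandwidth) -> np.ndarray:
    """Gaussian kernel density with sigma = bandwidth (R density() convention)."""
    e = np.asarray(eval_points, dtype=float)[:, None]
    x = np.asarray(data, dtype=float)[None, :]
    return stats.norm.pdf((e - x) / bandwidth).mean(axis=1) / bandwidth


def sample_estimation_genes(gmeans: pd.DataFrame, n_genes: int = DEFAULT_N_GENES,
                            seed: int = 0) -> list[str]:
    """Density-weighted sample of genes for the initial GLM-fitting step.

    Genes are drawn without replacement with probability proportional to
    1/d(log10 gmean), where d is a Gaussian KDE over all log10 gene means, so
    the sample is roughly uniform in log abundance and sparse abundance
    regions keep representation. Densities are floored at their 1st
    percentile to avoid near-infinite weights at extreme abundances.

    Parameters
    ----------
    gmeans : DataFrame indexed by gene_id with a ``gmean`` column (all > 0)
    n_genes : sample size; when >= the number of genes, all genes are used
    seed : RNG seed; the draw is deterministic given (gmeans, n_genes, seed)
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    ids = np.asarray(gmeans.index)
    g = gmeans["gmean"].to_numpy(dtype=float)
    if np.any(g <= 0):
        raise ValueError("all gmeans must be > 0 (filter all-zero genes first)")
    if n_genes >= len(ids):
        return list(ids)
    log_g = np.log10(g)
    try:
        bw = sj_bandwidth(log_g)
    except ValueError:
        bw = silverman_bandwidth(log_g)
    dens = gaussian_kde_density(log_g, log_g, bw)
    dens = np.maximum(dens, np.percentile(dens, 1))
    w = 1.0 / dens
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=n_genes, replace=False, p=w / w.sum())
    return list(ids[np.sort(pick)])


def kernel_smooth(x_query, x_data, y_data, bandwidth: float) -> np.ndarray:
    """Nadaraya-Watson regression with a normal kernel, ksmooth scaling.

    The kernel sigma is 0.25 * bandwidth / qnorm(0.75). Query points whose
    total kernel weight underflows to zero fall back to the nearest data
    point's value (logged); this also provides constant extrapolation beyond
    the data range, where the weighted average is dominated by the edge.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    xq = np.atleast_1d(np.asarray(x_query, dtype=float))
    xd = np.asarray(x_data, dtype=float)
    yd = np.asarray(y_data, dtype=float)
    if xd.shape != yd.shape:
        raise ValueError("x_data and y_data must have the same length")
    sigma = KSMOOTH_SIGMA * bandwidth
    out = np.empty(xq.shape)
    # chunked to bound the (query x data) weight matrix
    step = max(1, int(4e6 / max(xd.size, 1)))
    for s in range(0, xq.size, step):
        q = xq[s:s + step, None]
        w = np.exp(-0.5 * ((q - xd[None, :]) / sigma) ** 2)
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            val = (w @ yd) / tot
        dead = tot <= 0
        if dead.any():
            nearest = np.abs(q[dead] - xd[None, :]).argmin(axis=1)
            val[dead] = yd[nearest]
            logger.debug("%d query point(s) used nearest-neighbor fallback",
                         int(dead.sum()))
        out[s:s + step] = val
    return out


def regularize(raw: pd.DataFrame, all_gmeans: pd.DataFrame,
               baf: float = DEFAULT_BAF) -> tuple[pd.DataFrame, dict]:
    """Smooth raw per-gene parameters against log10 gmean, evaluate everywhere.

    beta0 and beta1 are smoothed on their natural scale and theta on log10
    scale (positivity and a tamed right tail), each with its own SJ bandwidth
    multiplied by ``baf``. Genes with failed raw fits or with theta on the
    cap boundary are excluded from the smoother input but still receive
    regularized values at their own gmean.

    Parameters
    ----------
    raw : DataFrame from ``fit_gene_models`` (the estimation subset)
    all_gmeans : DataFrame indexed by gene_id with ``gmean`` > 0 for every
        gene that should receive regularized parameters
    baf : bandwidth adjustment factor (> 0)

    Returns
    -------
    (table, bandwidths): table indexed by gene_id with columns gmean,
    beta0_reg, beta1_reg, theta_reg; bandwidths maps parameter name to the
    effective bandwidth used (base SJ bandwidth x baf).
    """
    if baf <= 0:
        raise ValueError("baf must be > 0")
    if raw.empty:
        raise ValueError("raw parameter table is empty")
    usable = raw[np.isfinite(raw[["beta0", "beta1", "theta"]]).all(axis=1)]
    if "converged" in usable:
        usable = usable[usable["converged"].astype(bool)]
    if usable.empty:
        raise ValueError("no usable raw fits to regularize")

    x_all = np.log10(all_gmeans["gmean"].to_numpy(dtype=float))
    x_beta = np.log10(usable["gmean"].to_numpy(dtype=float))
    theta_ok = usable
    if "theta_boundary" in usable:
        non_bound = usable[~usable["theta_boundary"].astype(bool)]
        if len(non_bound) >= 10:
            theta_ok = non_bound
    x_theta = np.log10(theta_ok["gmean"].to_numpy(dtype=float))

    def bw_of(x):
        try:
            return sj_bandwidth(x)
        except ValueError:
            return silverman_bandwidth(x)

    bw = {
        "beta0": bw_of(x_beta) * baf,
        "beta1": bw_of(x_beta) * baf,
        "theta": bw_of(x_theta) * baf,
    }
    beta0_reg = kernel_smooth(x_all, x_beta, usable["beta0"].to_numpy(), bw["beta0"])
    beta1_reg = kernel_smooth(x_all, x_beta, usable["beta1"].to_numpy(), bw["beta1"])
    log_theta = kernel_smooth(
        x_all, x_theta, np.log10(theta_ok["theta"].to_numpy()), bw["theta"]
    )
    table = pd.DataFrame(
        {
            "gmean": all_gmeans["gmean"].to_numpy(dtype=float),
            "beta0_reg": beta0_reg,
            "beta1_reg": beta1_reg,
            "theta_reg": 10.0 ** log_theta,
        },
        index=all_gmeans.index.rename("gene_id"),
    )
    return table, bw
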