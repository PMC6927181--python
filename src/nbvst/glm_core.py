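"""Per-gene GLMs of UMI counts on log10 sequencing depth.

The model for gene i is log mu_ij = beta0_i + beta1_i * log10(m_j) with either
Poisson error or negative binomial error (variance mu + mu^2/theta). Fits are
vectorized across genes: with a shared two-column design [1, log10 m] the IRLS
normal equations reduce to per-gene 2x2 solves, so thousands of genes are fit
simultaneously with array operations.

Three estimation methods, in increasing order of cost:

1. ``poisson_theta`` — Poisson IRLS for the betas, then theta by ML with the
   means held fixed (the default).
2. ``poisson_theta_refit`` — method 1 followed by an NB re-fit of the betas
   with theta fixed.
3. ``nb_alternating`` — alternate (beta | theta) IRLS and (theta | beta) ML
   to the joint NB maximum likelihood.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special

from .counts_io import CountMatrix, gene_means

logger = logging.getLogger(__name__)

THETA_CAP = 1e6
THETA_FLOOR = 1e-5
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
ALT_TOL = 1e-5
ALT_MAX_ITER = 25

METHODS = ("poisson_theta", "poisson_theta_refit", "nb_alternating")


def _check_design(log10_m: np.ndarray) -> None:
    if log10_m.size < 2 or np.ptp(log10_m) == 0:
        raise ValueError("singular design: no variation in log10 depth")


def _irls_batch(x, log10_m, theta=None, beta_init=None):
    """Batched IRLS for log-link regression on [1, log10 m].

    Parameters
    ----------
    x : (G, n) array of counts
    log10_m : (n,) array
    theta : (G,) array or None
        None fits Poisson; otherwise NB with the given fixed dispersions.

    Returns
    -------
    beta : (G, 2), se : (G, 2), converged : (G,) bool
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.asarray(log10_m, dtype=float)
    G, n = x.shape

    if beta_init is None:
        mu = x + 0.1  # standard GLM starting values
        eta = np.log(mu)
        beta = np.zeros((G, 2))
    else:
        beta = np.array(beta_init, dtype=float)
        eta = np.clip(beta[:, [0]] + beta[:, [1]] * t[None, :], -690, 690)
        mu = np.maximum(np.exp(eta), 1e-300)
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(IRLS_MAX_ITER):
        idx = np.flatnonzero(active)
        if not idx.size:
            break
        xa, mua, etaa = x[idx], mu[idx], eta[idx]
        if theta is None:
            w = mua
        else:
            w = mua / (1.0 + mua / theta[idx, None])
        z = etaa + (xa - mua) / mua
        a11 = w.sum(axis=1)
        a12 = w @ t
        a22 = w @ (t * t)
        b1 = (w * z).sum(axis=1)
        b2 = (w * z) @ t
        det = a11 * a22 - a12 * a12
        bad = ~np.isfinite(det) | (np.abs(det) < 1e-300)
        det = np.where(bad, 1.0, det)
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        new_beta = np.column_stack([beta0, beta1])
        new_beta[bad] = beta[idx][bad]
        beta[idx] = new_beta

        etaa = np.clip(new_beta[:, [0]] + new_beta[:, [1]] * t[None, :], -690, 690)
        mua = np.maximum(np.exp(etaa), 1e-300)
        eta[idx] = etaa
        mu[idx] = mua

        with np.errstate(divide="ignore", invalid="ignore"):
            xlogx = np.where(xa > 0, xa * np.log(np.where(xa > 0, xa, 1.0) / mua), 0.0)
        if theta is None:
            dev = 2.0 * (xlogx - (xa - mua)).sum(axis=1)
        else:
            th = theta[idx, None]
            dev = 2.0 * (
                xlogx - (xa + th) * np.log((xa + th) / (mua + th))
            ).sum(axis=1)
        delta = np.abs(dev - dev_old[idx]) / (np.abs(dev) + 0.1)
        done = delta < IRLS_TOL
        dev_old[idx] = dev
        converged[idx[done]] = True
        active[idx[done]] = False

    if theta is None:
        w = mu
    else:
        w = mu / (1.0 + mu / theta[:, None])
    a11 = w.sum(axis=1)
    a12 = w @ t
    a22 = w @ (t * t)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.column_stack([np.sqrt(a22 / det), np.sqrt(a11 / det)])
    finite = np.isfinite(beta).all(axis=1) & np.isfinite(mu).all(axis=1)
    converged &= finite
    return beta, se, converged


def fit_poisson_coefficients(x, m):
    """ML fit of log mu = beta0 + beta1 log10(m) under Poisson error.

    Returns ((beta0, beta1), (se_beta0, se_beta1)). Fisher-information
    standard errors are evaluated at the optimum.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.all(x == 0):
        raise ValueError("all-zero count vector (gene should have been filtered)")
    t = np.log10(m)
    _check_design(t)
    beta, se, conv = _irls_batch(x[None, :], t)
    if not conv[0]:
        logger.warning("Poisson IRLS did not converge")
    return (beta[0, 0], beta[0, 1]), (se[0, 0], se[0, 1])


def _nb_theta_score(u, x, mu):
    """d/du and d2/du2 of the NB log-likelihood in u = log(theta), batched.

    x, mu: (G, n); u: (G,). Returns (score, hessian) each (G,).
    """
    theta = np.exp(u)[:, None]
    tm = theta + mu
    # dl/dtheta
    dl = (
        special.digamma(x + theta)
        - special.digamma(theta)
        + np.log(theta)
        + 1.0
        - np.log(tm)
        - (theta + x) / tm
    ).sum(axis=1)
    # d2l/dtheta2
    d2l = (
        special.polygamma(1, x + theta)
        - special.polygamma(1, theta)
        + 1.0 / theta
        - 2.0 / tm
        + (theta + x) / tm**2
    ).sum(axis=1)
    th = theta[:, 0]
    return th * dl, th * th * d2l + th * dl


def _theta_ml_batch(x, mu, theta_cap=THETA_CAP):
    """Batched ML estimate of the NB dispersion with means held fixed.

    Newton iteration on log(theta) (positivity by construction); genes whose
    score is still positive at the cap are underdispersed and returned at the
    boundary. Per-gene Brent fallback when Newton stalls.

    Returns (theta, se_theta, boundary) arrays of shape (G,).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    G = x.shape[0]
    u_lo, u_hi = np.log(THETA_FLOOR), np.log(theta_cap)

    # method-of-moments start
    num = (mu * mu).sum(axis=1)
    den = ((x - mu) ** 2 - mu).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta0 = np.where(den > 0, num / np.maximum(den, 1e-300), theta_cap)
    u = np.clip(np.log(np.clip(theta0, THETA_FLOOR, theta_cap)), u_lo, u_hi)

    boundary = np.zeros(G, dtype=bool)
    # genes with positive score at the cap sit on the boundary (Poisson-like)
    score_hi, _ = _nb_theta_score(np.full(G, u_hi), x, mu)
    boundary_hi = score_hi >= 0
    score_lo, _ = _nb_theta_score(np.full(G, u_lo), x, mu)
    boundary_lo = score_lo <= 0
    boundary = boundary_hi | boundary_lo
    u[boundary_hi] = u_hi
    u[boundary_lo & ~boundary_hi] = u_lo

    active = ~boundary
    converged = boundary.copy()
    for _ in range(100):
        idx = np.flatnonzero(active)
        if not idx.size:
            break
        s, h = _nb_theta_score(u[idx], x[idx], mu[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h < 0, -s / h, np.sign(s))
        step = np.clip(step, -2.0, 2.0)
        u_new = np.clip(u[idx] + step, u_lo, u_hi)
        done = np.abs(u_new - u[idx]) < 1e-10
        u[idx] = u_new
        converged[idx[done]] = True
        active[idx[done]] = False

    # Brent fallback on the score for any stragglers
    for g in np.flatnonzero(~converged & ~boundary):
        xg, mg = x[g:g + 1], mu[g:g + 1]

        def score1(ug):
            return _nb_theta_score(np.array([ug]), xg, mg)[0][0]

        try:
            u[g] = optimize.brentq(score1, u_lo, u_hi, xtol=1e-10)
            converged[g] = True
        except ValueError:
            converged[g] = False

    theta = np.exp(u)
    _, h = _nb_theta_score(u, x, mu)
    # observed information on the theta scale: -d2l/dtheta2 = -(h - th*dl)/th^2
    s, _ = _nb_theta_score(u, x, mu)
    info = -(h - s) / theta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.abs(info)), np.nan)
    se[boundary] = np.nan
    return theta, se, boundary


def estimate_theta_ml(x, mu, theta_cap=THETA_CAP):
    """ML estimate of the NB dispersion theta for one gene.

    Parameters
    ----------
    x : (n,) counts
    mu : scalar or (n,) fitted means, all > 0
    theta_cap : upper bound; underdispersed genes return the cap.

    Returns
    -------
    (theta, se_theta); se is NaN at the boundary.
    """
    x = np.asarray(x, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
    if np.any(mu <= 0):
        raise ValueError("fitted means must be positive")
    if x.shape != mu.shape:
        raise ValueError("x and mu must have the same length")
    theta, se, _ = _theta_ml_batch(x[None, :], mu[None, :], theta_cap)
    if not np.isfinite(theta[0]):
        raise ValueError("non-finite likelihood in theta estimation")
    return float(theta[0]), float(se[0])


def nb_loglik(x, mu, theta) -> float:
    """NB log-likelihood with mean mu and variance mu + mu^2/theta."""
    x = np.asarray(x, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape)
    th = float(theta)
    return float(
        (
            special.gammaln(x + th)
            - special.gammaln(th)
            - special.gammaln(x + 1)
            + th * np.log(th / (th + mu))
            + x * np.log(mu / (th + mu))
        ).sum()
    )


def fit_nb_alternating(x, m, init=None, theta_cap=THETA_CAP):
    """Joint NB fit by alternating (beta | theta) IRLS and (theta | beta) ML.

    Returns a dict with beta0, beta1, theta, their SEs, and a ``converged``
    flag (False returns the best iterate reached).
    """
    x = np.asarray(x, dtype=float)[None, :]
    m = np.asarray(m, dtype=float)
    t = np.log10(m)
    _check_design(t)

    if init is not None:
        beta = np.array([[init[0], init[1]]], dtype=float)
        theta = np.array([float(init[2])])
        se_b = np.full((1, 2), np.nan)
    else:
        beta, se_b, _ = _irls_batch(x, t)
        mu = np.exp(beta[:, [0]] + beta[:, [1]] * t[None, :])
        theta, _, _ = _theta_ml_batch(x, mu, theta_cap)

    converged = False
    se_th = np.array([np.nan])
    for _ in range(ALT_MAX_ITER):
        old = np.array([beta[0, 0], beta[0, 1], np.log(theta[0])])
        beta, se_b, _ = _irls_batch(x, t, theta=theta, beta_init=beta)
        mu = np.exp(np.clip(beta[:, [0]] + beta[:, [1]] * t[None, :], -690, 690))
        theta, se_th, bound = _theta_ml_batch(x, mu, theta_cap)
        new = np.array([beta[0, 0], beta[0, 1], np.log(theta[0])])
        if np.max(np.abs(new - old)) < ALT_TOL:
            converged = True
            break

    return {
        "beta0": float(beta[0, 0]),
        "beta1": float(beta[0, 1]),
        "theta": float(theta[0]),
        "se_beta0": float(se_b[0, 0]),
        "se_beta1": float(se_b[0, 1]),
        "se_theta": float(se_th[0]),
        "method": "nb_alternating",
        "converged": converged,
    }


def fit_gene_models(
    counts: CountMatrix,
    depths,
    method: str = "poisson_theta",
    genes=None,
    theta_cap: float = THETA_CAP,
    epsilon: float = 1.0,
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Fit the per-gene depth-regression model for many genes.

    Parameters
    ----------
    counts : CountMatrix
    depths : (n_cells,) per-cell total UMI, all > 0
    method : {"poisson_theta", "poisson_theta_refit", "nb_alternating"}
    genes : optional list of gene ids to fit (defaults to all)

    Returns
    -------
    DataFrame indexed by gene_id with columns gmean, beta0, beta1, theta,
    se_beta0, se_beta1, se_theta, method, converged, theta_boundary.
    Genes whose fit fails are dropped with a logged reason.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    m = np.asarray(depths, dtype=float)
    if np.any(m <= 0):
        raise ValueError("all depths must be positive; drop empty cells first")
    t = np.log10(m)
    _check_design(t)

    gm = gene_means(counts, epsilon=epsilon)
    if genes is None:
        gene_list = list(counts.gene_ids)
    else:
        unknown = set(genes) - set(counts.gene_ids)
        if unknown:
            raise ValueError(f"unknown genes: {sorted(unknown)[:5]} ...")
        gene_list = list(genes)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = [gene_pos[g] for g in gene_list]

    frames = []
    for start in range(0, len(rows), chunk_size):
        idx = rows[start:start + chunk_size]
        x = np.asarray(counts.values[idx].todense(), dtype=float)
        ok = x.sum(axis=1) > 0
        if not ok.all():
            for bad in np.flatnonzero(~ok):
                logger.warning("gene %s is all-zero; dropped", gene_list[start + bad])
            x = x[ok]
            idx = [i for i, o in zip(idx, ok) if o]
        if not len(idx):
            continue

        beta, se_b, conv_b = _irls_batch(x, t)
        mu = np.exp(np.clip(beta[:, [0]] + beta[:, [1]] * t[None, :], -690, 690))
        theta, se_th, bound = _theta_ml_batch(x, mu, theta_cap)

        if method == "poisson_theta_refit":
            beta, se_b, conv_b = _irls_batch(x, t, theta=theta)
        elif method == "nb_alternating":
            for _ in range(ALT_MAX_ITER):
                old = np.column_stack([beta, np.log(theta)])
                beta, se_b, conv_b = _irls_batch(x, t, theta=theta, beta_init=beta)
                mu = np.exp(np.clip(beta[:, [0]] + beta[:, [1]] * t[None, :], -690, 690))
                theta, se_th, bound = _theta_ml_batch(x, mu, theta_cap)
                new = np.column_stack([beta, np.log(theta)])
                if np.max(np.abs(new - old)) < ALT_TOL:
                    break

        ids = [counts.gene_ids[i] for i in idx]
        frames.append(
            pd.DataFrame(
                {
                    "gmean": gm["gmean"].to_numpy()[idx],
                    "beta0": beta[:, 0],
                    "beta1": beta[:, 1],
                    "theta": theta,
                    "se_beta0": se_b[:, 0],
                    "se_beta1": se_b[:, 1],
                    "se_theta": se_th,
                    "method": method,
                    "converged": conv_b,
                    "theta_boundary": bound,
                },
                index=pd.Index(ids, name="gene_id"),
            )
        )
    if not frames:
        raise ValueError("no gene could be fitted")
    table = pd.concat(frames)
    failed = ~np.isfinite(table[["beta0", "beta1", "theta"]]).all(axis=1)
    if failed.any():
        for g in table.index[failed]:
            logger.warning("gene %s: non-finite fit; dropped", g)
        table = table[~failed]
    return table
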