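import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nbvst import (
    CountMatrix,
    CovariateSpec,
    ResidualMatrix,
    RegularizedNBModel,
    default_gene_params,
    fit_with_covariates,
    log_normalize,
    pearson_residuals,
    rank_variable_genes,
    residual_summaries,
    simulate_homogeneous,
)


def _model_table(gene_ids, beta0, beta1, theta, gmean=1.0):
    n = len(gene_ids)
    return pd.DataFrame(
        {
            "gmean": np.full(n, gmean),
            "beta0_reg": np.broadcast_to(beta0, n).astype(float),
            "beta1_reg": np.broadcast_to(beta1, n).astype(float),
            "theta_reg": np.broadcast_to(theta, n).astype(float),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


class TestPearsonResiduals:
    def test_direct_formula_evaluation(self):
        # mu = exp(-ln 1000 + ln 10 * log10 2000) = 2; sigma = sqrt(2 + 4/10)
        counts = CountMatrix(sp.csr_matrix(np.array([[5]])), ["g"], ["c"])
        model = _model_table(["g"], -np.log(1000.0), np.log(10.0), 10.0)
        res = pearson_residuals(counts, model, np.array([2000.0]), clip="none")
        assert res.values[0, 0] == pytest.approx(3.0 / np.sqrt(2.4), rel=1e-9)

    def test_counts_equal_to_the_mean_give_zero(self):
        counts = CountMatrix(sp.csr_matrix(np.array([[2, 4]])), ["g"], ["c1", "c2"])
        model = _model_table(["g"], np.log(2.0) - np.log(10.0) * 3, np.log(10.0), 5.0)
        res = pearson_residuals(counts, model, np.array([1000.0, 2000.0]))
        assert res.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_poisson_limit_matches_sqrt_mu_scaling(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(3.0, size=(1, 50))
        counts = CountMatrix(sp.csr_matrix(x), ["g"], [f"c{j}" for j in range(50)])
        m = np.full(50, 1000.0)
        beta0 = np.log(3.0) - np.log(10.0) * 3
        model_nb = _model_table(["g"], beta0, np.log(10.0), 1e6)
        res = pearson_residuals(counts, model_nb, m, clip="none")
        mu = 3.0
        expected = (x[0] - mu) / np.sqrt(mu)
        np.testing.assert_allclose(res.values[0], expected, rtol=1e-3, atol=1e-9)

    def test_clipping_at_sqrt_n(self):
        # 100 cells: an unclipped residual of 15 is stored as 10
        x = np.zeros((1, 100))
        x[0, 0] = 47
        counts = CountMatrix(sp.csr_matrix(x))
        m = np.full(100, 1000.0)
        model = _model_table(["gene0"], np.log(2.0) - 3 * np.log(10.0), np.log(10.0), 1e6)
        raw = pearson_residuals(counts, model, m, clip="none")
        assert raw.values[0, 0] > 10
        clipped = pearson_residuals(counts, model, m, clip="sqrt_n")
        assert clipped.clip_value == pytest.approx(10.0)
        assert clipped.values[0, 0] == pytest.approx(10.0)
        assert np.all(np.abs(clipped.values) <= 10.0)

    def test_invalid_theta_errors_with_gene_name(self):
        counts = CountMatrix(sp.csr_matrix(np.array([[1, 2]])), ["badgene"], ["a", "b"])
        model = _model_table(["badgene"], 0.0, 0.0, -1.0)
        with pytest.raises(ValueError, match="badgene"):
            pearson_residuals(counts, model, np.array([10.0, 20.0]))


class TestResidualSummaries:
    def test_two_cell_hand_arithmetic(self):
        res = ResidualMatrix(np.array([[1.0, -1.0], [2.0, 0.0]]), ["a", "b"], ["c1", "c2"])
        summ = residual_summaries(res)
        np.testing.assert_allclose(summ["residual_mean"], [0.0, 1.0])
        np.testing.assert_allclose(summ["residual_variance"], [2.0, 2.0])

    def test_constant_row_has_zero_variance(self):
        res = ResidualMatrix(np.zeros((1, 5)), ["a"], [f"c{j}" for j in range(5)])
        summ = residual_summaries(res)
        assert summ.loc["a", "residual_mean"] == 0.0
        assert summ.loc["a", "residual_variance"] == 0.0


class TestRankVariableGenes:
    def test_full_ranking_is_a_permutation(self):
        rng = np.random.default_rng(7)
        res = ResidualMatrix(
            rng.normal(size=(10, 20)), [f"g{i}" for i in range(10)],
            [f"c{j}" for j in range(20)],
        )
        ranked = rank_variable_genes(res)
        assert sorted(ranked.index) == sorted(res.gene_ids)
        rv = ranked["residual_variance"].to_numpy()
        assert np.all(np.diff(rv) <= 1e-12)

    def test_variance_tie_broken_by_gmean_then_name(self):
        vals = np.array([[1.0, -1.0], [1.0, -1.0], [1.0, -1.0]])
        res = ResidualMatrix(vals, ["b", "a", "c"], ["c1", "c2"])
        gmeans = pd.Series([2.0, 1.0, 2.0], index=["b", "a", "c"])
        ranked = rank_variable_genes(res, gmeans=gmeans)
        assert list(ranked.index) == ["b", "c", "a"]


class TestDepthIndependence:
    def test_residuals_uncorrelated_with_depth(self, homogeneous_sim, homogeneous_fit):
        res = homogeneous_fit
        z = res.residuals.values
        m = res.model.depths
        zc = z - z.mean(axis=1, keepdims=True)
        mc = np.log10(m) - np.log10(m).mean()
        cors = (zc @ mc) / np.sqrt((zc**2).sum(axis=1) * (mc**2).sum())
        assert np.median(np.abs(cors)) < 0.05
        # the log-normalization baseline fails this for abundant genes
        ln = log_normalize(res.model.counts, m)
        lc = ln.values - ln.values.mean(axis=1, keepdims=True)
        lcors = (lc @ mc) / np.sqrt((lc**2).sum(axis=1) * (mc**2).sum())
        abundant = res.gene_means.loc[res.residuals.gene_ids, "gmean"] > 1.0
        assert np.median(np.abs(lcors[abundant.to_numpy()])) > 0.05

    def test_clipping_touches_under_one_percent_of_entries(self, homogeneous_fit):
        res = homogeneous_fit.residuals
        frac = np.mean(np.abs(res.values) >= res.clip_value - 1e-12)
        assert frac < 0.01


class TestLogNormalize:
    def test_formula(self):
        counts = CountMatrix(sp.csr_matrix(np.array([[3, 0]])), ["g"], ["a", "b"])
        out = log_normalize(counts, np.array([100.0, 50.0]))
        assert out.values[0, 0] == pytest.approx(np.log(1e4 * 3 / 100 + 1))
        assert out.values[0, 1] == pytest.approx(0.0)


class TestCovariates:
    def test_zero_covariate_reduces_to_plain_residuals(self):
        params = default_gene_params(50, seed=1, gmean_range=(0.1, 5), profile="log_uniform")
        ds = simulate_homogeneous(params, n_cells=300, seed=2)
        model = RegularizedNBModel(ds.counts, n_genes=40, seed=3)
        res = model.fit()
        cres, coef = fit_with_covariates(
            model.counts, model.depths, res.regularized,
            [CovariateSpec("null", np.zeros(model.counts.n_cells))],
        )
        np.testing.assert_allclose(cres.values, res.residuals.values, rtol=1e-9)
        assert coef.shape[1] == 0

    def test_collinear_covariates_rejected(self):
        params = default_gene_params(30, seed=4, gmean_range=(0.1, 5), profile="log_uniform")
        ds = simulate_homogeneous(params, n_cells=200, seed=5)
        model = RegularizedNBModel(ds.counts, n_genes=25, seed=6)
        res = model.fit()
        v = np.arange(model.counts.n_cells, dtype=float)
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_with_covariates(
                model.counts, model.depths, res.regularized,
                [CovariateSpec("a", v), CovariateSpec("b", 2.0 * v)],
            )

    def test_planted_batch_effect_recovered(self):
        # e^0.5 shift for a minority batch on low-mass genes; high-mass or
        # global shifts are partially absorbed by the depth covariate
        params = default_gene_params(300, seed=95, gmean_range=(0.1, 10),
                                     profile="log_uniform")
        rng = np.random.default_rng(96)
        n_cells = 2500
        ds = simulate_homogeneous(params, n_cells=n_cells, seed=97)
        batch = (rng.random(n_cells) < 0.08).astype(int)
        g = params["gmean"].to_numpy()
        affected = (rng.random(300) < 0.25) & (g < 1.0)
        mu = np.exp(
            params["beta0"].to_numpy()[:, None]
            + params["beta1"].to_numpy()[:, None] * np.log10(ds.depths)[None, :]
        )
        mu[np.ix_(affected, batch == 1)] *= np.exp(0.5)
        th = params["theta"].to_numpy()[:, None]
        x = rng.negative_binomial(np.broadcast_to(th, mu.shape), th / (th + mu))
        counts = CountMatrix(
            sp.csr_matrix(x), list(params.index), [f"c{j}" for j in range(n_cells)]
        )
        model = RegularizedNBModel(counts, n_genes=150, seed=98)
        res = model.fit()
        _, coef = fit_with_covariates(
            model.counts, model.depths, res.regularized,
            [CovariateSpec("batch", batch.astype(str))],
        )
        gm = res.gene_means.loc[coef.index, "gmean"]
        aff = np.array(
            [affected[list(params.index).index(gn)] for gn in coef.index]
        )
        sel = aff & (gm > 0.1).to_numpy()
        err = (coef.loc[sel].iloc[:, 0] - 0.5).abs().median()
        assert err < 0.1
        # genes without a planted effect stay centered at zero
        assert abs(coef.loc[~aff].iloc[:, 0].median()) < 0.05
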