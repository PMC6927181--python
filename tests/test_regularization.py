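import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nbvst import kernel_smooth, regularize, sample_estimation_genes, sj_bandwidth
from nbvst.regularization import KSMOOTH_SIGMA

# frozen reference values from R (bw.SJ and ksmooth, R 4.3)
R_BW_SJ_NORMAL_N1000 = 0.25383851
R_KSMOOTH_X = np.array([0.0, 0.3, 0.9, 1.4, 2.2, 3.0, 3.1, 4.0])
R_KSMOOTH_Y = np.array([1.0, 0.5, 2.0, 1.5, 0.2, 2.5, 1.0, 0.7])
R_KSMOOTH_QUERIES = np.array([0.5, 1.0, 2.0, 3.5])
R_KSMOOTH_VALUES = np.array(
    [1.1251774896, 1.5606393334, 0.7600417049, 1.3592630230]
)


class TestSJBandwidth:
    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2024)
        x = rng.standard_normal(1000)
        assert sj_bandwidth(x) == pytest.approx(R_BW_SJ_NORMAL_N1000, rel=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        h = sj_bandwidth(x)
        assert sj_bandwidth(5.0 * x) == pytest.approx(5.0 * h, rel=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(300)
        assert sj_bandwidth(x + 17.0) == pytest.approx(sj_bandwidth(x), rel=1e-6)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            sj_bandwidth(np.arange(5, dtype=float))


class TestKernelSmooth:
    def test_matches_r_ksmooth(self):
        out = kernel_smooth(R_KSMOOTH_QUERIES, R_KSMOOTH_X, R_KSMOOTH_Y, 1.2)
        np.testing.assert_allclose(out, R_KSMOOTH_VALUES, atol=2e-4)

    def test_constant_values_stay_constant(self):
        out = kernel_smooth(
            np.linspace(-5, 5, 30), np.array([0.0, 1.0, 2.0]), np.full(3, 4.2), 0.7
        )
        np.testing.assert_allclose(out, 4.2)

    def test_output_is_a_convex_combination(self):
        rng = np.random.default_rng(3)
        xd, yd = rng.normal(size=60), rng.normal(size=60)
        out = kernel_smooth(np.linspace(-4, 4, 100), xd, yd, 0.5)
        assert out.min() >= yd.min() - 1e-12
        assert out.max() <= yd.max() + 1e-12

    def test_three_point_hand_calculation(self):
        # kernel sigma = 1 when bandwidth = 1/KSMOOTH_SIGMA; weights at
        # distances (1, 0, 1) from the query
        bw = 1.0 / KSMOOTH_SIGMA
        out = kernel_smooth([1.0], [0.0, 1.0, 2.0], [0.0, 1.0, 0.0], bw)
        w0, w1 = stats.norm.pdf(1.0), stats.norm.pdf(0.0)
        assert out[0] == pytest.approx(w1 / (2 * w0 + w1), rel=1e-9)

    def test_far_query_falls_back_to_nearest_value(self):
        out = kernel_smooth([1e4], [0.0, 1.0], [2.0, 5.0], 0.1)
        assert out[0] == pytest.approx(5.0)


class TestSampleEstimationGenes:
    @staticmethod
    def _gmeans(n=200, seed=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"gmean": 10.0 ** rng.uniform(-2, 1, n)},
            index=[f"g{i}" for i in range(n)],
        )

    def test_requesting_all_genes_returns_all(self):
        gm = self._gmeans()
        assert sample_estimation_genes(gm, len(gm), seed=0) == list(gm.index)

    def test_deterministic_given_seed(self):
        gm = self._gmeans()
        assert sample_estimation_genes(gm, 50, seed=9) == sample_estimation_genes(
            gm, 50, seed=9
        )
        assert sample_estimation_genes(gm, 50, seed=9) != sample_estimation_genes(
            gm, 50, seed=10
        )

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            sample_estimation_genes(self._gmeans(), 0, seed=0)

    def test_density_weighting_flattens_a_bimodal_abundance_profile(self):
        # bimodal density over a dense support: the average histogram of
        # selected genes over 10 equal-width log-abundance bins is uniform
        rng = np.random.default_rng(5)
        logg = np.concatenate(
            [
                rng.uniform(-2, 1.5, 360),
                rng.normal(-1.2, 0.2, 150),
                rng.normal(0.5, 0.25, 90),
            ]
        )
        logg = logg[(logg >= -2) & (logg <= 1.5)]
        gm = pd.DataFrame(
            {"gmean": 10.0**logg}, index=[f"g{i}" for i in range(len(logg))]
        )
        edges = np.linspace(logg.min(), logg.max() + 1e-9, 11)
        n_sel, n_seeds = 60, 40
        counts = np.zeros(10)
        for s in range(n_seeds):
            sel = sample_estimation_genes(gm, n_sel, seed=s)
            h, _ = np.histogram(np.log10(gm.loc[sel, "gmean"]), bins=edges)
            counts = counts + h
        avg = counts / n_seeds
        chi2 = ((avg - n_sel / 10) ** 2 / (n_sel / 10)).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01


class TestRegularize:
    @staticmethod
    def _raw(n=300, seed=6, noise=0.0):
        rng = np.random.default_rng(seed)
        lg = np.sort(rng.uniform(-2, 1.5, n))
        return pd.DataFrame(
            {
                "gmean": 10.0**lg,
                "beta0": -6.0 + noise * rng.normal(size=n),
                "beta1": 2.3 + noise * rng.normal(size=n),
                "theta": np.full(n, 2.0),
                "converged": True,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_constant_parameters_stay_constant_for_every_gene(self):
        raw = self._raw()
        reg, bw = regularize(raw, raw[["gmean"]], baf=3.0)
        np.testing.assert_allclose(reg["beta0_reg"], -6.0, atol=1e-9)
        np.testing.assert_allclose(reg["beta1_reg"], 2.3, atol=1e-9)
        np.testing.assert_allclose(reg["theta_reg"], 2.0, rtol=1e-9)
        assert set(bw) == {"beta0", "beta1", "theta"}

    def test_deterministic(self):
        raw = self._raw(noise=0.2)
        a, _ = regularize(raw, raw[["gmean"]], baf=3.0)
        b, _ = regularize(raw, raw[["gmean"]], baf=3.0)
        pd.testing.assert_frame_equal(a, b)

    def test_values_bounded_by_raw_range(self):
        raw = self._raw(noise=0.5)
        reg, _ = regularize(raw, raw[["gmean"]], baf=2.0)
        assert reg["beta1_reg"].min() >= raw["beta1"].min() - 1e-12
        assert reg["beta1_reg"].max() <= raw["beta1"].max() + 1e-12

    def test_genes_outside_subset_receive_values(self):
        raw = self._raw(n=100, noise=0.1)
        all_gm = pd.DataFrame(
            {"gmean": 10.0 ** np.linspace(-2.5, 2.0, 500)},
            index=[f"q{i}" for i in range(500)],
        )
        reg, _ = regularize(raw, all_gm, baf=3.0)
        assert len(reg) == 500
        assert np.isfinite(reg[["beta0_reg", "beta1_reg", "theta_reg"]]).all().all()
        assert (reg["theta_reg"] > 0).all()

    def test_smoothing_denoises_a_known_curve(self):
        # raw beta1 = smooth curve + N(0, 0.3) noise: the regularized curve
        # must be closer to the truth than the raw values, for every seed
        wins = 0
        for s in range(13):
            rng = np.random.default_rng(50 + s)
            lg = np.sort(rng.uniform(-2, 1.5, 600))
            true = 2.3 + 0.3 * np.sin(2 * lg)
            noisy = true + rng.normal(0, 0.3, 600)
            raw = pd.DataFrame(
                {
                    "gmean": 10.0**lg,
                    "beta0": noisy,
                    "beta1": noisy,
                    "theta": 1.0,
                    "converged": True,
                },
                index=[f"g{i}" for i in range(600)],
            )
            reg, _ = regularize(raw, raw[["gmean"]], baf=3.0)
            rmse_reg = np.sqrt(np.mean((reg["beta1_reg"].to_numpy() - true) ** 2))
            rmse_raw = np.sqrt(np.mean((noisy - true) ** 2))
            wins += rmse_reg < rmse_raw
        assert wins >= 12

    def test_invalid_baf_rejected(self):
        raw = self._raw()
        with pytest.raises(ValueError):
            regularize(raw, raw[["gmean"]], baf=0.0)

    def test_residual_variances_robust_to_moderate_bandwidth_change(self):
        # tripling the bandwidth adjustment factor barely moves the
        # per-gene residual variances; very large factors (kernel spanning
        # a third of the abundance range) oversmooth and are not robust
        from nbvst import RegularizedNBModel, default_gene_params, simulate_homogeneous

        params = default_gene_params(2000, seed=81)
        ds = simulate_homogeneous(params, n_cells=1500, seed=82)
        rv = {}
        for baf in (1.0, 3.0):
            res = RegularizedNBModel(ds.counts, n_genes=400, baf=baf, seed=83).fit()
            rv[baf] = res.gene_summary["residual_variance"]
        change = ((rv[3.0] - rv[1.0]).abs() / rv[1.0]).median()
        assert change < 0.05
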