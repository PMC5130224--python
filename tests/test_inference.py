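"""MCMC engine: oracle equivalence, DIC arithmetic, PIT, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import pesticar as pc
from pesticar.inference import central_interval, deviance
from pesticar.models import build_design_matrix, FixedEffectTerm, ModelSpec

from conftest import make_toy_panel


def conjugate_quadrature_oracle(x, y, prior_prec, a=1.0, b=5e-5, n_grid=3000):
    """Brute-force posterior of beta in a Gaussian linear model.

    Integrates the conditional Gaussian posterior over the error precision
    (Gamma(a, b) prior) on a fine log-precision grid: an independent oracle
    for the MCMC path.
    """
    n, p = x.shape
    grid = np.linspace(-6, 26, n_grid)
    logw = np.empty(n_grid)
    means = np.empty((n_grid, p))
    covs = np.empty((n_grid, p, p))
    pmat = np.diag(prior_prec)
    for k, l in enumerate(grid):
        tau = np.exp(l)
        q = x.T @ x * tau + pmat
        bvec = x.T @ y * tau
        m = np.linalg.solve(q, bvec)
        _, ld = np.linalg.slogdet(q)
        logw[k] = (0.5 * n * l - 0.5 * ld
                   - 0.5 * (tau * (y @ y) - bvec @ m)
                   + a * l - b * tau)
        means[k] = m
        covs[k] = np.linalg.inv(q)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    mean = w @ means
    cov = (np.einsum("k,kij->ij", w, covs)
           + np.einsum("k,ki,kj->ij", w, means - mean, means - mean))
    return mean, cov


def mcse(draws):
    """Monte-Carlo standard error of a chain mean via batch means."""
    n = len(draws)
    n_batch = max(int(np.sqrt(n)), 2)
    size = n // n_batch
    bm = draws[: n_batch * size].reshape(n_batch, size).mean(axis=1)
    return bm.std(ddof=1) / np.sqrt(n_batch)


class TestGaussianOracle:
    def test_intercept_only_posterior_mean(self):
        rows = [dict(county_id=f"C{i}", state_id="S1", year=1997,
                     y=float(i + 1) / 10, x_corn=0.1, x_cov=0.0, x_sw=0.1,
                     x_income=0.5, x_size=1.0, x_gdd=3.0, x_crop=0.5)
                for i in range(3)]
        panel = make_toy_panel(rows)
        panel.data["y"] = [1.0, 2.0, 3.0]
        spec = ModelSpec(model_id=1, fixed_terms=(
            FixedEffectTerm("intercept", "intercept", prior_precision=0.0),))
        fit = pc.fit_model(spec, panel, None,
                           pc.SamplerConfig(n_iterations=4000, n_burnin=500,
                                            thin=1, seed=1))
        m = fit.beta_draws[:, 0].mean()
        assert abs(m - 2.0) < 4 * mcse(fit.beta_draws[:, 0])

    @pytest.mark.parametrize("n_obs,seed", [(20, 2), (50, 3)])
    def test_model1_matches_conjugate_oracle(self, n_obs, seed):
        """Posterior mean and covariance of beta agree with the dense
        quadrature oracle within Monte-Carlo error."""
        cfg = pc.SimConfig(grid_rows=5, grid_cols=5, seed=seed,
                           generative_model=1)
        panel, _, _ = pc.simulate_panel(cfg)
        proc = pc.preprocess(panel, threshold=0.0)
        proc.data = proc.data.iloc[:n_obs].reset_index(drop=True)
        proc = pc.PanelDataset(proc.data, years=proc.years,
                               covariate_means=proc.covariate_means)
        spec = pc.make_model_spec(1, proc)
        x, names, prior_prec = build_design_matrix(spec, proc)
        y = proc.data["y"].to_numpy()
        o_mean, o_cov = conjugate_quadrature_oracle(x, y, prior_prec)

        fit = pc.fit_model(spec, proc, None,
                           pc.SamplerConfig(n_iterations=8000, n_burnin=1000,
                                            thin=1, seed=seed + 100))
        for j in range(x.shape[1]):
            se = mcse(fit.beta_draws[:, j])
            assert abs(fit.beta_draws[:, j].mean() - o_mean[j]) < 3 * se, names[j]
        ratio = fit.beta_draws.var(axis=0, ddof=1) / np.diag(o_cov)
        np.testing.assert_allclose(ratio, 1.0, atol=0.1)

    def test_saturated_design_means_still_match(self):
        """n = p = 8 is a near-saturated, slowly mixing design; posterior
        means still agree with the oracle given a long thinned chain."""
        cfg = pc.SimConfig(grid_rows=5, grid_cols=5, seed=2, generative_model=1)
        panel, _, _ = pc.simulate_panel(cfg)
        proc = pc.preprocess(panel, threshold=0.0)
        sub = pc.PanelDataset(proc.data.iloc[:8].reset_index(drop=True),
                              years=proc.years,
                              covariate_means=proc.covariate_means)
        spec = pc.make_model_spec(1, sub)
        x, names, prior_prec = build_design_matrix(spec, sub)
        o_mean, _ = conjugate_quadrature_oracle(
            x, sub.data["y"].to_numpy(), prior_prec)
        fit = pc.fit_model(spec, sub, None,
                           pc.SamplerConfig(n_iterations=30_000, n_burnin=2000,
                                            thin=3, seed=55))
        for j in range(x.shape[1]):
            se = mcse(fit.beta_draws[:, j])
            assert abs(fit.beta_draws[:, j].mean() - o_mean[j]) < 3 * se, names[j]


class TestDic:
    def test_direct_formula(self):
        dic, p_d = pc.compute_dic([10.0, 12.0, 14.0], 10.0)
        assert p_d == pytest.approx(2.0)
        assert dic == pytest.approx(14.0)

    def test_constant_trace(self):
        dic, p_d = pc.compute_dic([7.0, 7.0], 7.0)
        assert p_d == 0.0 and dic == 7.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            pc.compute_dic([], 0.0)

    def test_delta_dic(self):
        out = pc.delta_dic({1: -12798.0, 6: -23668.0})
        assert out == {1: 10870.0, 6: 0.0}
        assert pc.delta_dic({4: -5.0}) == {4: 0.0}

    def test_dic_stable_across_seeds(self, small_sim):
        proc, graph, truth, _ = small_sim
        spec = pc.make_model_spec(4, proc)
        dics = []
        for seed in (1, 2):
            fit = pc.fit_model(spec, proc, None,
                               pc.SamplerConfig(n_iterations=1500, n_burnin=500,
                                                thin=1, seed=seed))
            dics.append(fit.dic)
        assert abs(dics[0] - dics[1]) < 0.05 * abs(np.mean(dics))


class TestPit:
    def test_extreme_and_median_observations(self, small_sim):
        proc, graph, truth, _ = small_sim
        spec = pc.make_model_spec(1, proc)
        fit = pc.fit_model(spec, proc, None,
                           pc.SamplerConfig(n_iterations=1000, n_burnin=300,
                                            thin=1, seed=5))
        pit = pc.compute_pit(fit, proc)
        assert np.all((pit >= 0) & (pit <= 1))
        # shift one observation far above all predictive mass
        shifted = proc.copy()
        shifted.data.loc[0, "y"] += 50.0
        pit2 = pc.compute_pit(fit, shifted)
        assert pit2[0] > 0.999
        # an observation at the predictive mean scores near 1/2
        at_mean = proc.copy()
        at_mean.data.loc[0, "y"] = fit.mu_mean[0]
        pit3 = pc.compute_pit(fit, at_mean)
        assert abs(pit3[0] - 0.5) < 0.05

    def test_calibrated_model_gives_uniform_pit(self, replicate_fits_m1_m4_m6):
        """On data simulated from the fitted model the PIT chi-square
        statistic stays non-extreme in most replicates."""
        from scipy.stats import chi2

        ok = 0
        reps = replicate_fits_m1_m4_m6
        for proc, graph, truth, fits in reps:
            summary = pc.pit_uniformity_summary(fits[6].pit, n_bins=20)
            ok += summary.chi_square < chi2.ppf(0.99, summary.dof)
        assert ok >= 0.9 * len(reps)


class TestReproducibility:
    def test_identical_seed_identical_draws(self, small_sim):
        proc, graph, truth, _ = small_sim
        spec = pc.make_model_spec(6, proc, graph)
        config = pc.SamplerConfig(n_iterations=120, n_burnin=40, thin=1, seed=11)
        a = pc.fit_model(spec, proc, graph, config)
        b = pc.fit_model(spec, proc, graph, config)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.sigma2_draws, b.sigma2_draws)
        np.testing.assert_array_equal(a.rho_draws["icar_ar1_intercept"],
                                      b.rho_draws["icar_ar1_intercept"])

    def test_deviance_definition(self):
        y = np.array([0.0, 1.0])
        mu = np.array([0.0, 1.0])
        assert deviance(y, mu, 1.0) == pytest.approx(2 * np.log(2 * np.pi))


class TestSummary:
    def test_normal_sample_quantiles(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(100_000)
        lo, hi = central_interval(draws, 0.95)
        assert abs(lo + 1.96) < 0.03 and abs(hi - 1.96) < 0.03

    def test_summary_table_contents(self, small_sim):
        proc, graph, truth, _ = small_sim
        spec = pc.make_model_spec(4, proc)
        fit = pc.fit_model(spec, proc, None,
                           pc.SamplerConfig(n_iterations=600, n_burnin=200,
                                            thin=2, seed=8))
        s = fit.summary()
        assert {"mean", "q2.5", "q97.5", "p_le_zero"} <= set(s.columns)
        assert (s["q2.5"] <= s["mean"]).all() and (s["mean"] <= s["q97.5"]).all()
        draws = fit.beta_draws[:, fit.term_names.index("x_corn")]
        if (draws > 0).all():
            assert s.loc["x_corn", "p_le_zero"] == 0.0
        assert fit.dic == pytest.approx(
            fit.deviance_trace.mean() + fit.p_d)

    def test_write_fit_outputs(self, tmp_path, small_sim):
        proc, graph, truth, _ = small_sim
        spec = pc.make_model_spec(1, proc)
        fit = pc.fit_model(spec, proc, None,
                           pc.SamplerConfig(n_iterations=200, n_burnin=50,
                                            thin=1, seed=4))
        pc.write_fit(fit, tmp_path / "fit")
        assert (tmp_path / "fit" / "summary.csv").exists()
        assert (tmp_path / "fit" / "metadata.json").exists()

    def test_variance_component_recovery_model4(self):
        """Posterior intervals bracket the generating scales for Model 4."""
        hits = {"sigma": 0, "sd_county": 0}
        n_rep = 6
        for r in range(n_rep):
            cfg = pc.SimConfig(grid_rows=12, grid_cols=12, seed=600 + r,
                               generative_model=4, tau_iid_county=1.0 / 0.05**2)
            panel, graph0, _ = pc.simulate_panel(cfg)
            proc = pc.preprocess(panel, threshold=0.0)
            spec = pc.make_model_spec(4, proc)
            fit = pc.fit_model(spec, proc, None,
                               pc.SamplerConfig(n_iterations=800, n_burnin=300,
                                                thin=1, seed=700 + r))
            lo, hi = central_interval(np.sqrt(fit.sigma2_draws), 0.95)
            hits["sigma"] += lo <= cfg.sigma <= hi
            lo, hi = central_interval(
                1 / np.sqrt(fit.tau_draws["iid_county"]), 0.95)
            hits["sd_county"] += lo <= 0.05 <= hi
        assert hits["sigma"] >= n_rep - 1
        assert hits["sd_county"] >= n_rep - 1
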