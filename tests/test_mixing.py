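"""Algebraic and Bayesian marine-fraction estimators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isomix.mixing import (
    DegenerateLikelihoodError,
    DietEstimate,
    MCMCConfig,
    _log_likelihood,
    alpha_marine_fraction,
    compare_estimators,
    fit_population,
    fit_two_source_model,
    grid_posterior_mean,
    split_rhat,
)
from isomix.records import CLAW, SourceDistribution

from conftest import make_consumer


class TestAlpha:
    def test_endpoint_and_midpoint_values(self):
        for d13c, want in [(-26.8, 0.0), (-7.6, 100.0), (-17.2, 50.0)]:
            value, out_of_range = alpha_marine_fraction(d13c, 3.8, -30.6, -11.4)
            assert value == pytest.approx(want, abs=1e-12)
            assert not out_of_range

    def test_clamped_with_flag(self):
        value, oor = alpha_marine_fraction(-5.0, 3.8, -30.6, -11.4)
        assert value == 100.0 and oor
        value, oor = alpha_marine_fraction(-29.0, 3.8, -30.6, -11.4)
        assert value == 0.0 and oor

    def test_equal_endmembers_undefined(self):
        with pytest.raises(ValueError, match="equal endmember"):
            alpha_marine_fraction(-18.0, 3.8, -20.0, -20.0)

    @given(st.floats(min_value=-26.79, max_value=-7.61),
           st.floats(min_value=0.01, max_value=5.0))
    def test_strictly_monotone_between_endmembers(self, d13c, eps):
        lo, _ = alpha_marine_fraction(d13c, 3.8, -30.6, -11.4)
        hi, _ = alpha_marine_fraction(min(d13c + eps, -7.6), 3.8, -30.6, -11.4)
        if d13c + eps <= -7.6:
            assert hi > lo


class TestBayesianModel:
    def test_mcmc_matches_grid_oracle(self, random_consumers, sources, claw):
        """Posterior mean from the sampler agrees with 1001-point quadrature."""
        for k, (consumer, _) in enumerate(random_consumers):
            est = fit_two_source_model(consumer, sources, claw, MCMCConfig(seed=100 + k))
            grid = grid_posterior_mean(consumer, sources, claw)
            assert est.p_marine_mean == pytest.approx(grid, abs=0.02)

    def test_consumer_at_marine_endmember(self, claw):
        mar = SourceDistribution("marine", -10.0, 9.0, 0.3, 0.3)
        ter = SourceDistribution("terrestrial", -28.0, 2.0, 0.3, 0.3)
        c = make_consumer("m", mar.mu_C + claw.dC_mean, mar.mu_N + claw.dN_mean)
        assert grid_posterior_mean(c, (mar, ter), claw) > 0.9
        est = fit_two_source_model(c, (mar, ter), claw, MCMCConfig(seed=1))
        assert est.p_marine_mean > 0.9

    def test_symmetric_midpoint_gives_half(self, claw):
        mar = SourceDistribution("marine", -10.0, 9.0, 1.2, 1.2)
        ter = SourceDistribution("terrestrial", -25.6, 2.0, 1.2, 1.2)
        mid_C = (mar.mu_C + ter.mu_C) / 2 + claw.dC_mean
        mid_N = (mar.mu_N + ter.mu_N) / 2 + claw.dN_mean
        est = fit_two_source_model(make_consumer("mid", mid_C, mid_N), (mar, ter),
                                   claw, MCMCConfig(seed=5))
        assert est.p_marine_mean == pytest.approx(0.5, abs=0.02)

    def test_flat_likelihood_recovers_uniform_prior_mean(self, claw):
        mar = SourceDistribution("marine", -10.0, 9.0, 500.0, 500.0)
        ter = SourceDistribution("terrestrial", -28.0, 2.0, 500.0, 500.0)
        est = fit_two_source_model(make_consumer("f", -18.0, 6.0), (mar, ter),
                                   claw, MCMCConfig(seed=5))
        assert est.p_marine_mean == pytest.approx(0.5, abs=0.03)

    def test_draws_on_simplex_and_ci_ordering(self, sources, claw):
        est = fit_two_source_model(make_consumer("x", -18.0, 6.0), sources, claw,
                                   MCMCConfig(seed=9))
        assert np.all(est.draws >= 0) and np.all(est.draws <= 1)
        median = np.median(est.draws)
        assert est.ci_low <= median <= est.ci_high
        assert est.rhat <= 1.05 and est.flags == []

    def test_zero_variance_degenerate(self, claw):
        mar = SourceDistribution("marine", -10.0, 9.0, 0.0, 0.0)
        ter = SourceDistribution("terrestrial", -28.0, 2.0, 0.0, 0.0)
        disc = type(claw)("claw", dC_mean=1.2, dC_sd=0.0, dN_mean=0.7, dN_sd=0.0)
        with pytest.raises(DegenerateLikelihoodError):
            fit_two_source_model(make_consumer("z", -5.0, 20.0), (mar, ter), disc,
                                 MCMCConfig(seed=1))

    def test_label_swap_mirrors_posterior_on_grid(self, sources, claw):
        """Exchanging which source is 'marine' maps p to 1-p in the posterior
        (asserted on the quadrature route, which is order-explicit)."""
        from isomix.mixing import _mixture_moments

        mu, var, _ = _mixture_moments(sources, claw)
        x = np.array([-18.0, 6.0])
        p = np.linspace(0.0, 1.0, 1001)
        ll = _log_likelihood(p, x, mu, var)
        ll_sw = _log_likelihood(p, x, mu[::-1].copy(), var[::-1].copy())
        w, w_sw = np.exp(ll - ll.max()), np.exp(ll_sw - ll_sw.max())
        mean = np.sum(p * w) / np.sum(w)
        mean_sw = np.sum(p * w_sw) / np.sum(w_sw)
        assert mean_sw == pytest.approx(1.0 - mean, abs=1e-9)

    def test_same_seed_reproduces_draws(self, sources, claw):
        c = make_consumer("r", -16.0, 7.0)
        a = fit_two_source_model(c, sources, claw, MCMCConfig(seed=11))
        b = fit_two_source_model(c, sources, claw, MCMCConfig(seed=11))
        assert np.array_equal(a.draws, b.draws)

    def test_split_rhat_matches_arviz(self, sources, claw):
        arviz = pytest.importorskip("arviz")
        est = fit_two_source_model(make_consumer("r", -16.0, 7.0), sources, claw,
                                   MCMCConfig(seed=3))
        chains = est.draws.reshape(2, -1)
        ours = float(split_rhat(chains[:, :, None])[0])
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains[:, :, None]),
                                  method="split")["x"].values.squeeze())
        assert ours == pytest.approx(theirs, abs=0.01)


class TestPopulation:
    def test_single_consumer_site_mean(self, sources, claw):
        ests, site = fit_population([make_consumer("only", -18.0, 6.0, site="PR")],
                                    sources, claw, MCMCConfig(seed=2))
        assert site.loc[0, "pct_marine_mean"] == pytest.approx(ests[0].percent)

    def test_two_point_site_sd(self):
        ests = [DietEstimate("a", "alpha", 0.2, site="S"),
                DietEstimate("b", "alpha", 0.6, site="S")]
        from isomix.mixing import aggregate_alpha
        df = aggregate_alpha(ests)
        assert df.loc[0, "pct_marine_mean"] == pytest.approx(40.0)
        assert df.loc[0, "pct_marine_sd"] == pytest.approx(28.2843, abs=1e-3)

    def test_site_mean_recovery_30_consumers(self, sources, claw):
        """Simulation oracle: the site mean tracks the truth within 2 MC SEs."""
        rng = np.random.default_rng(8)
        mar, ter = sources
        mu = np.array([[mar.mu_C + claw.dC_mean, mar.mu_N + claw.dN_mean],
                       [ter.mu_C + claw.dC_mean, ter.mu_N + claw.dN_mean]])
        var = np.array([[mar.sd_C, mar.sd_N], [ter.sd_C, ter.sd_N]]) ** 2 \
            + np.array([claw.dC_sd, claw.dN_sd]) ** 2
        p_true = 0.35
        consumers = []
        for k in range(30):
            m = p_true * mu[0] + (1 - p_true) * mu[1]
            sd = np.sqrt(p_true**2 * var[0] + (1 - p_true) ** 2 * var[1])
            x = m + sd * rng.standard_normal(2)
            consumers.append(make_consumer(f"s{k}", float(x[0]), float(x[1]), site="S"))
        ests, site = fit_population(consumers, sources, claw, MCMCConfig(seed=8))
        pct = np.array([e.percent for e in ests])
        se = pct.std(ddof=1) / np.sqrt(len(pct))
        assert abs(site.loc[0, "pct_marine_mean"] - 100 * p_true) <= 2 * se + 1.0

    def test_empty_input_rejected(self, sources, claw):
        with pytest.raises(ValueError):
            fit_population([], sources, claw)


class TestCompare:
    def test_identical_and_arithmetic(self):
        b = [DietEstimate("a", "bayes", 0.51, site="S"), DietEstimate("b", "bayes", 0.2, site="S")]
        a = [DietEstimate("a", "alpha", 0.40, site="S"), DietEstimate("b", "alpha", 0.2, site="S")]
        df, summary = compare_estimators(b, a)
        assert df.set_index("sample_id").loc["a", "abs_diff_pct"] == pytest.approx(11.0)
        assert df.set_index("sample_id").loc["b", "abs_diff_pct"] == pytest.approx(0.0)
        assert summary["max_abs_diff_pct"] == pytest.approx(11.0)

    def test_unmatched_ids_error(self):
        with pytest.raises(ValueError, match="unmatched"):
            compare_estimators([DietEstimate("a", "bayes", 0.5)],
                               [DietEstimate("b", "alpha", 0.5)])

    def test_divergence_grows_with_marine_fraction(self, sources, claw):
        """On synthetic beach data the algebraic estimator drifts below the
        Bayesian one as diets become marine-leaning (positive rank correlation
        of the gap with p_marine)."""
        from scipy.stats import spearmanr

        from isomix.mixing import alpha_marine_fraction as amf
        from isomix.simulate import SyntheticConfig, simulate_study

        cfg = SyntheticConfig(seed=4)
        study = simulate_study(cfg)
        ests, _ = fit_population(study.beach_lizards,
                                 (cfg.marine_source, cfg.terrestrial_source),
                                 claw, MCMCConfig(seed=4))
        alpha = [DietEstimate(l.sample_id, "alpha",
                              amf(l.d13C, 3.8, cfg.blackberry_mu_C, cfg.algae_mu_C)[0] / 100,
                              site=l.site)
                 for l in study.beach_lizards]
        df, _ = compare_estimators(ests, alpha)
        merged = df.merge(study.truth, on="sample_id")
        upper = merged[merged["true_p_marine"] > 0.25]
        rho, _ = spearmanr(merged["true_p_marine"], merged["abs_diff_pct"])
        assert rho > 0
        assert upper["abs_diff_pct"].mean() >= merged["abs_diff_pct"].mean()
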