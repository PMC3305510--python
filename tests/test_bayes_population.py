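"""Bernoulli-logit posteriors, multiplier combination, convergence tools."""

import numpy as np
import pytest

from dogpop import (
    McmcSettings,
    PriorSpec,
    SurveyConfig,
    beta_oracle,
    credibility_interval,
    gelman_rubin,
    generate_survey,
    population_from_household_rate,
    population_from_subpop,
    proportion_posterior,
)
from helpers import make_dataset

from dogpop.synthetic_data import joint_from_marginals


class TestBetaOracle:
    def test_uniform_median(self):
        assert beta_oracle(1, 2, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 10, 50])
    def test_symmetric_median(self, k):
        assert beta_oracle(k, 2 * k, 0.5) == pytest.approx(0.5)

    def test_known_quantile(self):
        assert beta_oracle(73, 181, 0.5) == pytest.approx(0.4031, abs=5e-4)

    @pytest.mark.parametrize("y,n", [(0, 5), (5, 5)])
    def test_boundary_counts_rejected(self, y, n):
        with pytest.raises(ValueError):
            beta_oracle(y, n, 0.5)


class TestProportionPosteriorDogMode:
    def test_balanced_counts_centre_at_half(self, quick_mcmc):
        ds = make_dataset(
            {"a": [(1, True, 100)]},
            flags={("a", 1, j): (j < 50, False, False, False) for j in range(100)},
        )
        post = proportion_posterior(ds, "vet", mode="dog", settings=quick_mcmc(1))
        assert post.median() == pytest.approx(0.5, abs=0.02)

    def test_matches_beta_posterior_for_five_count_pairs(self):
        """Flat prior on the logit intercept induces Beta(y, n-y) on p; the
        sampler must agree within 0.01 at every checked quantile."""
        settings = McmcSettings(
            n_iterations=40_000, burn_in=5_000, thin=10, seed=2
        )
        for y, n in [(73, 181), (10, 40), (55, 181), (130, 181), (3, 12)]:
            ds = make_dataset(
                {"a": [(1, True, n)]},
                flags={("a", 1, j): (j < y, False, False, False) for j in range(n)},
            )
            post = proportion_posterior(
                ds, "vet", mode="dog", prior=PriorSpec("flat"), settings=settings
            )
            for q in (0.025, 0.25, 0.5, 0.75, 0.975):
                assert float(np.quantile(post.p, q)) == pytest.approx(
                    beta_oracle(y, n, q), abs=0.01
                )

    def test_retained_sample_count_is_exact(self, fixture_ds):
        settings = McmcSettings(n_iterations=100_000, burn_in=10_000, thin=50, seed=3)
        post = proportion_posterior(fixture_ds, "vet", mode="dog", settings=settings)
        assert post.p.size == 2 * (100_000 - 10_000) // 50 == 3600

    def test_degenerate_flags_warn_but_run(self, quick_mcmc, caplog):
        ds = make_dataset(
            {"a": [(1, True, 5)]},
            flags={("a", 1, j): (True, True, True, True) for j in range(5)},
        )
        with caplog.at_level("WARNING"):
            post = proportion_posterior(ds, "vet", mode="dog", settings=quick_mcmc(4))
        assert any("flags are all" in r.message for r in caplog.records)
        assert post.median() > 0.7

    def test_parameter_recovery_on_synthetic_survey(self, quick_mcmc):
        """Posterior median recovers the generating membership probability
        within 3 Monte-Carlo SEs for n >= 500 dogs."""
        p_true = 0.35
        config = SurveyConfig(
            n_areas=10,
            calls_per_area=300,
            p_valid=0.9,
            p_own=0.5,
            area_effect_sd=0.0,
            membership_joint=joint_from_marginals(p_true, 0.4, 0.3, 0.02),
            seed=5,
        )
        ds = generate_survey(config)
        n = len(ds.dogs)
        assert n >= 500
        post = proportion_posterior(ds, "vet", mode="dog", settings=quick_mcmc(6))
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(post.median() - p_true) < 3 * se


class TestAreaMode:
    def test_fixture_medians_track_cluster_heterogeneity(self, fixture_ds, quick_mcmc):
        post = proportion_posterior(
            fixture_ds, "insured", mode="area", settings=quick_mcmc(7)
        )
        # centred near the raw pooled share, far wider than the dog-level CI
        assert post.median() == pytest.approx(73 / 181, abs=0.05)
        lo, hi = post.ci()
        assert hi - lo > 0.3

    def test_rhat_near_one_on_fixture(self, fixture_ds, quick_mcmc):
        for name in ("vet", "insured", "kc"):
            post = proportion_posterior(
                fixture_ds, name, mode="area", settings=quick_mcmc(8)
            )
            assert post.rhat() < 1.05


class TestPopulationFromSubpop:
    def test_degenerate_ratio_is_exact(self):
        est = population_from_subpop(100.0, np.array([0.5]), "toy")
        assert est.median == 200.0

    def test_matches_brute_force_ratio_oracle(self):
        rng = np.random.default_rng(9)
        s = rng.normal(2e6, 2e5, size=10**6)
        p = rng.beta(73, 108, size=10**6)
        est = population_from_subpop(s, p, "toy")
        brute = np.median(s / p)
        assert est.median == pytest.approx(brute, rel=1e-12)
        sub = rng.choice(s, 4000)
        psub = rng.choice(p, 4000)
        small = population_from_subpop(sub, psub, "toy")
        assert small.median == pytest.approx(brute, rel=0.02)

    def test_nonpositive_proportions_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            est = population_from_subpop(
                100.0, np.array([0.5, -0.1, 0.0, 0.25]), "toy"
            )
        assert est.draws.size == 2
        assert any("non-positive" in r.message for r in caplog.records)

    def test_recycling_aligns_sample_sets(self):
        est = population_from_subpop(
            np.array([100.0, 200.0]), np.array([0.5, 0.5, 0.5, 0.5]), "toy"
        )
        assert sorted(set(est.draws)) == [200.0, 400.0]


class TestHouseholdRateModel:
    def test_equal_rates_flat_prior_is_exact(self, quick_mcmc):
        est = population_from_household_rate(
            [0.4] * 5,
            n_households=25.9e6,
            prior=PriorSpec("flat"),
            settings=quick_mcmc(10),
        )
        assert np.allclose(est.draws, 0.4 * 25.9e6)

    def test_tight_prior_dominates(self, quick_mcmc):
        est = population_from_household_rate(
            [0.2, 0.3, 0.4, 0.5],
            n_households=25.9e6,
            prior=PriorSpec("normal", 12e6, 1e3),
            settings=quick_mcmc(11),
        )
        assert est.median == pytest.approx(12e6, rel=1e-3)

    def test_flat_prior_centres_on_sample_mean(self, quick_mcmc):
        rates = [0.3, 0.35, 0.4, 0.45, 0.5]
        est = population_from_household_rate(
            rates, n_households=1e6, prior=PriorSpec("flat"), settings=quick_mcmc(12)
        )
        assert est.median == pytest.approx(np.mean(rates) * 1e6, rel=0.02)

    def test_input_validation(self, quick_mcmc):
        with pytest.raises(ValueError):
            population_from_household_rate([0.4], settings=quick_mcmc(13))
        with pytest.raises(ValueError):
            population_from_household_rate(
                [0.4, 0.5], n_households=0, settings=quick_mcmc(14)
            )


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self):
        chain = np.random.default_rng(15).normal(size=500)
        assert gelman_rubin(np.vstack([chain, chain])) == 1.0

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(10, 1, 1000)
        assert gelman_rubin(np.vstack([a, b])) > 1.5

    def test_matches_textbook_formula_on_random_chains(self):
        rng = np.random.default_rng(17)
        chains = rng.normal(size=(4, 800)) + rng.normal(scale=0.2, size=(4, 1))
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestCredibilityInterval:
    def test_constant_draws(self):
        assert credibility_interval([5.0, 5.0, 5.0]) == (5.0, 5.0)

    def test_matches_sorted_interpolation_oracle(self):
        draws = np.arange(1, 1001, dtype=float)
        lo, hi = credibility_interval(draws, 0.95)
        # linear interpolation on the sorted sample
        def q(p):
            h = (len(draws) - 1) * p
            lo_i = int(np.floor(h))
            return draws[lo_i] + (h - lo_i) * (draws[min(lo_i + 1, 999)] - draws[lo_i])
        assert lo == pytest.approx(q(0.025))
        assert hi == pytest.approx(q(0.975))

    def test_symmetric_about_median_for_symmetric_draws(self):
        draws = np.random.default_rng(18).normal(size=200_000)
        lo, hi = credibility_interval(draws)
        med = np.median(draws)
        assert (med - lo) == pytest.approx(hi - med, abs=0.03)
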