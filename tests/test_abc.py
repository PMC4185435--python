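"""ABC machinery tests: chain contracts, tolerance schedule, posterior
discretization, KL divergence, marginals, credible intervals."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from scratchabc import (
    ABCConfig,
    InitializationError,
    Marginal,
    PosteriorChain,
    PosteriorHistogram,
    abc_mcmc,
    epsilon_schedule,
    histogram_posterior,
    kl_divergence,
    marginals,
    mean_and_ci,
    probs_to_rates,
    simulate,
    summarize,
)


@pytest.fixture
def small_observed(small_sim_config):
    return summarize(simulate(small_sim_config))


@pytest.fixture
def small_abc_config(small_sim_config):
    return ABCConfig(
        sim_config=small_sim_config, epsilon=1.0, Gamma=(0.2, 0.02), M=150,
        statistic="K", seed=5,
    )


def _chain_from_states(states, observed=None, config=None):
    states = np.asarray(states, dtype=float)
    M = len(states)
    return PosteriorChain(
        states, np.ones(M, bool), np.zeros(M), observed, config
    )


class TestChain:
    def test_infinite_epsilon_accepts_every_inbox_proposal(
        self, small_abc_config, small_observed
    ):
        cfg = replace(small_abc_config, epsilon=np.inf, M=100)
        chain = abc_mcmc(cfg, small_observed)
        inbox = np.isfinite(chain.distances)
        assert chain.accepted[inbox].all()
        assert not chain.accepted[~inbox].any()

    def test_states_never_leave_prior_box(self, small_abc_config, small_observed):
        cfg = replace(small_abc_config, epsilon=np.inf, M=300, Gamma=(0.5, 0.5))
        chain = abc_mcmc(cfg, small_observed)
        assert (chain.states >= 0).all() and (chain.states <= 1).all()

    def test_same_seed_gives_identical_chain(self, small_abc_config, small_observed):
        a = abc_mcmc(small_abc_config, small_observed)
        b = abc_mcmc(small_abc_config, small_observed)
        assert (a.states == b.states).all()
        assert (a.accepted == b.accepted).all()
        d = np.nan_to_num(a.distances, nan=-1.0)
        assert (d == np.nan_to_num(b.distances, nan=-1.0)).all()

    def test_unreachable_epsilon_raises_with_advice(
        self, small_abc_config, small_observed
    ):
        cfg = replace(small_abc_config, epsilon=1e-9, init_attempts=30)
        with pytest.raises(InitializationError, match="larger epsilon"):
            abc_mcmc(cfg, small_observed)

    def test_geometry_mismatch_rejected(self, small_abc_config, paper_sim_config):
        wrong = summarize(simulate(paper_sim_config))
        with pytest.raises(ValueError, match="lattice"):
            abc_mcmc(small_abc_config, wrong)

    def test_unset_epsilon_rejected(self, small_abc_config, small_observed):
        with pytest.raises(ValueError, match="epsilon"):
            abc_mcmc(replace(small_abc_config, epsilon=None), small_observed)

    def test_accepted_distances_never_exceed_epsilon(
        self, small_abc_config, small_observed
    ):
        chain = abc_mcmc(small_abc_config, small_observed)
        assert np.all(
            chain.distances[chain.accepted] <= small_abc_config.epsilon
        )

    def test_shrinking_epsilon_shrinks_accepted_spread(
        self, small_abc_config, small_observed
    ):
        wide = abc_mcmc(replace(small_abc_config, epsilon=2.0), small_observed)
        narrow = abc_mcmc(replace(small_abc_config, epsilon=0.5), small_observed)
        assert (
            narrow.distances[narrow.accepted].max()
            <= wide.distances[wide.accepted].max()
        )


class TestEpsilonSchedule:
    def test_single_factor_rejected(self, small_abc_config, small_observed):
        with pytest.raises(ValueError, match="2 candidate"):
            epsilon_schedule(small_abc_config, small_observed, [1.0])

    def test_nonmonotone_factors_rejected(self, small_abc_config, small_observed):
        with pytest.raises(ValueError, match="decreasing"):
            epsilon_schedule(small_abc_config, small_observed, [0.5, 1.0])

    def test_indistinguishably_large_thresholds_choose_the_larger(
        self, small_abc_config, small_observed
    ):
        # both thresholds far above every simulated distance: the posterior
        # cannot depend on which is used, so TV ~ 0 and the larger wins
        cfg = replace(small_abc_config, epsilon=1e6)
        eps, table = epsilon_schedule(
            cfg, small_observed, [1.0, 0.999], pilot_M=150
        )
        assert eps == pytest.approx(1e6)
        assert table.attrs["warning"] is False
        assert table["tv_to_next"].iloc[0] <= 0.05

    def test_diagnostic_table_schema(self, small_abc_config, small_observed):
        eps, table = epsilon_schedule(
            small_abc_config, small_observed, [2.0, 1.0, 0.5], pilot_M=60
        )
        assert list(table["epsilon"]) == [2.0, 1.0, 0.5]
        assert {"acceptance_rate", "tv_to_next", "best_Pm", "best_Pp"} <= set(
            table.columns
        )
        assert eps in set(table["epsilon"])


class TestHistogram:
    def test_point_mass_chain(self):
        chain = _chain_from_states([[0.305, 0.0042]] * 50)
        hist = histogram_posterior(chain, n_m=10, n_p=100)
        assert hist.mass.sum() == pytest.approx(1.0)
        assert hist.mass[3, 0] == pytest.approx(1.0)  # 0.305 -> bin 3, 0.0042 -> bin 0
        assert np.count_nonzero(hist.mass) == 1

    def test_mass_sums_to_one_for_any_chain(self, rng):
        chain = _chain_from_states(rng.random((500, 2)))
        hist = histogram_posterior(chain, n_m=7, n_p=13)
        assert hist.mass.sum() == pytest.approx(1.0)

    def test_uniform_chain_is_uniform_within_multinomial_error(self, rng):
        n = 200_000
        chain = _chain_from_states(rng.random((n, 2)))
        hist = histogram_posterior(chain, n_m=5, n_p=5)
        p = 1 / 25
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(hist.mass - p) < 5 * se)


class TestKL:
    def test_uniform_histogram_has_zero_divergence(self):
        hist = PosteriorHistogram(np.full((20, 30), 1 / 600), 20, 30)
        assert kl_divergence(hist) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_closed_form(self):
        mass = np.zeros((100, 10_000))
        mass[42, 4242] = 1.0
        assert kl_divergence(
            PosteriorHistogram(mass, 100, 10_000)
        ) == pytest.approx(np.log(1e6))

    def test_divergence_is_nonnegative(self, rng):
        for _ in range(20):
            m = rng.random((8, 9))
            hist = PosteriorHistogram(m / m.sum(), 8, 9)
            assert kl_divergence(hist) >= 0


class TestMarginals:
    def test_product_form_recovers_factors(self, rng):
        a = rng.random(6)
        a /= a.sum()
        b = rng.random(11)
        b /= b.sum()
        hist = PosteriorHistogram(np.outer(a, b), 6, 11)
        m_pm, m_pp = marginals(hist)
        assert m_pm.mass == pytest.approx(a)
        assert m_pp.mass == pytest.approx(b)

    def test_point_mass_marginals(self):
        mass = np.zeros((4, 5))
        mass[2, 3] = 1.0
        m_pm, m_pp = marginals(PosteriorHistogram(mass, 4, 5))
        assert m_pm.mass[2] == 1.0 and m_pp.mass[3] == 1.0
        assert m_pm.mass.sum() == pytest.approx(1.0)
        assert m_pp.mass.sum() == pytest.approx(1.0)


class TestMeanAndCI:
    def test_point_mass(self):
        mass = np.zeros(100)
        mass[49] = 1.0  # centre 0.495
        marg = Marginal((np.arange(100) + 0.5) / 100, mass)
        mean, mode, lo, hi = mean_and_ci(marg)
        assert mean == mode == lo == hi == pytest.approx(0.495)

    def test_symmetric_triangle(self):
        mass = np.array([1, 2, 3, 4, 3, 2, 1], dtype=float)
        mass /= mass.sum()
        centres = np.linspace(0.2, 0.8, 7)
        mean, mode, lo, hi = mean_and_ci(Marginal(centres, mass), level=0.9)
        assert mean == pytest.approx(0.5)
        assert mode == pytest.approx(0.5)
        assert lo == pytest.approx(0.5 - (hi - 0.5))

    def test_mode_tie_broken_toward_smaller_value(self):
        mass = np.array([0.0, 0.5, 0.5, 0.0])
        centres = np.array([0.125, 0.375, 0.625, 0.875])
        _, mode, _, _ = mean_and_ci(Marginal(centres, mass), level=0.5)
        assert mode == pytest.approx(0.375)

    def test_discretized_normal_matches_quantiles(self):
        # Normal(0.5, 0.1^2) on 100 cells: the 90% mode-symmetric interval
        # coincides with the symmetric quantile interval (0.335, 0.665)
        edges = np.linspace(0, 1, 101)
        cdf = stats.norm(0.5, 0.1).cdf(edges)
        mass = np.diff(cdf)
        mass /= mass.sum()
        marg = Marginal((edges[:-1] + edges[1:]) / 2, mass)
        mean, mode, lo, hi = mean_and_ci(marg, level=0.90)
        assert mean == pytest.approx(0.5, abs=1e-6)
        assert lo == pytest.approx(stats.norm(0.5, 0.1).ppf(0.05), abs=0.01)
        assert hi == pytest.approx(stats.norm(0.5, 0.1).ppf(0.95), abs=0.01)
        inside = (marg.centres >= lo) & (marg.centres <= hi)
        assert mass[inside].sum() >= 0.90

    def test_unnormalized_marginal_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            mean_and_ci(Marginal(np.array([0.25, 0.75]), np.array([0.5, 0.1])))


class TestUnitConsistency:
    def test_posterior_mean_conversion_is_linear(self, rng):
        # converting the mean equals averaging converted samples
        samples = rng.random((200, 2)) * [1.0, 0.01]
        delta, tau = 25.0, 1 / 24
        mean_then_convert = probs_to_rates(
            samples[:, 0].mean(), samples[:, 1].mean(), delta, tau
        )
        convert_then_mean = np.mean(
            [probs_to_rates(pm, pp, delta, tau) for pm, pp in samples], axis=0
        )
        assert mean_then_convert == pytest.approx(tuple(convert_then_mean))
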